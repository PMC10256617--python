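"""NB additive model: residual AR estimation, basis/constraint behavior,
parameter recovery, shrinkage, concurvity, selection, AUC."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.signal import lfilter

from podcompare import tempmodel as T


def _nb(rng, mu, theta):
    return rng.negative_binomial(theta, theta / (theta + mu)).astype(float)


class TestEstimateRho:
    def test_white_noise_has_negligible_rho(self):
        e = np.random.default_rng(5).normal(size=10_000)
        assert abs(T.estimate_rho(e)) < 0.03

    def test_ar_half_is_recovered(self):
        eps = np.random.default_rng(5).normal(size=10_000)
        e = lfilter([1.0], [1.0, -0.5], eps)
        assert 0.47 <= T.estimate_rho(e) <= 0.53

    def test_constant_series_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert T.estimate_rho(np.ones(500)) == 0.0

    def test_short_series_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="fewer"):
            assert T.estimate_rho(np.random.default_rng(0).normal(size=50)) == 0.0

    def test_block_boundaries_excluded(self):
        # two independent AR(1) blocks: estimate must not couple them
        rng = np.random.default_rng(3)
        a = lfilter([1.0], [1.0, -0.8], rng.normal(size=5000))
        b = lfilter([1.0], [1.0, -0.8], rng.normal(size=5000))
        blocks = np.repeat([0, 1], 5000)
        rho = T.estimate_rho(np.concatenate([a, b]), blocks)
        assert 0.75 <= rho <= 0.85


class TestBases:
    def test_cyclic_basis_wraps_smoothly(self):
        B0 = T.cyclic_bspline_basis(np.array([0.0]), 10, 12.0)
        B12 = T.cyclic_bspline_basis(np.array([12.0]), 10, 12.0)
        assert np.allclose(B0, B12)

    def test_bases_partition_unity(self):
        x = np.linspace(0.3, 9.7, 57)
        assert np.allclose(T.bspline_basis(x, 10, 0, 10).sum(axis=1), 1.0)
        assert np.allclose(T.cyclic_bspline_basis(x, 10, 10.0).sum(axis=1), 1.0)

    def test_small_basis_dimension_rejected(self):
        with pytest.raises(ValueError):
            T.SmoothTerm("x", k=2)


@pytest.fixture(scope="module")
def month_diel_fit():
    """NB hourly counts with a sinusoidal month effect, a negative night
    offset, and latent AR(1) noise."""
    rng = np.random.default_rng(9)
    n = 6000
    hours = pd.date_range("2021-01-01", periods=n, freq="h")
    month_c = (hours.dayofyear.to_numpy() - 1) / 365.25 * 12.0
    diel = np.where((hours.hour >= 21) | (hours.hour < 5), "night", "day")
    eta = 1.0 + np.sin(2 * np.pi * month_c / 12.0) + np.where(diel == "night", -0.5, 0.0)
    eps = rng.normal(0, 0.4 * np.sqrt(1 - 0.25), n)
    eps[0] = rng.normal(0, 0.4)
    lat = lfilter([1.0], [1.0, -0.5], eps)
    y = _nb(rng, np.exp(eta + lat), 2.0)
    tab = pd.DataFrame({"y": y, "month_c": month_c, "diel_period": diel}, index=hours)
    spec = T.ModelSpec(
        response="y",
        smooths=(T.SmoothTerm("month_c", "cyclic", k=12, period=12.0),),
        factors=(T.FactorTerm("diel_period", "day"),),
    )
    return T.fit_additive_model(tab, spec), tab


class TestRecovery:
    def test_month_smooth_tracks_truth(self, month_diel_fit):
        fit, _ = month_diel_fit
        grid = np.linspace(0, 12, 49)
        f = fit.predict_smooth("month_c", grid)
        truth = np.sin(2 * np.pi * grid / 12.0)
        truth -= truth.mean()
        assert np.corrcoef(f, truth)[0, 1] > 0.95

    def test_night_coefficient_negative_and_significant(self, month_diel_fit):
        fit, _ = month_diel_fit
        eff = T.effect_table(fit)
        row = eff.loc["diel_period[night]"]
        assert row["sign"] == "-" and row["effect_size"] < 0
        assert row["p_value"] < 0.001

    def test_cyclic_smooth_matches_at_period_ends(self, month_diel_fit):
        fit, _ = month_diel_fit
        f0 = fit.predict_smooth("month_c", np.array([0.0]))
        f12 = fit.predict_smooth("month_c", np.array([12.0]))
        assert f0 == pytest.approx(f12)

    def test_metadata_reports_the_fit(self, month_diel_fit):
        fit, _ = month_diel_fit
        meta = fit.metadata()
        assert meta["converged"] and 0 <= meta["deviance_explained_pct"] <= 100
        assert meta["theta"] > 0 and 0 <= meta["rho"] < 1
        assert meta["gamma"] == 1.2

    def test_duplicated_hours_rejected(self, month_diel_fit):
        _, tab = month_diel_fit
        dup = pd.concat([tab, tab.iloc[:3]])
        with pytest.raises(ValueError, match="duplicated"):
            T.fit_additive_model(dup, T.ModelSpec(response="y"))


class TestWhitening:
    def test_whitening_at_generating_rho_removes_autocorrelation(self):
        # Gaussian-like counts around a constant mean with AR(1) noise, so
        # the residual lag-1 ACF equals the generating coefficient
        n = 10_000
        hours = pd.date_range("2021-01-01", periods=n, freq="h")
        rng = np.random.default_rng(5)
        eps = rng.normal(0, np.sqrt(1 - 0.25), n)
        eps[0] = rng.normal(0, 1.0)
        lat = lfilter([1.0], [1.0, -0.5], eps)
        y = np.clip(np.round(100.0 + 10.0 * lat), 0, None)
        fit = T.fit_additive_model(
            pd.DataFrame({"y": y}, index=hours),
            T.ModelSpec(response="y", ar1_rho=0.5, theta="auto"),
        )
        assert abs(fit.residual_acf1 - 0.5) < 0.05
        assert abs(fit.whitened_acf1) < 0.05


class TestShrinkage:
    def test_null_covariate_is_shrunk_to_nothing(self):
        """A covariate with zero true effect keeps essentially no degrees of
        freedom under the shrinkage basis (matches the reference shrinkage
        construction's behavior; occasional sub-1-EDF survivors are
        expected at this sample size)."""
        rng = np.random.default_rng(11)
        edfs = []
        for _ in range(20):
            n = 2000
            x1 = rng.uniform(0, 1, n)
            xnull = rng.uniform(0, 1, n)
            y = _nb(rng, np.exp(1.0 + np.sin(2 * np.pi * x1)), 2.0)
            tab = pd.DataFrame({"y": y, "x1": x1, "xnull": xnull})
            spec = T.ModelSpec(
                response="y",
                smooths=(T.SmoothTerm("x1", k=10), T.SmoothTerm("xnull", k=10)),
                ar1_rho=0.0,
                theta=2.0,
            )
            edfs.append(T.fit_additive_model(tab, spec).edf["xnull"])
        edfs = np.array(edfs)
        assert np.median(edfs) < 0.05
        assert (edfs < 0.5).mean() >= 0.75
        assert edfs.max() < 3.0


class TestConcurvity:
    def test_independent_covariates_have_low_concurvity(self):
        rng = np.random.default_rng(2)
        n = 5000
        x1, x2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        y = _nb(rng, np.exp(1 + np.sin(2 * np.pi * x1) + x2), 2.0)
        tab = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        fit = T.fit_additive_model(
            tab,
            T.ModelSpec(
                response="y",
                smooths=(T.SmoothTerm("x1", k=8), T.SmoothTerm("x2", k=8)),
                ar1_rho=0.0,
                theta=2.0,
            ),
        )
        assert (T.concurvity(fit) < 0.2).all()

    def test_duplicated_covariate_has_concurvity_one(self):
        rng = np.random.default_rng(2)
        n = 2000
        x1 = rng.uniform(0, 1, n)
        y = _nb(rng, np.exp(1 + np.sin(2 * np.pi * x1)), 2.0)
        tab = pd.DataFrame({"y": y, "x1": x1, "x3": x1.copy()})
        fit = T.fit_additive_model(
            tab,
            T.ModelSpec(
                response="y",
                smooths=(T.SmoothTerm("x1", k=8), T.SmoothTerm("x3", k=8)),
                ar1_rho=0.0,
                theta=2.0,
            ),
        )
        assert (T.concurvity(fit) > 0.95).all()

    def test_single_smooth_gives_empty_result(self, month_diel_fit):
        fit, _ = month_diel_fit
        assert len(T.concurvity(fit)) == 0


class TestAUC:
    def test_informative_model_beats_chance_and_null_does_not(self):
        rng = np.random.default_rng(4)
        n = 10_000
        x = rng.uniform(0, 1, n)
        y_info = _nb(rng, np.exp(-1.5 + 4.0 * x), 1.0)
        tab = pd.DataFrame({"y": y_info, "x": x})
        fit = T.fit_additive_model(
            tab, T.ModelSpec(response="y", smooths=(T.SmoothTerm("x", k=8),), ar1_rho=0.0, theta=1.0)
        )
        assert T.model_auc(fit) > 0.7
        # scores independent of presence: AUC within the null band
        y_null = _nb(rng, np.full(n, 1.0), 1.0)
        tabn = pd.DataFrame({"y": y_null, "x": x})
        fitn = T.fit_additive_model(
            tabn, T.ModelSpec(response="y", smooths=(T.SmoothTerm("x", k=8),), ar1_rho=0.0, theta=1.0)
        )
        assert 0.45 <= T.model_auc(fitn) <= 0.55

    def test_single_class_presence_is_missing(self):
        rng = np.random.default_rng(1)
        y = _nb(rng, np.full(500, 50.0), 100.0) + 1  # never zero
        fit = T.fit_additive_model(
            pd.DataFrame({"y": y}), T.ModelSpec(response="y", ar1_rho=0.0, theta=100.0)
        )
        assert np.isnan(T.model_auc(fit))


class TestSelection:
    def test_all_significant_model_is_kept(self):
        rng = np.random.default_rng(6)
        n = 2000
        x1 = rng.uniform(0, 1, n)
        diel = rng.choice(["day", "night"], n)
        mu = np.exp(1 + np.sin(2 * np.pi * x1) - 0.8 * (diel == "night"))
        tab = pd.DataFrame({"y": _nb(rng, mu, 2.0), "x1": x1, "diel_period": diel})
        spec = T.ModelSpec(
            response="y",
            smooths=(T.SmoothTerm("x1", k=8),),
            factors=(T.FactorTerm("diel_period", "day"),),
            ar1_rho=0.0,
            theta=2.0,
        )
        fit, trace = T.stepwise_select(tab, spec)
        assert len(trace) == 0
        assert set(fit.spec.term_names) == {"x1", "diel_period"}

    def test_noise_term_is_dropped_first(self):
        rng = np.random.default_rng(42)
        first = 0
        reps = 12
        for _ in range(reps):
            n = 2000
            x1 = rng.uniform(0, 1, n)
            xn = rng.uniform(0, 1, n)
            y = _nb(rng, np.exp(1 + np.sin(2 * np.pi * x1)), 2.0)
            tab = pd.DataFrame({"y": y, "x1": x1, "xn": xn})
            spec = T.ModelSpec(
                response="y",
                smooths=(T.SmoothTerm("x1", k=8), T.SmoothTerm("xn", k=8)),
                ar1_rho=0.0,
                theta=2.0,
            )
            _, trace = T.stepwise_select(tab, spec)
            if len(trace) and trace.iloc[0]["dropped"] == "xn":
                first += 1
        assert first >= reps - 1

    def test_intercept_only_end_state_allowed(self):
        rng = np.random.default_rng(13)
        n = 1500
        xn = rng.uniform(0, 1, n)
        y = _nb(rng, np.full(n, 3.0), 2.0)
        tab = pd.DataFrame({"y": y, "xn": xn})
        spec = T.ModelSpec(
            response="y", smooths=(T.SmoothTerm("xn", k=8),), ar1_rho=0.0, theta=2.0
        )
        fit, trace = T.stepwise_select(tab, spec)
        if len(trace) and trace.iloc[0]["accepted"]:
            assert fit.spec.term_names == ()

    def test_true_model_aic_beats_overfitted(self):
        rng = np.random.default_rng(8)
        wins, reps = 0, 30
        for _ in range(reps):
            n = 1200
            x1 = rng.uniform(0, 1, n)
            xn = rng.uniform(0, 1, n)
            y = _nb(rng, np.exp(1 + np.sin(2 * np.pi * x1)), 2.0)
            tab = pd.DataFrame({"y": y, "x1": x1, "xn": xn})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_true = T.fit_additive_model(
                    tab,
                    T.ModelSpec(response="y", smooths=(T.SmoothTerm("x1", k=8),), ar1_rho=0.0, theta=2.0),
                )
                f_over = T.fit_additive_model(
                    tab,
                    T.ModelSpec(
                        response="y",
                        smooths=(T.SmoothTerm("x1", k=8), T.SmoothTerm("xn", k=8)),
                        ar1_rho=0.0,
                        theta=2.0,
                    ),
                )
            wins += f_true.aic <= f_over.aic + 1e-9
        assert wins / reps >= 0.8


class TestPoissonLimit:
    def test_large_theta_matches_poisson_glm(self):
        """With theta -> large on Poisson data, fitted means agree with a
        plain Poisson GLM (statsmodels) within 1%."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 3000
        diel = rng.choice(["day", "night", "morning"], n)
        eta = 1.0 + np.where(diel == "night", -0.6, 0.0) + np.where(diel == "morning", 0.3, 0.0)
        y = rng.poisson(np.exp(eta)).astype(float)
        tab = pd.DataFrame({"y": y, "diel_period": diel})
        fit = T.fit_additive_model(
            tab,
            T.ModelSpec(response="y", factors=(T.FactorTerm("diel_period", "day"),), ar1_rho=0.0, theta=1e6),
        )
        X = pd.get_dummies(
            pd.Categorical(diel, categories=["day", "morning", "night"]), drop_first=True
        ).astype(float)
        glm = sm.GLM(y, sm.add_constant(X), family=sm.families.Poisson()).fit()
        assert np.max(np.abs(fit.mu - glm.mu) / glm.mu) < 0.01


class TestHourlyTable:
    def _table(self, pod, effort, hourly_cov, buzz=None):
        from podcompare import metrics as metr

        dpm_h = metr.aggregate_detections(pod.trains, "HiModLo", "hour", effort, pod.clicks)
        return T.build_hourly_table(dpm_h, hourly_cov, buzz)

    def test_rows_bounded_by_effort_hours(self, pod_c, effort, small_occupancy):
        from podcompare import covariates as cov

        sun_t = cov.make_sun_table(small_occupancy.start, small_occupancy.end)
        tide_t = cov.make_tide_table(small_occupancy.start, small_occupancy.end)
        hours = pd.date_range(small_occupancy.start, small_occupancy.end, freq="h", inclusive="left")
        hcov = cov.build_hour_covariates(hours, sun_t, tide_t, pod_c.minutes)
        tab = self._table(pod_c, effort, hcov)
        assert len(tab) <= len(hours)
        assert "month_c" in tab and tab["month_c"].between(0, 12).all()
        # hours without detections have no buzz-model offset
        assert tab.loc[tab["dpm"] == 0, "log_dpm"].isna().all()
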