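"""Detection metrics: aggregation semantics, rates, ratios, rank
correlation, matched bins and the validation subsample."""

import numpy as np
import pandas as pd
import pytest

from podcompare import metrics as metr
from podcompare import simulate as sim


def _trains(rows, pod="C"):
    df = pd.DataFrame(
        rows, columns=["start_time", "end_time", "n_clicks", "quality"]
    )
    df["start_time"] = pd.to_datetime(df["start_time"])
    df["end_time"] = pd.to_datetime(df["end_time"])
    df.insert(0, "pod_label", pod)
    df.insert(1, "train_id", [f"{pod}{i}" for i in range(len(df))])
    df["species"] = "NBHF"
    df["truth_behavior"] = "regular"
    return df


DAY = ("2021-06-01", "2021-06-02")


class TestAggregate:
    def test_minute_counting_example(self):
        # clicks in minutes 0, 0 and 5 of one hour
        tr = _trains(
            [
                ("2021-06-01 00:00:10", "2021-06-01 00:00:12", 5, "Hi"),
                ("2021-06-01 00:00:40", "2021-06-01 00:00:42", 5, "Hi"),
                ("2021-06-01 00:05:02", "2021-06-01 00:05:04", 5, "Hi"),
            ]
        )
        hour = metr.aggregate_detections(tr, "Hi", "hour", DAY)
        day = metr.aggregate_detections(tr, "Hi", "day", DAY)
        assert hour.df["value"].iloc[0] == 2  # DPM of the hour
        assert day.df["value"].iloc[0] == 1  # DPH of the day
        assert day.totals()["positive_bins"] == 1  # DPD

    def test_no_trains_gives_zeros_with_effort(self):
        tr = _trains([])
        s = metr.aggregate_detections(tr, "HiModLo", "minute", DAY)
        assert s.df["value"].sum() == 0
        assert s.df["effort"].all() and len(s.df) == 1440

    def test_hi_filter_excludes_lo_trains(self):
        tr = _trains([("2021-06-01 02:00:01", "2021-06-01 02:00:05", 8, "Lo")])
        assert metr.aggregate_detections(tr, "Hi", "minute", DAY).totals()["positive_bins"] == 0
        assert metr.aggregate_detections(tr, "HiModLo", "minute", DAY).totals()["positive_bins"] == 1

    def test_span_vs_start_minute_assignment(self):
        tr = _trains([("2021-06-01 03:00:58", "2021-06-01 03:01:10", 20, "Hi")])
        span = metr.aggregate_detections(tr, "Hi", "minute", DAY, assign="span")
        start = metr.aggregate_detections(tr, "Hi", "minute", DAY, assign="start")
        assert span.totals()["positive_bins"] == 2
        assert start.totals()["positive_bins"] == 1

    def test_trains_outside_effort_raise_unless_clipped(self):
        tr = _trains([("2021-06-03 00:00:01", "2021-06-03 00:00:05", 5, "Hi")])
        with pytest.raises(ValueError):
            metr.aggregate_detections(tr, "Hi", "minute", DAY)
        s = metr.aggregate_detections(tr, "Hi", "minute", DAY, clip=True)
        assert s.totals()["positive_bins"] == 0

    def test_grouping_nesting(self):
        assert metr.GROUPINGS["Hi"].included < metr.GROUPINGS["HiMod"].included
        assert metr.GROUPINGS["HiMod"].included < metr.GROUPINGS["HiModLo"].included


class TestRates:
    def test_rate_standardizes_by_effort(self):
        tr = _trains(
            [(f"2021-06-01 {h:02d}:{m:02d}:01", f"2021-06-01 {h:02d}:{m:02d}:02", 3, "Hi")
             for h in range(4) for m in range(36)]
        )
        s = metr.aggregate_detections(tr, "Hi", "minute", DAY)
        rate = metr.detection_rate(s, "season")
        assert rate.loc["summer"] == pytest.approx(100.0 * 144 / 1440)

    def test_all_positive_gives_100(self):
        tr = _trains([("2021-06-01 00:00:00", "2021-06-01 23:59:59", 10000, "Hi")])
        s = metr.aggregate_detections(tr, "Hi", "minute", DAY)
        assert metr.detection_rate(s, "month").loc[6] == pytest.approx(100.0)

    def test_equal_rates_under_unequal_effort(self):
        # 6 positive minutes/hour in June (1 day) and July (2 days): same rate
        rows = [
            (f"2021-{mo:02d}-{d:02d} {h:02d}:{m:02d}:01", f"2021-{mo:02d}-{d:02d} {h:02d}:{m:02d}:02", 3, "Hi")
            for mo, days in ((6, [1]), (7, [1, 2]))
            for d in days
            for h in range(24)
            for m in range(0, 60, 10)
        ]
        s = metr.aggregate_detections(_trains(rows), "Hi", "minute", ("2021-06-01", "2021-06-02"), clip=True)
        s2 = metr.aggregate_detections(_trains(rows), "Hi", "minute", ("2021-07-01", "2021-07-03"), clip=True)
        r1 = metr.detection_rate(s, "month").loc[6]
        r2 = metr.detection_rate(s2, "month").loc[7]
        assert r1 == pytest.approx(r2)

    def test_detection_ratio_examples(self):
        assert metr.detection_ratio(138, 100) == pytest.approx(1.38)
        assert metr.detection_ratio(7, 7) == 1.0
        with pytest.warns(UserWarning):
            assert np.isnan(metr.detection_ratio(5, 0))


def kendall_tau_oracle(x, y):
    """O(n^2) pair counting with tau-b tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    denom = np.sqrt((n0 - (tx + 0)) * (n0 - (ty + 0)))
    # recompute tie counts the standard way (per tied group)
    def tie_count(v):
        _, counts = np.unique(v, return_counts=True)
        return int(np.sum(counts * (counts - 1) // 2))

    n1, n2 = tie_count(x), tie_count(y)
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        return np.nan
    return (conc - disc) / denom


class TestKendall:
    def test_perfect_concordance_and_discordance(self):
        assert metr.kendall_tau([1, 2, 3], [1, 2, 3])[0] == pytest.approx(1.0)
        assert metr.kendall_tau([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_tie_corrected_value_matches_pair_count_oracle(self):
        x, y = [1, 2, 2, 3], [1, 3, 2, 3]
        tau, _ = metr.kendall_tau(x, y)
        assert tau == pytest.approx(kendall_tau_oracle(x, y))

    def test_constant_series_is_missing(self):
        tau, p = metr.kendall_tau([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(tau) and np.isnan(p)

    def test_matches_oracle_on_random_tied_series(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(3, 51))
            x = rng.integers(0, 6, n)
            y = rng.integers(0, 6, n)
            if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
                continue
            tau, _ = metr.kendall_tau(x, y)
            assert tau == pytest.approx(kendall_tau_oracle(x, y), abs=1e-12)


class TestMatching:
    def _series(self, positives, pod):
        tr = _trains(
            [(f"2021-06-01 {h:02d}:00:01", f"2021-06-01 {h:02d}:00:02", 3, "Hi") for h in positives],
            pod=pod,
        )
        return metr.aggregate_detections(tr, "Hi", "hour", DAY)

    def test_identical_series_fully_matched(self):
        a = self._series([1, 5, 9], "C")
        b = self._series([1, 5, 9], "F")
        assert metr.match_positive_bins(a, b) == {"C": 0.0, "F": 0.0}

    def test_disjoint_series_fully_unmatched(self):
        a = self._series([1, 2], "C")
        b = self._series([10, 11], "F")
        assert metr.match_positive_bins(a, b) == {"C": 1.0, "F": 1.0}

    def test_strict_subset(self):
        a = self._series([3, 4], "C")
        b = self._series([3, 4, 5, 6], "F")
        out = metr.match_positive_bins(a, b)
        assert out["C"] == 0.0 and out["F"] == pytest.approx(0.5)

    def test_mismatched_effort_rejected(self):
        a = self._series([1], "C")
        tr = _trains([("2021-06-01 01:00:01", "2021-06-01 01:00:02", 3, "Hi")], pod="F")
        b = metr.aggregate_detections(tr, "Hi", "hour", ("2021-06-01", "2021-06-03"))
        with pytest.raises(ValueError):
            metr.match_positive_bins(a, b)


class TestValidationSample:
    def test_returns_all_when_fewer_than_requested(self, pod_c, effort):
        out = metr.validation_sample(pod_c.trains.head(20), effort, n_random=10_000, seed=1)
        himod = out[out["component"] == "random_himod"]
        sel = pod_c.trains.head(20)
        expected = metr._positive_minutes(sel, metr.GROUPINGS["HiMod"], "span")
        assert len(himod) == len(expected)

    def test_sample_is_reproducible(self, pod_c, effort):
        a = metr.validation_sample(pod_c.trains, effort, n_random=100, seed=9)
        b = metr.validation_sample(pod_c.trains, effort, n_random=100, seed=9)
        pd.testing.assert_frame_equal(a, b)
        assert (a["component"] == "random_himod").sum() == 100

    def test_every_lo_minute_included(self, pod_c, effort):
        out = metr.validation_sample(pod_c.trains, effort, n_random=5, seed=0)
        lo_minutes = metr._positive_minutes(
            pod_c.trains, metr.FilterGrouping("Lo", frozenset({"Lo"})), "span"
        )
        assert set(out.loc[out["component"] == "all_lo", "minute"]) == set(lo_minutes)


class TestInvariants:
    def test_hierarchy_and_filter_monotonicity_on_random_scenarios(self):
        rng = np.random.default_rng(5)
        for rep in range(6):
            occ = sim.OccupancyParams(
                base_encounter_rate=float(rng.uniform(0.05, 0.6)),
                start_date="2021-06-01",
                end_date="2021-06-06",
            )
            enc = sim.simulate_occupancy(occ, seed=int(rng.integers(2**31)))
            truth = sim.simulate_click_trains(
                enc, sim.TrainParams(), seed=int(rng.integers(2**31)), params_occ=occ
            )
            prof = sim.profile_c_like(p_click=float(rng.uniform(0.2, 0.9)))
            pod = sim.apply_detector(truth, prof, seed=int(rng.integers(2**31)))
            eff = (occ.start, occ.end)
            tot = metr.summary_totals(pod.trains, eff, pod.clicks).set_index("grouping")
            days = 5
            for g in ("Hi", "HiMod", "HiModLo"):
                row = tot.loc[g]
                assert row["DPD"] <= days
                assert row["DPH"] <= 24 * row["DPD"]
                assert row["DPM"] <= 60 * row["DPH"]
                assert row["NClx"] >= row["DPM"]
            for a, b in (("Hi", "HiMod"), ("HiMod", "HiModLo")):
                for m in ("NClx", "DPM", "DPH", "DPD"):
                    assert tot.loc[a, m] <= tot.loc[b, m]

    def test_coarser_bins_positive_when_finer_positive(self, pod_c, effort):
        minute = metr.aggregate_detections(pod_c.trains, "HiModLo", "minute", effort)
        hour = metr.aggregate_detections(pod_c.trains, "HiModLo", "hour", effort)
        pos_hours_from_minutes = set(minute.df.index[minute.df["detpos"] > 0].floor("h"))
        pos_hours = set(hour.df.index[hour.df["detpos"] > 0])
        assert pos_hours_from_minutes == pos_hours
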