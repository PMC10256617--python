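"""Synthetic two-detector click-train data with known ground truth.

The generator produces harbor porpoise NBHF click series with a known
occupancy pattern (seasonal, diel and tidal modulation of encounter rate),
known buzz fraction, and a known per-click observation model for each of two
co-located detectors.  Every downstream stage (detection metrics, buzz
classification, additive models) can therefore be tested against truth
without any field data.

Time convention: all event times are absolute ``pandas.Timestamp`` values
(naive UTC) derived from seconds since deployment start at microsecond
resolution.  Minutes and hours are half-open clock-aligned bins
``[t, t + 60 s)`` and ``[t, t + 3600 s)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

M2_PERIOD_H = 12.4206  # principal lunar semidiurnal tide period, hours

#: default clock-hour diel phases used when no sun table is supplied
_DEFAULT_DIEL_HOURS = {"morning": (5, 9), "day": (9, 17), "evening": (17, 21)}

QUALITY_CLASSES = ("Hi", "Mod", "Lo")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OccupancyParams:
    """Encounter process parameters.

    The instantaneous encounter rate (encounters/hour) is

    ``base_encounter_rate * exp(month_amplitude * cos(2*pi*(doy - month_peak_doy)/365.25))
    * diel_multipliers[phase] * exp(tide_amplitude * cos(2*pi * dt_high / 12.4206))``

    where ``dt_high`` is the signed time (hours) to the nearest high water.
    The exponential-cosine form keeps multipliers positive and makes the
    log-rate sinusoidal, matching the additive-model structure fitted
    downstream.
    """

    base_encounter_rate: float = 0.12  # encounters per hour
    month_amplitude: float = 0.7
    diel_multipliers: dict = field(
        default_factory=lambda: {"morning": 0.9, "day": 1.0, "evening": 0.8, "night": 0.6}
    )
    tide_amplitude: float = 0.25
    encounter_duration_mean: float = 10.0  # minutes
    start_date: str = "2021-04-01"
    end_date: str = "2022-06-19"  # 444 days
    month_peak_doy: float = 15.0  # winter peak, mid-January

    def __post_init__(self) -> None:
        if self.base_encounter_rate < 0:
            raise ValueError("base_encounter_rate must be >= 0")
        if self.encounter_duration_mean <= 0:
            raise ValueError("encounter_duration_mean must be > 0")
        if any(v < 0 for v in self.diel_multipliers.values()):
            raise ValueError("diel multipliers must be >= 0")
        if pd.Timestamp(self.end_date) <= pd.Timestamp(self.start_date):
            raise ValueError("end_date must be after start_date")

    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(self.start_date)

    @property
    def end(self) -> pd.Timestamp:
        return pd.Timestamp(self.end_date)


@dataclass(frozen=True)
class TrainParams:
    """Click-train structure on the log10-millisecond ICI scale.

    Three ICI regimes: buzz (< 10 ms), regular echolocation, and the
    inter-train gap separating successive trains of one encounter.  A train
    is entirely buzz or entirely regular; ``buzz_train_probability`` sets the
    per-train Bernoulli probability of the buzz regime.
    """

    regular_ici_log10_mean: float = 1.78  # ~60 ms
    regular_ici_log10_sd: float = 0.15
    buzz_ici_log10_mean: float = 0.70  # ~5 ms
    buzz_ici_log10_sd: float = 0.15
    intertrain_gap_log10_mean: float = 4.0  # ~10 s
    intertrain_gap_log10_sd: float = 0.3
    buzz_train_probability: float = 0.1
    clicks_per_train_distribution: dict = field(
        default_factory=lambda: {"kind": "geometric", "mean": 14.0, "min": 2}
    )
    #: sd of the per-train log-odds detectability offset (click source
    #: level / beam orientation, shared by co-located detectors); 0 disables
    amplitude_sd: float = 1.0
    #: sd of the per-encounter detectability offset (range of the animal to
    #: the mooring); added to the train-level offset
    encounter_amplitude_sd: float = 1.5

    def __post_init__(self) -> None:
        if not (
            self.buzz_ici_log10_mean
            < 1.0
            < self.regular_ici_log10_mean
            < self.intertrain_gap_log10_mean
        ):
            raise ValueError(
                "ICI ordering violated: need buzz mean < 10 ms < regular mean < gap mean"
            )
        if not 0.0 <= self.buzz_train_probability <= 1.0:
            raise ValueError("buzz_train_probability must be in [0, 1]")


@dataclass(frozen=True)
class DetectorProfile:
    """Per-click observation model for one POD.

    A true click emitted in a minute with standardized noise ``z`` is
    detected independently with probability
    ``logistic(logit(p_click) + noise_slope * z)``; ``noise_slope <= 0``
    means detection degrades as the soundscape gets noisier.  Detected
    clicks of one true train form one detected train when at least
    ``min_clicks_train`` survive.  The train quality class (Hi/Mod/Lo) is
    drawn from a categorical table keyed on completeness (fraction of the
    train's true clicks detected).  False-positive trains are injected as a
    homogeneous Poisson process.
    """

    pod_label: str = "C"
    p_click: float = 0.30
    noise_slope: float = -0.8
    quality_probs: tuple = (
        # (min completeness, P(Hi), P(Mod), P(Lo))
        (0.75, 0.70, 0.25, 0.05),
        (0.40, 0.25, 0.50, 0.25),
        (0.00, 0.05, 0.35, 0.60),
    )
    false_train_rate: float = 0.01  # trains per hour
    min_clicks_train: int = 4
    false_quality_probs: tuple = (0.02, 0.10, 0.88)
    temperature_bias_c: float = 0.0
    #: weight of the per-train detectability offset carried by the truth
    amplitude_coef: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_click <= 1.0:
            raise ValueError("p_click must be in [0, 1]")
        if self.false_train_rate < 0:
            raise ValueError("false_train_rate must be >= 0")
        if self.min_clicks_train < 2:
            raise ValueError("min_clicks_train must be >= 2")
        for row in self.quality_probs:
            if abs(sum(row[1:]) - 1.0) > 1e-9:
                raise ValueError("quality_probs rows must sum to 1")
        if abs(sum(self.false_quality_probs) - 1.0) > 1e-9:
            raise ValueError("false_quality_probs must sum to 1")

    def detection_prob(self, nall_z: np.ndarray, amp: np.ndarray | float = 0.0) -> np.ndarray:
        """Per-click detection probability given standardized Nall and the
        train's detectability offset."""
        nall_z = np.asarray(nall_z, dtype=float)
        if self.p_click <= 0.0:
            return np.zeros_like(nall_z)
        if self.p_click >= 1.0:
            return np.ones_like(nall_z)
        logit = np.log(self.p_click / (1.0 - self.p_click))
        eta = logit + self.noise_slope * nall_z + self.amplitude_coef * np.asarray(amp)
        return 1.0 / (1.0 + np.exp(-eta))


def profile_c_like(**overrides) -> DetectorProfile:
    """A C-POD-like profile: lower sensitivity, strong noise response."""
    return replace(DetectorProfile(), **overrides)


def profile_f_like(**overrides) -> DetectorProfile:
    """An F-POD-like profile: higher sensitivity, weak noise response,
    more Hi-quality trains, fewer false positives."""
    base = DetectorProfile(
        pod_label="F",
        p_click=0.75,
        noise_slope=-0.15,
        quality_probs=(
            (0.75, 0.90, 0.09, 0.01),
            (0.40, 0.55, 0.35, 0.10),
            (0.00, 0.15, 0.45, 0.40),
        ),
        false_train_rate=0.004,
        min_clicks_train=4,
    )
    return replace(base, **overrides)


@dataclass
class GroundTruth:
    """True state of one simulated deployment.

    Attributes
    ----------
    encounters : DataFrame [encounter_id, start, end]
    clicks : DataFrame [encounter_id, train_id, time, behavior]
        behavior in {"regular", "buzz"}.
    minutes : DataFrame indexed by minute [presence, nall, nbhf_clicks]
        ``nall`` counts all click-like events per minute (ambient noise
        events plus the NBHF clicks emitted), so nall >= nbhf_clicks.
    temperature : Series indexed by hour (deg C)
    """

    encounters: pd.DataFrame
    clicks: pd.DataFrame
    minutes: pd.DataFrame
    temperature: pd.Series
    start: pd.Timestamp
    end: pd.Timestamp


@dataclass
class PodData:
    """One detector's view of a deployment: train, click and minute tables."""

    pod_label: str
    trains: pd.DataFrame  # pod_label, train_id, start_time, end_time, n_clicks, quality, species, truth_behavior
    clicks: pd.DataFrame  # pod_label, train_id, time, ici_ms, truth_label
    minutes: pd.DataFrame  # pod_label, minute, nall, temperature_c


# ---------------------------------------------------------------------------
# default diel / tide lookups (used when no sun/tide table is supplied)
# ---------------------------------------------------------------------------


def default_diel_lookup(times: pd.DatetimeIndex) -> np.ndarray:
    """Clock-hour diel phases: morning 05-09, day 09-17, evening 17-21,
    night otherwise."""
    hours = times.hour.to_numpy()
    phase = np.full(len(times), "night", dtype=object)
    for name, (lo, hi) in _DEFAULT_DIEL_HOURS.items():
        phase[(hours >= lo) & (hours < hi)] = name
    return phase


def default_tide_lookup(times: pd.DatetimeIndex) -> np.ndarray:
    """Signed hours to the nearest high water for a pure M2 tide with high
    water at the epoch."""
    t_h = (times.asi8 / 3.6e12) % M2_PERIOD_H
    return np.where(t_h <= M2_PERIOD_H / 2, t_h, t_h - M2_PERIOD_H)


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------


def simulate_occupancy(
    params: OccupancyParams,
    seed: int,
    diel_lookup=None,
    tide_lookup=None,
) -> pd.DataFrame:
    """Draw non-overlapping encounter intervals from an inhomogeneous
    Poisson process by thinning.

    Parameters
    ----------
    params : OccupancyParams
    seed : int
        Seeds a dedicated generator; identical seeds give identical output.
    diel_lookup, tide_lookup : callable, optional
        Map a DatetimeIndex to diel phase labels / signed hours to high
        water.  Defaults emulate fixed clock phases and a pure M2 tide; the
        pipeline passes lookups built from its sun and tide tables so that
        simulation and covariate construction agree.

    Returns
    -------
    DataFrame with columns encounter_id, start, end (overlaps merged,
    clipped to the deployment window).
    """
    rng = np.random.default_rng(seed)
    diel_lookup = diel_lookup or default_diel_lookup
    tide_lookup = tide_lookup or default_tide_lookup

    start, end = params.start, params.end
    span_h = (end - start).total_seconds() / 3600.0
    diel_max = max(params.diel_multipliers.values()) if params.diel_multipliers else 1.0
    bound = (
        params.base_encounter_rate
        * np.exp(abs(params.month_amplitude))
        * diel_max
        * np.exp(abs(params.tide_amplitude))
    )
    if bound == 0.0:
        return pd.DataFrame(columns=["encounter_id", "start", "end"])

    n_cand = rng.poisson(bound * span_h)
    cand_h = np.sort(rng.uniform(0.0, span_h, size=n_cand))
    cand_t = start + pd.to_timedelta(cand_h, unit="h")

    doy = cand_t.dayofyear.to_numpy().astype(float)
    month_mult = np.exp(
        params.month_amplitude * np.cos(2 * np.pi * (doy - params.month_peak_doy) / 365.25)
    )
    phases = diel_lookup(cand_t)
    diel_mult = np.array([params.diel_multipliers.get(p, 1.0) for p in phases])
    dt_high = np.asarray(tide_lookup(cand_t), dtype=float)
    tide_mult = np.exp(params.tide_amplitude * np.cos(2 * np.pi * dt_high / M2_PERIOD_H))

    rate = params.base_encounter_rate * month_mult * diel_mult * tide_mult
    keep = rng.uniform(size=n_cand) < rate / bound
    starts_h = cand_h[keep]
    dur_h = rng.exponential(params.encounter_duration_mean / 60.0, size=starts_h.size)
    ends_h = np.minimum(starts_h + dur_h, span_h)

    # merge overlapping intervals so encounters are disjoint
    merged: list[tuple[float, float]] = []
    for s, e in zip(starts_h, ends_h):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    if not merged:
        return pd.DataFrame(columns=["encounter_id", "start", "end"])
    arr = np.array(merged)
    # microsecond resolution throughout; avoids sub-us float residue
    to_us = lambda h: pd.to_timedelta(np.round(h * 3.6e9).astype(np.int64), unit="us")
    return pd.DataFrame(
        {
            "encounter_id": np.arange(len(arr)),
            "start": start + to_us(arr[:, 0]),
            "end": start + to_us(arr[:, 1]),
        }
    )


# ---------------------------------------------------------------------------
# click trains
# ---------------------------------------------------------------------------


def _draw_clicks_per_train(dist: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist.get("kind", "geometric")
    lo = int(dist.get("min", 2))
    if kind == "fixed":
        return np.full(n, max(int(dist["n"]), lo))
    if kind == "poisson":
        return lo + rng.poisson(max(dist["mean"] - lo, 0.0), size=n)
    if kind == "geometric":
        # shifted geometric: support {lo, lo+1, ...} with the requested mean
        mean_excess = max(dist["mean"] - lo, 1e-9)
        p = 1.0 / (1.0 + mean_excess)
        return lo + rng.geometric(p, size=n) - 1
    raise ValueError(f"unknown clicks_per_train distribution kind: {kind!r}")


def simulate_click_trains(
    encounters: pd.DataFrame, params: TrainParams, seed: int, params_occ: OccupancyParams | None = None
) -> GroundTruth:
    """Fill encounters with click trains.

    Within an encounter, trains alternate with lognormal inter-train gaps;
    each train is buzz or regular per ``buzz_train_probability`` and its
    successive ICIs are lognormal in the corresponding regime.  Every click
    carries a behavior label.

    The returned :class:`GroundTruth` also carries per-minute true presence,
    a per-minute Nall noise series (lognormal AR(1) ambient events plus the
    emitted NBHF clicks) and an hourly temperature series; see
    :func:`simulate_noise_and_temperature`.
    """
    rng = np.random.default_rng(seed)
    if len(encounters) == 0:
        empty_clicks = pd.DataFrame(columns=["encounter_id", "train_id", "time", "behavior", "amp"])
        if params_occ is None:
            raise ValueError("params_occ required to frame an empty truth")
        minutes, temperature = simulate_noise_and_temperature(
            params_occ.start, params_occ.end, empty_clicks, rng
        )
        return GroundTruth(
            encounters.copy(), empty_clicks, minutes, temperature, params_occ.start, params_occ.end
        )

    starts = encounters["start"].to_numpy()
    ends = encounters["end"].to_numpy()
    exp_ici_ms = (1 - params.buzz_train_probability) * 10 ** (
        params.regular_ici_log10_mean + 1.15 * params.regular_ici_log10_sd**2
    ) + params.buzz_train_probability * 10 ** (params.buzz_ici_log10_mean)
    exp_clicks = max(params.clicks_per_train_distribution.get("mean", 10), 2)
    exp_gap_ms = 10 ** (params.intertrain_gap_log10_mean + 1.15 * params.intertrain_gap_log10_sd**2)
    exp_cycle_s = (exp_clicks * exp_ici_ms + exp_gap_ms) / 1000.0

    frames = []
    train_counter = 0
    for enc_id, (s, e) in enumerate(zip(starts, ends)):
        dur_s = (e - s) / np.timedelta64(1, "s")
        n_trains = int(dur_s / exp_cycle_s * 2.0) + 8  # generous overshoot, trimmed below
        is_buzz = rng.uniform(size=n_trains) < params.buzz_train_probability
        amp = (
            rng.normal(0.0, params.amplitude_sd, size=n_trains)
            if params.amplitude_sd > 0
            else np.zeros(n_trains)
        )
        if params.encounter_amplitude_sd > 0:
            amp = amp + rng.normal(0.0, params.encounter_amplitude_sd)
        n_clicks = _draw_clicks_per_train(params.clicks_per_train_distribution, n_trains, rng)
        total = int(n_clicks.sum())
        train_of_click = np.repeat(np.arange(n_trains), n_clicks)
        mu = np.where(is_buzz, params.buzz_ici_log10_mean, params.regular_ici_log10_mean)
        sd = np.where(is_buzz, params.buzz_ici_log10_sd, params.regular_ici_log10_sd)
        ici_ms = 10 ** rng.normal(mu[train_of_click], sd[train_of_click], size=total)
        # the first interval of each train is the preceding inter-train gap
        first_idx = np.concatenate(([0], np.cumsum(n_clicks)[:-1]))
        gaps_ms = 10 ** rng.normal(
            params.intertrain_gap_log10_mean, params.intertrain_gap_log10_sd, size=n_trains
        )
        ici_ms[first_idx] = gaps_ms
        ici_ms[0] = 0.0  # first train starts at the encounter start
        t_s = np.cumsum(ici_ms) / 1000.0
        inside = t_s <= dur_s
        if not inside.any():
            continue
        t_s = t_s[inside]
        toc = train_of_click[inside]
        times = pd.Timestamp(s) + pd.to_timedelta(np.round(t_s * 1e6).astype(np.int64), unit="us")
        frames.append(
            pd.DataFrame(
                {
                    "encounter_id": enc_id,
                    "train_id": train_counter + toc,
                    "time": times,
                    "behavior": np.where(is_buzz[toc], "buzz", "regular"),
                    "amp": amp[toc],
                }
            )
        )
        train_counter += int(toc.max()) + 1

    clicks = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["encounter_id", "train_id", "time", "behavior", "amp"])
    )
    # drop trains reduced to a single click by trimming (a train has >= 2 clicks)
    if len(clicks):
        sizes = clicks.groupby("train_id")["time"].transform("size")
        clicks = clicks[sizes >= 2].reset_index(drop=True)

    if params_occ is not None:
        start, end = params_occ.start, params_occ.end
    else:
        start = pd.Timestamp(starts.min()).floor("D")
        end = pd.Timestamp(ends.max()).ceil("D")
    minutes, temperature = simulate_noise_and_temperature(start, end, clicks, rng)
    return GroundTruth(encounters.copy(), clicks, minutes, temperature, start, end)


def simulate_noise_and_temperature(
    start: pd.Timestamp,
    end: pd.Timestamp,
    clicks: pd.DataFrame,
    rng: np.random.Generator,
    nall_log_mean: float = 4.5,
    nall_log_sd: float = 0.8,
    nall_ar1: float = 0.97,
    temp_mean_c: float = 11.5,
    temp_amplitude_c: float = 3.5,
    temp_noise_sd: float = 0.3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-minute Nall (lognormal AR(1) ambient events + emitted NBHF
    clicks) and an hourly seasonal temperature series.

    Both co-deployed detectors share this series: co-located devices
    experience the same soundscape and water mass.
    """
    minute_index = pd.date_range(start, end, freq="min", inclusive="left")
    n = len(minute_index)
    from scipy.signal import lfilter

    eps = rng.normal(0.0, nall_log_sd * np.sqrt(1 - nall_ar1**2), size=n)
    eps[0] = rng.normal(0.0, nall_log_sd)  # stationary start
    log_nall = lfilter([1.0], [1.0, -nall_ar1], eps)
    ambient = np.exp(nall_log_mean + log_nall).astype(np.int64)

    nbhf = np.zeros(n, dtype=np.int64)
    presence = np.zeros(n, dtype=bool)
    if len(clicks):
        idx = ((clicks["time"].to_numpy() - start.to_datetime64()) / np.timedelta64(1, "m")).astype(
            np.int64
        )
        idx = idx[(idx >= 0) & (idx < n)]
        counts = np.bincount(idx, minlength=n)
        nbhf = counts.astype(np.int64)
        presence = counts > 0

    minutes = pd.DataFrame(
        {"presence": presence, "nall": ambient + nbhf, "nbhf_clicks": nbhf}, index=minute_index
    )
    minutes.index.name = "minute"

    hour_index = pd.date_range(start, end, freq="h", inclusive="left")
    doy = hour_index.dayofyear.to_numpy().astype(float)
    temp = (
        temp_mean_c
        - temp_amplitude_c * np.cos(2 * np.pi * (doy - 60.0) / 365.25)
        + rng.normal(0.0, temp_noise_sd, size=len(hour_index))
    )
    temperature = pd.Series(np.round(temp, 2), index=hour_index, name="temperature_c")
    temperature.index.name = "hour"
    return minutes, temperature


# ---------------------------------------------------------------------------
# detector observation model
# ---------------------------------------------------------------------------


def apply_detector(truth: GroundTruth, profile: DetectorProfile, seed: int) -> PodData:
    """Pass the true click series through one detector's observation model.

    Each true click is detected independently with probability
    ``logistic(logit(p_click) + noise_slope * z)`` where ``z`` is the
    standardized log-Nall of the click's minute.  Detected clicks of a true
    train form one detected train when at least ``min_clicks_train``
    survive; its quality class is drawn from the completeness table.
    False-positive trains (species still "NBHF" — they emulate
    misclassified noise) are injected at ``false_train_rate`` per hour.
    """
    rng = np.random.default_rng(seed)
    minutes = truth.minutes
    log_nall = np.log(minutes["nall"].to_numpy().astype(float) + 1.0)
    z_all = (log_nall - log_nall.mean()) / max(log_nall.std(), 1e-12)
    z_by_minute = pd.Series(z_all, index=minutes.index)

    clicks = truth.clicks
    det_clicks = clicks.iloc[0:0]
    if len(clicks):
        click_minute = clicks["time"].dt.floor("min")
        z = z_by_minute.reindex(click_minute).to_numpy()
        z = np.nan_to_num(z, nan=0.0)
        amp = clicks["amp"].to_numpy() if "amp" in clicks.columns else 0.0
        p = profile.detection_prob(z, amp)
        detected = rng.uniform(size=len(clicks)) < p
        det_clicks = clicks[detected]

    train_rows = []
    click_rows = []
    trains = pd.DataFrame()
    pod_clicks = pd.DataFrame()
    if len(det_clicks):
        det_clicks = det_clicks.sort_values(["train_id", "time"], kind="stable")
        counts = det_clicks.groupby("train_id", sort=True).size()
        kept_ids = counts.index[counts >= profile.min_clicks_train]
        if len(kept_ids):
            true_sizes = clicks.groupby("train_id").size()
            kept = det_clicks[det_clicks["train_id"].isin(kept_ids)]
            agg = kept.groupby("train_id", sort=True).agg(
                start_time=("time", "first"),
                end_time=("time", "last"),
                n_clicks=("time", "size"),
                truth_behavior=("behavior", "first"),
            )
            completeness = agg["n_clicks"].to_numpy() / true_sizes.loc[agg.index].to_numpy()
            thresholds = np.array([row[0] for row in profile.quality_probs])
            cum = np.cumsum([row[1:] for row in profile.quality_probs], axis=1)
            bin_idx = np.array(
                [np.flatnonzero(c >= thresholds)[0] for c in np.round(completeness, 12)]
            )
            u = rng.uniform(size=len(agg))
            q_idx = (u[:, None] > cum[bin_idx]).sum(axis=1).clip(0, 2)
            label_of = {
                tid: f"{profile.pod_label}{tid:08d}" for tid in agg.index
            }
            trains = pd.DataFrame(
                {
                    "pod_label": profile.pod_label,
                    "train_id": [label_of[t] for t in agg.index],
                    "start_time": agg["start_time"].to_numpy(),
                    "end_time": agg["end_time"].to_numpy(),
                    "n_clicks": agg["n_clicks"].to_numpy(),
                    "quality": np.array(QUALITY_CLASSES)[q_idx],
                    "species": "NBHF",
                    "truth_behavior": agg["truth_behavior"].to_numpy(),
                }
            )
            t_ns = kept["time"].to_numpy().astype("datetime64[us]").astype(np.int64)
            same_train = np.concatenate(
                ([False], kept["train_id"].to_numpy()[1:] == kept["train_id"].to_numpy()[:-1])
            )
            ici_ms = np.where(same_train, np.concatenate(([0], np.diff(t_ns))) / 1000.0, np.nan)
            pod_clicks = pd.DataFrame(
                {
                    "pod_label": profile.pod_label,
                    "train_id": kept["train_id"].map(label_of).to_numpy(),
                    "time": kept["time"].to_numpy(),
                    "ici_ms": ici_ms,
                    "truth_label": kept["behavior"].to_numpy(),
                }
            )

    # false-positive trains
    span_h = (truth.end - truth.start).total_seconds() / 3600.0
    n_false = rng.poisson(profile.false_train_rate * span_h)
    if n_false:
        f_starts = truth.start + pd.to_timedelta(
            np.round(np.sort(rng.uniform(0.0, span_h, size=n_false)) * 3.6e9).astype(np.int64),
            unit="us",
        )
        for j, fs in enumerate(f_starts):
            nc = int(rng.integers(profile.min_clicks_train, profile.min_clicks_train + 6))
            ici_ms = 10 ** rng.normal(1.9, 0.25, size=nc - 1)
            t_ms = np.concatenate(([0.0], np.cumsum(ici_ms)))
            times = pd.Series(fs + pd.to_timedelta(np.round(t_ms * 1000).astype(np.int64), unit="us"))
            quality = rng.choice(QUALITY_CLASSES, p=profile.false_quality_probs)
            tid = f"{profile.pod_label}FP{j:06d}"
            train_rows.append(
                {
                    "pod_label": profile.pod_label,
                    "train_id": tid,
                    "start_time": times.iloc[0],
                    "end_time": times.iloc[-1],
                    "n_clicks": nc,
                    "quality": quality,
                    "species": "NBHF",
                    "truth_behavior": "false",
                }
            )
            click_rows.append(
                pd.DataFrame(
                    {
                        "pod_label": profile.pod_label,
                        "train_id": tid,
                        "time": times,
                        "ici_ms": np.concatenate(([np.nan], ici_ms)),
                        "truth_label": "false",
                    }
                )
            )

    train_cols = [
        "pod_label",
        "train_id",
        "start_time",
        "end_time",
        "n_clicks",
        "quality",
        "species",
        "truth_behavior",
    ]
    click_cols = ["pod_label", "train_id", "time", "ici_ms", "truth_label"]
    false_trains = pd.DataFrame(train_rows, columns=train_cols)
    parts_t = [df for df in (trains, false_trains) if len(df)]
    trains = pd.concat(parts_t, ignore_index=True) if parts_t else pd.DataFrame(columns=train_cols)
    if len(trains):
        trains = trains.sort_values("start_time", kind="stable").reset_index(drop=True)
    parts_c = [df for df in [pod_clicks] + click_rows if len(df)]
    pod_clicks = (
        pd.concat(parts_c, ignore_index=True) if parts_c else pd.DataFrame(columns=click_cols)
    )
    if len(pod_clicks):
        pod_clicks = pod_clicks.sort_values(["time", "train_id"], kind="stable").reset_index(
            drop=True
        )

    temp_minute = truth.temperature.reindex(minutes.index.floor("h")).to_numpy()
    pod_minutes = pd.DataFrame(
        {
            "pod_label": profile.pod_label,
            "minute": minutes.index,
            "nall": minutes["nall"].to_numpy(),
            "temperature_c": np.round(temp_minute + profile.temperature_bias_c, 2),
        }
    )
    return PodData(profile.pod_label, trains, pod_clicks, pod_minutes)


# ---------------------------------------------------------------------------
# export round-trip
# ---------------------------------------------------------------------------

_TIME_FMT = "%Y-%m-%dT%H:%M:%S.%f"


def write_pod_export(pod: PodData, path) -> None:
    """Write one pod's trains/clicks/minutes as CSVs under ``path``.

    Deterministic: identical data yield byte-identical files.
    """
    import pathlib

    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trains = pod.trains.copy()
    for col in ("start_time", "end_time"):
        trains[col] = pd.to_datetime(trains[col]).dt.strftime(_TIME_FMT)
    trains.to_csv(path / "trains.csv", index=False)
    clicks = pod.clicks.copy()
    clicks["time"] = pd.to_datetime(clicks["time"]).dt.strftime(_TIME_FMT)
    clicks["ici_ms"] = clicks["ici_ms"].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
    clicks.to_csv(path / "clicks.csv", index=False)
    minutes = pod.minutes.copy()
    minutes["minute"] = pd.to_datetime(minutes["minute"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    minutes.to_csv(path / "minutes.csv", index=False)


def _read_csv_checked(fn, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(fn, **kw)
    except pd.errors.ParserError as exc:  # surface the offending line
        raise ValueError(f"malformed POD export {fn}: {exc}") from exc


def read_pod_export(path, sort_on_read: bool = False) -> PodData:
    """Read a directory written by :func:`write_pod_export`.

    Raises ``ValueError`` on malformed files or, unless ``sort_on_read``,
    on out-of-order click timestamps.
    """
    import pathlib

    path = pathlib.Path(path)
    trains = _read_csv_checked(path / "trains.csv")
    for col in ("start_time", "end_time"):
        trains[col] = pd.to_datetime(trains[col], format=_TIME_FMT)
    trains["train_id"] = trains["train_id"].astype(str)
    clicks = _read_csv_checked(path / "clicks.csv")
    clicks["time"] = pd.to_datetime(clicks["time"], format=_TIME_FMT)
    clicks["train_id"] = clicks["train_id"].astype(str)
    if "ici_ms" in clicks:
        clicks["ici_ms"] = pd.to_numeric(clicks["ici_ms"], errors="coerce")
    if len(clicks) and not clicks["time"].is_monotonic_increasing:
        if sort_on_read:
            clicks = clicks.sort_values(["time", "train_id"], kind="stable").reset_index(drop=True)
        else:
            bad = int(np.argmax(np.diff(clicks["time"].to_numpy()) < np.timedelta64(0))) + 2
            raise ValueError(f"clicks.csv: out-of-order timestamp at data line {bad}")
    minutes = _read_csv_checked(path / "minutes.csv")
    minutes["minute"] = pd.to_datetime(minutes["minute"])
    label = str(
        trains["pod_label"].iloc[0]
        if len(trains)
        else (minutes["pod_label"].iloc[0] if len(minutes) else "?")
    )
    return PodData(label, trains, clicks, minutes)
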