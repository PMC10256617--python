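"""Detection metrics and inter-POD comparison statistics.

Aggregates quality-filtered click trains into detection-positive minutes /
hours / days (DPM, DPH, DPD) and classified-click counts (NClx), computes
effort-standardized detection rates, the F/C detection ratio, Kendall
rank correlations between co-deployed detectors, and matched/unmatched
positive-bin proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from podcompare.covariates import SEASONS


@dataclass(frozen=True)
class FilterGrouping:
    """A nested train-quality filter: Hi, HiMod or HiModLo."""

    name: str
    included: frozenset

    def __post_init__(self) -> None:
        if not self.included <= {"Hi", "Mod", "Lo"}:
            raise ValueError(f"unknown quality classes in {self.included}")


GROUPINGS = {
    "Hi": FilterGrouping("Hi", frozenset({"Hi"})),
    "HiMod": FilterGrouping("HiMod", frozenset({"Hi", "Mod"})),
    "HiModLo": FilterGrouping("HiModLo", frozenset({"Hi", "Mod", "Lo"})),
}

RESOLUTIONS = ("minute", "hour", "day")


@dataclass
class DetectionSeries:
    """Per-bin detection values for one pod, grouping and resolution.

    ``df`` is indexed by bin start with columns:

    - ``detpos``: 1 if the bin contains >= 1 included train, else 0
    - ``value``: the resolution's count metric — the minute indicator,
      DPM per hour (0-60), or DPH per day (0-24)
    - ``nclx``: clicks of included trains in the bin
    - ``effort``: True where the bin was monitored
    """

    pod_label: str
    grouping: FilterGrouping
    resolution: str
    df: pd.DataFrame

    def totals(self) -> dict:
        d = self.df[self.df["effort"]]
        return {
            "positive_bins": int(d["detpos"].sum()),
            "value_total": int(d["value"].sum()),
            "nclx": int(d["nclx"].sum()),
            "monitored_bins": int(d["effort"].sum()),
        }


def _positive_minutes(
    trains: pd.DataFrame, grouping: FilterGrouping, assign: str
) -> pd.DatetimeIndex:
    """Minutes occupied by included trains (span- or start-minute rule)."""
    sel = trains[trains["quality"].isin(grouping.included)]
    if len(sel) == 0:
        return pd.DatetimeIndex([])
    starts = sel["start_time"].dt.floor("min")
    if assign == "start":
        return pd.DatetimeIndex(starts.unique()).sort_values()
    ends = sel["end_time"].dt.floor("min")
    spans = ((ends - starts).dt.total_seconds().to_numpy() / 60.0).round().astype(np.int64)
    sizes = spans + 1
    start_min = starts.to_numpy().astype("datetime64[m]").astype(np.int64)
    offsets = np.arange(sizes.sum()) - np.repeat(np.cumsum(sizes) - sizes, sizes)
    mins = np.repeat(start_min, sizes) + offsets
    return pd.DatetimeIndex(np.unique(mins).astype("datetime64[m]").astype("datetime64[ns]"))


def aggregate_detections(
    trains: pd.DataFrame,
    grouping: FilterGrouping | str,
    resolution: str,
    effort: tuple,
    clicks: pd.DataFrame | None = None,
    assign: str = "span",
    clip: bool = False,
) -> DetectionSeries:
    """Aggregate trains into a :class:`DetectionSeries`.

    A minute is detection-positive iff at least one train of the grouping
    overlaps it; by default a train occupies every minute between its
    first and last click (``assign="span"``), with ``assign="start"``
    restricting to the start minute.  Hour values count positive minutes,
    day values count positive hours.  NClx uses click times when
    ``clicks`` is given, otherwise a train's clicks all count in its
    start bin.

    Trains extending outside the effort window raise unless ``clip=True``.
    """
    if isinstance(grouping, str):
        grouping = GROUPINGS[grouping]
    if resolution not in RESOLUTIONS:
        raise ValueError(f"resolution must be one of {RESOLUTIONS}")
    start, end = pd.Timestamp(effort[0]), pd.Timestamp(effort[1])
    pod = str(trains["pod_label"].iloc[0]) if len(trains) else "?"

    if len(trains):
        outside = (trains["end_time"] < start) | (trains["start_time"] >= end)
        if outside.any() and not clip:
            raise ValueError("trains outside the effort period (pass clip=True to clip)")
        trains = trains[~outside]

    minute_index = pd.date_range(start, end, freq="min", inclusive="left")
    pos_min = _positive_minutes(trains, grouping, assign)
    pos_min = pos_min[(pos_min >= start) & (pos_min < end)]
    minute_pos = pd.Series(0, index=minute_index, dtype=np.int64)
    minute_pos.loc[pos_min] = 1

    nclx_min = pd.Series(0, index=minute_index, dtype=np.int64)
    included_ids = set(trains.loc[trains["quality"].isin(grouping.included), "train_id"])
    if clicks is not None and len(clicks):
        cl = clicks[clicks["train_id"].isin(included_ids)]
        counts = cl["time"].dt.floor("min").value_counts()
        counts = counts[(counts.index >= start) & (counts.index < end)]
        nclx_min.loc[counts.index] = counts.to_numpy()
    elif len(trains):
        sel = trains[trains["quality"].isin(grouping.included)]
        counts = sel.groupby(sel["start_time"].dt.floor("min"))["n_clicks"].sum()
        counts = counts[(counts.index >= start) & (counts.index < end)]
        nclx_min.loc[counts.index] = counts.to_numpy()

    if resolution == "minute":
        df = pd.DataFrame(
            {"detpos": minute_pos, "value": minute_pos, "nclx": nclx_min, "effort": True}
        )
    else:
        hour_pos = minute_pos.groupby(minute_pos.index.floor("h")).sum()  # DPM per hour
        nclx_h = nclx_min.groupby(nclx_min.index.floor("h")).sum()
        if resolution == "hour":
            df = pd.DataFrame(
                {
                    "detpos": (hour_pos > 0).astype(np.int64),
                    "value": hour_pos,
                    "nclx": nclx_h,
                    "effort": True,
                }
            )
        else:
            day_pos = (hour_pos > 0).astype(np.int64)
            dph = day_pos.groupby(day_pos.index.floor("D")).sum()  # DPH per day
            nclx_d = nclx_h.groupby(nclx_h.index.floor("D")).sum()
            df = pd.DataFrame(
                {
                    "detpos": (dph > 0).astype(np.int64),
                    "value": dph,
                    "nclx": nclx_d,
                    "effort": True,
                }
            )
    df.index.name = "bin"
    return DetectionSeries(pod, grouping, resolution, df)


def summary_totals(
    trains: pd.DataFrame, effort: tuple, clicks: pd.DataFrame | None = None, assign: str = "span"
) -> pd.DataFrame:
    """NClx / DPM / DPH / DPD totals for every quality grouping."""
    rows = []
    for gname, grouping in GROUPINGS.items():
        minute = aggregate_detections(trains, grouping, "minute", effort, clicks, assign)
        hour = aggregate_detections(trains, grouping, "hour", effort, clicks, assign)
        day = aggregate_detections(trains, grouping, "day", effort, clicks, assign)
        rows.append(
            {
                "pod_label": minute.pod_label,
                "grouping": gname,
                "NClx": minute.totals()["nclx"],
                "DPM": minute.totals()["positive_bins"],
                "DPH": hour.totals()["positive_bins"],
                "DPD": day.totals()["positive_bins"],
            }
        )
    return pd.DataFrame(rows)


def detection_rate(series: DetectionSeries, period: str = "season") -> pd.Series:
    """Effort-standardized percentage of positive bins per season/month:
    100 x positive bins / monitored bins.  Periods without effort are
    missing (never divided by zero)."""
    if period not in ("season", "month"):
        raise ValueError("period must be 'season' or 'month'")
    d = series.df[series.df["effort"]]
    if period == "month":
        key = pd.Index(d.index.month, name="month")
    else:
        key = pd.Index([SEASONS[m] for m in d.index.month], name="season")
    grp = d.groupby(key)
    rate = 100.0 * grp["detpos"].sum() / grp["detpos"].count()
    rate.name = f"{series.resolution}_rate_pct"
    return rate


def detection_ratio(det_f: float, det_c: float) -> float:
    """F/C detection ratio, NaN (with a warning) when the C count is 0."""
    if det_c == 0:
        warnings.warn("C-POD count is zero; detection ratio undefined", stacklevel=2)
        return float("nan")
    return float(det_f) / float(det_c)


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall tau-b with tie correction and its p-value.

    The p-value uses exact enumeration for n <= 8 without ties, otherwise
    the tie-corrected normal approximation (no continuity correction).
    All-constant input yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    ties = len(np.unique(x)) < len(x) or len(np.unique(y)) < len(y)
    method = "exact" if (len(x) <= 8 and not ties) else "asymptotic"
    res = scipy.stats.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


def match_positive_bins(series_a: DetectionSeries, series_b: DetectionSeries) -> dict:
    """Fraction of each pod's positive bins not positive on the other pod."""
    if series_a.resolution != series_b.resolution:
        raise ValueError("series resolutions differ")
    if series_a.grouping.name != series_b.grouping.name:
        raise ValueError("series groupings differ")
    if not series_a.df.index.equals(series_b.df.index):
        raise ValueError("effort periods differ")
    a = series_a.df["detpos"].to_numpy() > 0
    b = series_b.df["detpos"].to_numpy() > 0
    out = {}
    for label, own, other in ((series_a.pod_label, a, b), (series_b.pod_label, b, a)):
        n = int(own.sum())
        out[label] = float((own & ~other).sum() / n) if n else float("nan")
    return out


def validation_sample(
    trains: pd.DataFrame, effort: tuple, n_random: int = 100, seed: int = 0, assign: str = "span"
) -> pd.DataFrame:
    """Minutes to inspect for visual validation.

    ``n_random`` uniform Hi/Mod-positive minutes without replacement (all
    of them if fewer exist) plus every Lo-positive minute; deterministic
    for a fixed seed.  The judgment itself is left to the analyst.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    start, end = pd.Timestamp(effort[0]), pd.Timestamp(effort[1])
    himod = _positive_minutes(trains, GROUPINGS["HiMod"], assign)
    lo = _positive_minutes(trains, FilterGrouping("Lo", frozenset({"Lo"})), assign)
    himod = himod[(himod >= start) & (himod < end)]
    lo = lo[(lo >= start) & (lo < end)]
    if len(himod) > n_random:
        pick = np.sort(rng.choice(len(himod), size=n_random, replace=False))
        himod = himod[pick]
    parts = []
    if len(himod):
        parts.append(pd.DataFrame({"minute": himod, "component": "random_himod"}))
    if len(lo):
        parts.append(pd.DataFrame({"minute": lo, "component": "all_lo"}))
    if not parts:
        return pd.DataFrame(columns=["minute", "component"])
    return pd.concat(parts, ignore_index=True)


def comparison_summary(
    pods: dict,
    effort: tuple,
    clicks: dict | None = None,
    assign: str = "span",
) -> pd.DataFrame:
    """Metric x grouping comparison table for a C/F co-deployment.

    ``pods`` maps pod label -> trains DataFrame for exactly two pods; the
    first is the reference (denominator, C-like) and the second the
    comparison (numerator, F-like).  Rows carry totals, Kendall tau and
    p, the F/C ratio, and unmatched proportions per metric and grouping.
    """
    if len(pods) != 2:
        raise ValueError("need exactly two pods")
    (lab_c, trains_c), (lab_f, trains_f) = pods.items()
    clicks = clicks or {}
    rows = []
    for gname in GROUPINGS:
        for resolution, metric in (("minute", "DPM"), ("hour", "DPH"), ("day", "DPD")):
            sc = aggregate_detections(trains_c, gname, resolution, effort, clicks.get(lab_c), assign)
            sf = aggregate_detections(trains_f, gname, resolution, effort, clicks.get(lab_f), assign)
            tot_c, tot_f = sc.totals(), sf.totals()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tau, p = kendall_tau(sc.df["value"], sf.df["value"])
                ratio = detection_ratio(tot_f["positive_bins"], tot_c["positive_bins"])
            unmatched = match_positive_bins(sc, sf)
            rows.append(
                {
                    "metric": metric,
                    "grouping": gname,
                    f"total_{lab_c}": tot_c["positive_bins"],
                    f"total_{lab_f}": tot_f["positive_bins"],
                    f"nclx_{lab_c}": tot_c["nclx"],
                    f"nclx_{lab_f}": tot_f["nclx"],
                    "kendall_tau": tau,
                    "kendall_p": p,
                    "ratio_f_over_c": ratio,
                    f"unmatched_{lab_c}": unmatched[lab_c],
                    f"unmatched_{lab_f}": unmatched[lab_f],
                }
            )
    return pd.DataFrame(rows)
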