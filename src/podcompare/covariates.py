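"""Environmental covariates for the hourly modeling table.

Builds diel phase, tidal covariates (signed time to high water, tidal
phase, tidal range), pooled POD temperature, hourly noise proxy and season
from supplied sun and tide tables plus the per-minute POD summaries.  Sun
and tide tables are inputs (delimited text); synthetic generators are
provided so the whole pipeline runs without downloads.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from podcompare.simulate import M2_PERIOD_H

SEASONS = {
    1: "winter", 2: "winter", 3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer", 9: "autumn", 10: "autumn",
    11: "autumn", 12: "winter",
}

DIEL_PHASES = ("morning", "day", "evening", "night")


def season_of(month: int) -> str:
    """Season of a calendar month: spring Mar-May, summer Jun-Aug,
    autumn Sep-Nov, winter Dec-Feb."""
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month must be 1..12, got {month}")
    return SEASONS[int(month)]


# ---------------------------------------------------------------------------
# sun table
# ---------------------------------------------------------------------------


def validate_sun_table(sun: pd.DataFrame) -> pd.DataFrame:
    required = {"date", "civil_dawn", "sunrise", "sunset", "civil_dusk"}
    missing = required - set(sun.columns)
    if missing:
        raise ValueError(f"sun table missing columns: {sorted(missing)}")
    sun = sun.copy()
    sun["date"] = pd.to_datetime(sun["date"]).dt.normalize()
    for col in ("civil_dawn", "sunrise", "sunset", "civil_dusk"):
        sun[col] = pd.to_datetime(sun[col])
    bad = ~(
        (sun["civil_dawn"] < sun["sunrise"])
        & (sun["sunrise"] < sun["sunset"])
        & (sun["sunset"] < sun["civil_dusk"])
    )
    if bad.any():
        raise ValueError(f"sun table ordering violated on {int(bad.sum())} day(s)")
    return sun.set_index("date").sort_index()


def read_sun_table(path) -> pd.DataFrame:
    return validate_sun_table(pd.read_csv(path))


def make_sun_table(
    start_date,
    end_date,
    daylight_mean_h: float = 12.25,
    daylight_amplitude_h: float = 4.6,
    twilight_min: float = 40.0,
) -> pd.DataFrame:
    """Synthetic sun table with a sinusoidal seasonal daylight cycle.

    Defaults approximate ~51 deg N (about 17 h daylight at the June
    solstice, 7.7 h at the December one, ~40 min civil twilight).
    """
    days = pd.date_range(
        pd.Timestamp(start_date).normalize(), pd.Timestamp(end_date).normalize(), freq="D"
    )
    doy = days.dayofyear.to_numpy().astype(float)
    daylight = daylight_mean_h + daylight_amplitude_h * np.sin(2 * np.pi * (doy - 80.0) / 365.25)
    noon = days + pd.Timedelta(hours=12)
    half = pd.to_timedelta(daylight / 2.0, unit="h").round("s")
    tw = pd.Timedelta(minutes=twilight_min)
    sun = pd.DataFrame(
        {
            "date": days,
            "civil_dawn": noon - half - tw,
            "sunrise": noon - half,
            "sunset": noon + half,
            "civil_dusk": noon + half + tw,
        }
    )
    return validate_sun_table(sun)


def diel_period(
    times, sun: pd.DataFrame, morning_offset_h: float = 1.0, evening_offset_h: float = 1.0
):
    """Diel phase of each timestamp.

    Defaults: morning = [civil_dawn, sunrise + 1 h), day = [sunrise + 1 h,
    sunset - 1 h), evening = [sunset - 1 h, civil_dusk), night otherwise
    (civil dusk to the next civil dawn).  Offsets are configurable.
    """
    scalar = np.isscalar(times) or isinstance(times, (pd.Timestamp, str))
    idx = pd.DatetimeIndex([times]) if scalar else pd.DatetimeIndex(times)
    dates = idx.normalize()
    missing = ~dates.isin(sun.index)
    if missing.any():
        raise KeyError(f"sun table missing {dates[missing][0].date()}")
    day_rows = sun.loc[dates]
    t = idx.to_numpy()
    dawn = day_rows["civil_dawn"].to_numpy()
    sr1 = (day_rows["sunrise"] + pd.Timedelta(hours=morning_offset_h)).to_numpy()
    ss1 = (day_rows["sunset"] - pd.Timedelta(hours=evening_offset_h)).to_numpy()
    dusk = day_rows["civil_dusk"].to_numpy()
    phase = np.full(len(idx), "night", dtype=object)
    phase[(t >= dawn) & (t < sr1)] = "morning"
    phase[(t >= sr1) & (t < ss1)] = "day"
    phase[(t >= ss1) & (t < dusk)] = "evening"
    return phase[0] if scalar else phase


# ---------------------------------------------------------------------------
# tide table
# ---------------------------------------------------------------------------


def validate_tide_table(tide: pd.DataFrame) -> pd.DataFrame:
    required = {"datetime", "type", "height_m"}
    missing = required - set(tide.columns)
    if missing:
        raise ValueError(f"tide table missing columns: {sorted(missing)}")
    tide = tide.copy()
    tide["datetime"] = pd.to_datetime(tide["datetime"])
    tide = tide.sort_values("datetime").reset_index(drop=True)
    if tide["datetime"].duplicated().any():
        raise ValueError("tide event times must be strictly increasing")
    types = tide["type"].to_numpy()
    if not set(types) <= {"high", "low"}:
        raise ValueError("tide event type must be 'high' or 'low'")
    if len(types) > 1 and (types[1:] == types[:-1]).any():
        raise ValueError("tide events must alternate high/low")
    return tide


def read_tide_table(path) -> pd.DataFrame:
    return validate_tide_table(pd.read_csv(path))


def make_tide_table(
    start_date,
    end_date,
    mean_high_m: float = 3.2,
    mean_low_m: float = 0.9,
    spring_neap_amplitude_m: float = 0.7,
    first_high="2021-04-01 00:00:00",
) -> pd.DataFrame:
    """Synthetic semidiurnal tide table: alternating high/low water every
    half M2 period, heights modulated on the 14.77-day spring-neap cycle."""
    start = pd.Timestamp(start_date) - pd.Timedelta(hours=M2_PERIOD_H)
    end = pd.Timestamp(end_date) + pd.Timedelta(hours=M2_PERIOD_H)
    t0 = pd.Timestamp(first_high)
    half = pd.Timedelta(hours=M2_PERIOD_H / 2)
    k0 = int(np.floor((start - t0) / half)) - 1
    k1 = int(np.ceil((end - t0) / half)) + 1
    ks = np.arange(k0, k1 + 1)
    times = (t0 + pd.to_timedelta(ks * (M2_PERIOD_H / 2), unit="h")).round("s")
    is_high = ks % 2 == 0
    t_days = ((times - t0).total_seconds() / 86400.0).to_numpy()
    spring = spring_neap_amplitude_m * np.cos(2 * np.pi * t_days / 14.765)
    height = np.where(is_high, mean_high_m + spring, mean_low_m - spring * 0.6)
    tide = pd.DataFrame(
        {
            "datetime": times,
            "type": np.where(is_high, "high", "low"),
            "height_m": np.round(height, 2),
        }
    )
    return validate_tide_table(tide)


def tide_covariates(times, tide: pd.DataFrame, phase_window_h: float = 0.5):
    """Signed hours to the nearest high water, tidal phase, tidal range.

    diff < 0 before the nearest high water, > 0 after.  Phase is "high" /
    "low" within ``phase_window_h`` of the respective event, otherwise
    "flow" while rising (low -> high) and "ebb" while falling.  Tidal range
    is |height(nearest high) - height(adjacent low)| with the low on the
    same side of the high as the timestamp.
    """
    scalar = np.isscalar(times) or isinstance(times, (pd.Timestamp, str))
    idx = pd.DatetimeIndex([times]) if scalar else pd.DatetimeIndex(times)
    ev_t = tide["datetime"].to_numpy()
    ev_type = tide["type"].to_numpy()
    ev_h = tide["height_m"].to_numpy()
    t = idx.to_numpy()
    if len(t) and (t.min() < ev_t[0] or t.max() > ev_t[-1]):
        raise ValueError("timestamp outside tide table span")

    highs_i = np.flatnonzero(ev_type == "high")
    lows_i = np.flatnonzero(ev_type == "low")
    high_t = ev_t[highs_i]
    pos = np.searchsorted(high_t, t)
    prev_i = np.clip(pos - 1, 0, len(high_t) - 1)
    next_i = np.clip(pos, 0, len(high_t) - 1)
    d_prev = (t - high_t[prev_i]) / np.timedelta64(1, "h")
    d_next = (t - high_t[next_i]) / np.timedelta64(1, "h")
    use_prev = np.abs(d_prev) <= np.abs(d_next)
    near_high = np.where(use_prev, highs_i[prev_i], highs_i[next_i])
    diff_h = np.where(use_prev, d_prev, d_next)

    low_t = ev_t[lows_i]
    posl = np.searchsorted(low_t, t)
    prev_l = np.clip(posl - 1, 0, len(low_t) - 1)
    next_l = np.clip(posl, 0, len(low_t) - 1)
    dl_prev = (t - low_t[prev_l]) / np.timedelta64(1, "h")
    dl_next = (t - low_t[next_l]) / np.timedelta64(1, "h")
    use_prev_l = np.abs(dl_prev) <= np.abs(dl_next)
    diff_low_h = np.where(use_prev_l, dl_prev, dl_next)

    # rising toward the nearest high before it, falling after it
    phase = np.where(diff_h < 0, "flow", "ebb").astype(object)
    phase[np.abs(diff_low_h) <= phase_window_h] = "low"
    phase[np.abs(diff_h) <= phase_window_h] = "high"

    # adjacent low: the low event on the timestamp's side of the nearest high
    adj_low = np.where(
        diff_h < 0, np.maximum(near_high - 1, 0), np.minimum(near_high + 1, len(ev_t) - 1)
    )
    # guard deployment edges where the adjacent event is another high
    adj_is_low = ev_type[adj_low] == "low"
    other_side = np.where(
        diff_h < 0, np.minimum(near_high + 1, len(ev_t) - 1), np.maximum(near_high - 1, 0)
    )
    adj_low = np.where(adj_is_low, adj_low, other_side)
    rng = np.abs(ev_h[near_high] - ev_h[adj_low])

    if scalar:
        return float(diff_h[0]), str(phase[0]), float(rng[0])
    return diff_h, phase, rng


# ---------------------------------------------------------------------------
# POD-derived covariates
# ---------------------------------------------------------------------------


def pooled_temperature(temp_a: pd.Series, temp_b: pd.Series) -> pd.DataFrame:
    """Hourly mean of the two pods' hourly mean temperatures.

    POD temperature is relative, so pooling the co-deployed devices
    reduces per-device recording bias.  Hours covered by one pod only use
    that pod, flagged in ``single_pod``; hours with neither are missing.
    """
    a = temp_a.copy()
    b = temp_b.copy()
    a.index = pd.DatetimeIndex(a.index).floor("h")
    b.index = pd.DatetimeIndex(b.index).floor("h")
    ah = a.groupby(level=0).mean()
    bh = b.groupby(level=0).mean()
    df = pd.concat({"a": ah, "b": bh}, axis=1)
    out = pd.DataFrame(
        {
            "temperature_c": df.mean(axis=1, skipna=True),
            "single_pod": df.isna().any(axis=1) & ~df.isna().all(axis=1),
        }
    )
    out.index.name = "hour"
    return out


def hourly_nall(minute_nall: pd.Series, statistic: str = "mean") -> pd.Series:
    """Aggregate the per-minute Nall noise proxy to hours."""
    s = minute_nall.copy()
    s.index = pd.DatetimeIndex(s.index)
    grouped = s.groupby(s.index.floor("h"))
    if statistic == "mean":
        out = grouped.mean()
    elif statistic == "median":
        out = grouped.median()
    elif statistic == "sum":
        out = grouped.sum()
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    out.index.name = "hour"
    return out.rename("nall_hour")


def build_hour_covariates(
    hours: pd.DatetimeIndex,
    sun: pd.DataFrame,
    tide: pd.DataFrame,
    minutes_a: pd.DataFrame,
    minutes_b: pd.DataFrame | None = None,
    nall_statistic: str = "mean",
    diel_at: str = "midpoint",
) -> pd.DataFrame:
    """One covariate row per hour of the effort period.

    Every requested hour receives a row; covariates that cannot be
    computed stay missing (never silently dropped).  ``diel_at`` evaluates
    the diel phase at the hour midpoint (default) or start.
    """
    hours = pd.DatetimeIndex(hours)
    probe = hours + (pd.Timedelta(minutes=30) if diel_at == "midpoint" else pd.Timedelta(0))
    out = pd.DataFrame(index=hours)
    out.index.name = "hour"
    out["month"] = hours.month
    out["season"] = [SEASONS[m] for m in hours.month]
    out["diel_period"] = diel_period(probe, sun)
    diff_h, phase, rng = tide_covariates(probe, tide)
    out["diff_to_high_tide"] = diff_h
    out["tidal_phase"] = phase
    out["tidal_range"] = rng

    ta = minutes_a.set_index("minute")["temperature_c"]
    if minutes_b is not None:
        tb = minutes_b.set_index("minute")["temperature_c"]
        temp = pooled_temperature(ta, tb)
    else:
        temp = pooled_temperature(ta, ta)
        temp["single_pod"] = True
    out = out.join(temp.reindex(hours))

    na = hourly_nall(minutes_a.set_index("minute")["nall"], nall_statistic)
    out[f"nall_{minutes_a['pod_label'].iloc[0]}"] = na.reindex(hours)
    if minutes_b is not None:
        nb = hourly_nall(minutes_b.set_index("minute")["nall"], nall_statistic)
        out[f"nall_{minutes_b['pod_label'].iloc[0]}"] = nb.reindex(hours)
    return out
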