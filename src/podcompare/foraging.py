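"""Foraging-buzz classification from inter-click intervals.

Porpoise prey-capture attempts end in a terminal "buzz": click trains
whose inter-click interval (ICI) drops below 10 ms.  This module computes
ICIs, fits a univariate Gaussian mixture to log10(ICI) by EM, maps
mixture components to behavioral categories (buzz / regular echolocation /
inter-train pause), classifies clicks by maximum posterior, and aggregates
buzz-positive minutes (BPM), buzz-positive hours (BPH) and the hourly buzz
rate 100 x BPM/DPM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from podcompare.metrics import DetectionSeries

BUZZ_THRESHOLD_MS = 10.0
BUZZ_THRESHOLD_LOG10 = np.log10(BUZZ_THRESHOLD_MS)


def compute_icis(clicks: pd.DataFrame) -> pd.DataFrame:
    """ICI samples from a time-sorted click table.

    One sample per successive within-train click pair (``kind="within"``)
    plus one candidate inter-train sample per gap between a train's last
    click and the next train's first click on the same pod
    (``kind="intertrain"``).  Duplicate timestamps within a train raise.
    """
    if len(clicks) == 0:
        return pd.DataFrame(columns=["pod_label", "train_id", "time", "ici_ms", "log10_ici", "kind"])
    out = []
    for pod, cl in clicks.groupby("pod_label", sort=True):
        cl = cl.sort_values("time", kind="stable")
        # within-train
        by_train = cl.sort_values(["train_id", "time"], kind="stable")
        t_us = by_train["time"].to_numpy().astype("datetime64[us]").astype(np.int64)
        same = np.concatenate(
            ([False], by_train["train_id"].to_numpy()[1:] == by_train["train_id"].to_numpy()[:-1])
        )
        d_ms = np.concatenate(([0], np.diff(t_us))) / 1000.0
        if np.any(same & (d_ms <= 0)):
            raise ValueError("duplicate timestamps within a train")
        within = pd.DataFrame(
            {
                "pod_label": pod,
                "train_id": by_train["train_id"].to_numpy()[same],
                "time": by_train["time"].to_numpy()[same],
                "ici_ms": d_ms[same],
                "kind": "within",
            }
        )
        out.append(within)
        # inter-train gaps in chronological train order
        firsts = cl.groupby("train_id", sort=False).first().sort_values("time")
        lasts = cl.groupby("train_id", sort=False).last().sort_values("time")
        if len(firsts) > 1:
            gap_ms = (
                firsts["time"].to_numpy()[1:] - lasts["time"].to_numpy()[:-1]
            ) / np.timedelta64(1, "ms")
            ok = gap_ms > 0  # overlapping trains yield no usable gap
            out.append(
                pd.DataFrame(
                    {
                        "pod_label": pod,
                        "train_id": firsts.index.to_numpy()[1:][ok],
                        "time": firsts["time"].to_numpy()[1:][ok],
                        "ici_ms": gap_ms[ok],
                        "kind": "intertrain",
                    }
                )
            )
    res = pd.concat(out, ignore_index=True)
    res["log10_ici"] = np.log10(res["ici_ms"])
    return res[["pod_label", "train_id", "time", "ici_ms", "log10_ici", "kind"]]


@dataclass
class ICIMixtureFit:
    """A fitted univariate Gaussian mixture on log10(ICI) in ms.

    Components are sorted by mean.  ``labels[k]`` maps component k to a
    behavior: every component whose mean ICI is below 10 ms is "buzz", the
    largest-mean component is "inter-train" (unless it is itself a buzz
    component), the rest are "regular".
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    labels: tuple
    log_likelihood: float
    bic: float
    n_iterations: int
    converged: bool
    loglik_trace: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "labels": list(self.labels),
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }


def _component_labels(means: np.ndarray) -> tuple:
    labels = ["regular"] * len(means)
    for i, m in enumerate(means):
        if m < BUZZ_THRESHOLD_LOG10:
            labels[i] = "buzz"
    top = int(np.argmax(means))
    if labels[top] != "buzz" and len(means) > 1:
        labels[top] = "inter-train"
    return tuple(labels)


def _em_once(
    x: np.ndarray, k: int, rng: np.random.Generator, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool, np.ndarray]:
    n = len(x)
    # init: random data points as means, pooled sd
    means = rng.choice(x, size=k, replace=False).astype(float)
    sds = np.full(k, x.std() / k + 1e-3)
    weights = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step in log space
        log_comp = (
            np.log(weights)[:, None]
            - 0.5 * np.log(2 * np.pi)
            - np.log(sds)[:, None]
            - 0.5 * ((x[None, :] - means[:, None]) / sds[:, None]) ** 2
        )
        log_norm = logsumexp(log_comp, axis=0)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_comp - log_norm[None, :])
        # M step
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-10):  # dead component: restart with jitter
            dead = nk < 1e-10
            means[dead] = rng.choice(x, size=int(dead.sum()))
            sds[dead] = x.std()
            weights = np.full(k, 1.0 / k)
            prev_ll = -np.inf
            trace.clear()
            continue
        weights = nk / n
        means = resp @ x / nk
        var = (resp * (x[None, :] - means[:, None]) ** 2).sum(axis=1) / nk
        if np.any(var < 1e-12):  # degenerate sd: jitter and continue
            var = np.maximum(var, 1e-6)
            means[var <= 1e-6] += rng.normal(0, 0.01, size=int((var <= 1e-6).sum()))
        sds = np.sqrt(var)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
    order = np.argsort(means)
    return weights[order], means[order], sds[order], ll, it, converged, np.array(trace)


def fit_ici_mixture(
    samples,
    k_candidates=(2, 3, 4),
    seed: int = 0,
    n_starts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 500,
    include_intertrain: bool = True,
    max_samples: int = 50_000,
) -> ICIMixtureFit:
    """EM-fit Gaussian mixtures on log10(ICI) and select K by BIC.

    ``samples`` is the frame from :func:`compute_icis` or any object with
    a ``log10_ici`` column / a 1-D array of log10 values.  Each candidate
    K gets ``n_starts`` random restarts with a fixed seed; the best
    (highest-likelihood) converged start represents K and the
    BIC-minimizing K wins.  Non-convergence in every start yields a
    flagged fit (``converged=False``), not an exception.
    """
    if isinstance(samples, pd.DataFrame):
        df = samples if include_intertrain else samples[samples["kind"] == "within"]
        x = df["log10_ici"].to_numpy(dtype=float)
    else:
        x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if max_samples and len(x) > max_samples:
        # parameter recovery saturates well below this; subsample for speed
        x = np.random.default_rng((seed, 997)).choice(x, size=max_samples, replace=False)
    kmax = max(k_candidates)
    if len(x) < 10 * kmax:
        raise ValueError(f"need >= {10 * kmax} samples for k up to {kmax}, got {len(x)}")

    best: ICIMixtureFit | None = None
    for k in sorted(k_candidates):
        rng = np.random.default_rng((seed, k))
        k_best = None
        for _ in range(n_starts):
            w, m, s, ll, it, conv, trace = _em_once(x, k, rng, tol, max_iter)
            if k_best is None or ll > k_best[3] or (conv and not k_best[5]):
                k_best = (w, m, s, ll, it, conv, trace)
        w, m, s, ll, it, conv, trace = k_best
        n_params = 3 * k - 1
        bic = n_params * np.log(len(x)) - 2.0 * ll
        fit = ICIMixtureFit(
            k=k,
            weights=w,
            means=m,
            sds=s,
            labels=_component_labels(m),
            log_likelihood=ll,
            bic=float(bic),
            n_iterations=it,
            converged=conv,
            loglik_trace=trace,
        )
        if best is None or fit.bic < best.bic:
            best = fit
    return best


def posterior_probs(fit: ICIMixtureFit, log10_ici: np.ndarray) -> np.ndarray:
    """(n, k) posterior component membership probabilities."""
    x = np.asarray(log10_ici, dtype=float)
    log_comp = (
        np.log(fit.weights)[:, None]
        - 0.5 * np.log(2 * np.pi)
        - np.log(fit.sds)[:, None]
        - 0.5 * ((x[None, :] - fit.means[:, None]) / fit.sds[:, None]) ** 2
    )
    return np.exp(log_comp - logsumexp(log_comp, axis=0)[None, :]).T


def classify_clicks(fit: ICIMixtureFit, samples) -> pd.DataFrame:
    """Maximum-posterior behavior label per ICI sample.

    Posterior ties break toward the lower-mean component (components are
    mean-sorted, so ``argmax`` on the first maximal entry does this).
    Thresholding at 10 ms directly is available via
    :func:`classify_clicks_threshold` as a cross-check.
    """
    if isinstance(samples, pd.DataFrame):
        x = samples["log10_ici"].to_numpy(dtype=float)
        out = samples.copy()
    else:
        x = np.asarray(samples, dtype=float)
        out = pd.DataFrame({"log10_ici": x})
    if len(x) == 0:
        out["behavior"] = pd.Series(dtype=object)
        return out
    post = posterior_probs(fit, x)
    comp = post.argmax(axis=1)
    out["behavior"] = [fit.labels[c] for c in comp]
    out["posterior"] = post[np.arange(len(x)), comp]
    return out


def classify_clicks_threshold(samples) -> pd.DataFrame:
    """Pure-threshold fallback: buzz iff ICI < 10 ms."""
    out = samples.copy()
    out["behavior"] = np.where(out["ici_ms"] < BUZZ_THRESHOLD_MS, "buzz", "regular")
    return out


@dataclass
class BuzzSeries:
    """Hourly BPM and buzz rate plus daily BPH for one pod/grouping."""

    pod_label: str
    grouping_name: str
    hourly: pd.DataFrame  # index hour: bpm, dpm, buzz_rate (NaN when dpm=0)
    daily: pd.DataFrame  # index day: bph


def buzz_series(
    labeled: pd.DataFrame, dpm_hourly: DetectionSeries, grouping_name: str | None = None
) -> BuzzSeries:
    """Aggregate buzz-labeled ICI samples against the DPM series.

    A minute is buzz-positive iff >= 1 buzz-labeled sample falls in it;
    buzz rate per hour is 100 x BPM/DPM, missing (not zero) when DPM = 0;
    BPH counts hours of a day with >= 1 buzz-positive minute.  BPM
    exceeding DPM in any hour indicates inconsistent inputs and raises.
    """
    if dpm_hourly.resolution != "hour":
        raise ValueError("dpm_hourly must be an hourly DetectionSeries")
    hours = dpm_hourly.df.index
    buz = labeled[labeled["behavior"] == "buzz"]
    if len(buz):
        bmin = pd.DatetimeIndex(pd.to_datetime(buz["time"])).floor("min").unique()
        bpm = (
            pd.Series(1, index=bmin).groupby(bmin.floor("h")).sum().reindex(hours, fill_value=0)
        )
    else:
        bpm = pd.Series(0, index=hours)
    dpm = dpm_hourly.df["value"]
    if (bpm > dpm).any():
        raise ValueError("BPM exceeds DPM in some hour: labels and DPM series disagree")
    rate = pd.Series(np.where(dpm > 0, 100.0 * bpm / dpm.replace(0, np.nan), np.nan), index=hours)
    hourly = pd.DataFrame({"bpm": bpm, "dpm": dpm, "buzz_rate": rate})
    hourly.index.name = "hour"
    bph = (bpm > 0).groupby(hours.floor("D")).sum().astype(int)
    daily = pd.DataFrame({"bph": bph})
    daily.index.name = "day"
    return BuzzSeries(
        dpm_hourly.pod_label,
        grouping_name or dpm_hourly.grouping.name,
        hourly,
        daily,
    )
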