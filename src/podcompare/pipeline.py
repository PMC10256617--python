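"""End-to-end orchestration of the co-deployment comparison.

A scenario config (YAML or dict) describes the deployment window, the
occupancy and click-train generators and the two detector profiles.
:func:`run_pipeline` executes the requested stages in dependency order —
simulate, metrics, foraging, covariates, model, compare — writing every
artifact under one output directory together with a JSON manifest (inputs,
outputs, per-stage seeds and timings).  Runs are deterministic for a fixed
global seed: each stage derives its own seed by a documented counter
scheme, so re-running a single stage reproduces its outputs exactly.

The numbered scripts under ``analysis/`` are thin drivers over this
module; together they are the command-line surface of the package.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import time
import warnings

import numpy as np
import pandas as pd
import yaml

from podcompare import covariates as cov
from podcompare import foraging as forg
from podcompare import metrics as metr
from podcompare import simulate as sim
from podcompare import tempmodel as tm

STAGES = ("simulate", "metrics", "foraging", "covariates", "model", "compare")

#: dependency closure: artifacts each stage needs from earlier ones
_REQUIRES = {
    "simulate": (),
    "metrics": ("simulate",),
    "foraging": ("simulate",),
    "covariates": ("simulate",),
    "model": ("simulate", "metrics", "foraging", "covariates"),
    "compare": ("simulate", "metrics", "foraging"),
}


def stage_seed(base_seed: int, stage: str) -> int:
    """Per-stage seed: (base * 100003 + stage index) mod 2^31."""
    return (int(base_seed) * 100003 + STAGES.index(stage)) % 2**31


def demo_scenario(n_days: int = 120, start: str = "2021-04-01") -> dict:
    """A two-pod co-deployment scenario with the package defaults: a
    C-like and an F-like detector observing the same occupancy truth."""
    start_ts = pd.Timestamp(start)
    end_ts = start_ts + pd.Timedelta(days=n_days)
    return {
        "occupancy": {
            "start_date": str(start_ts.date()),
            "end_date": str(end_ts.date()),
        },
        "trains": {},
        "detectors": [
            {"kind": "c_like"},
            {"kind": "f_like"},
        ],
    }


def load_scenario(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _build_profiles(config: dict) -> list[sim.DetectorProfile]:
    profiles = []
    for d in config.get("detectors", [{"kind": "c_like"}, {"kind": "f_like"}]):
        d = dict(d)
        kind = d.pop("kind", "c_like")
        maker = sim.profile_f_like if kind == "f_like" else sim.profile_c_like
        profiles.append(maker(**d))
    return profiles


class MissingStageError(RuntimeError):
    pass


def _need(outdir: pathlib.Path, relpath: str, stage: str, needed_by: str):
    p = outdir / relpath
    if not p.exists():
        raise MissingStageError(
            f"stage '{needed_by}' needs {relpath}; run stage '{stage}' first"
        )
    return p


def run_pipeline(config, outdir, seed: int = 1, stages=None) -> dict:
    """Execute the requested pipeline stages; returns the manifest."""
    if isinstance(config, (str, pathlib.Path)):
        config = load_scenario(config)
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = {
        "seed": int(seed),
        "config": config,
        "stages": {},
        "versions": {"podcompare": __import__("podcompare").__version__},
    }
    occ = sim.OccupancyParams(**config.get("occupancy", {}))
    trains_p = sim.TrainParams(**config.get("trains", {}))
    profiles = _build_profiles(config)
    effort = (occ.start, occ.end)

    for stage in stages:
        t0 = time.time()
        s_seed = stage_seed(seed, stage)
        if stage == "simulate":
            _run_simulate(outdir, occ, trains_p, profiles, s_seed)
        elif stage == "metrics":
            _need(outdir, f"pod_{profiles[0].pod_label}/trains.csv", "simulate", stage)
            _run_metrics(outdir, profiles, effort)
        elif stage == "foraging":
            _need(outdir, f"pod_{profiles[0].pod_label}/clicks.csv", "simulate", stage)
            _run_foraging(outdir, profiles, effort, s_seed)
        elif stage == "covariates":
            _need(outdir, f"pod_{profiles[0].pod_label}/minutes.csv", "simulate", stage)
            _run_covariates(outdir, profiles, occ)
        elif stage == "model":
            _need(outdir, "covariates/hourly.csv", "covariates", stage)
            _need(outdir, f"foraging/buzz_hourly_{profiles[0].pod_label}.csv", "foraging", stage)
            _run_model(outdir, profiles, effort)
        elif stage == "compare":
            _need(outdir, "metrics/comparison_summary.csv", "metrics", stage)
            compare_report(outdir, profiles)
        manifest["stages"][stage] = {
            "seed": s_seed,
            "seconds": round(time.time() - t0, 2),
        }

    manifest["outputs"] = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _run_simulate(outdir, occ, trains_p, profiles, s_seed):
    sun = cov.make_sun_table(occ.start, occ.end)
    tide = cov.make_tide_table(occ.start, occ.end, first_high=str(occ.start))
    diel_lookup = lambda t: cov.diel_period(t, sun)
    tide_lookup = lambda t: cov.tide_covariates(t, tide)[0]
    enc = sim.simulate_occupancy(occ, s_seed, diel_lookup, tide_lookup)
    truth = sim.simulate_click_trains(enc, trains_p, s_seed + 1, params_occ=occ)
    for i, prof in enumerate(profiles):
        pod = sim.apply_detector(truth, prof, s_seed + 2 + i)
        sim.write_pod_export(pod, outdir / f"pod_{prof.pod_label}")
    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    enc.to_csv(tdir / "encounters.csv", index=False)
    truth.minutes.to_csv(tdir / "minutes.csv")
    truth.clicks.assign(time=truth.clicks["time"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")).to_csv(
        tdir / "clicks.csv", index=False
    )
    sun.reset_index().to_csv(tdir / "sun_table.csv", index=False)
    tide.to_csv(tdir / "tide_table.csv", index=False)


def _read_pods(outdir, profiles):
    return {p.pod_label: sim.read_pod_export(outdir / f"pod_{p.pod_label}") for p in profiles}


def _run_metrics(outdir, profiles, effort):
    pods = _read_pods(outdir, profiles)
    mdir = outdir / "metrics"
    mdir.mkdir(exist_ok=True)
    tidy = []
    for label, pod in pods.items():
        for gname in metr.GROUPINGS:
            for resolution in metr.RESOLUTIONS:
                s = metr.aggregate_detections(
                    pod.trains, gname, resolution, effort, pod.clicks, clip=True
                )
                df = s.df.reset_index()
                df.insert(0, "pod", label)
                df.insert(1, "grouping", gname)
                df.insert(2, "resolution", resolution)
                tidy.append(df)
        hour_series = metr.aggregate_detections(
            pod.trains, "HiModLo", "minute", effort, pod.clicks, clip=True
        )
        metr.detection_rate(hour_series, "season").to_csv(mdir / f"dpm_rate_season_{label}.csv")
        metr.detection_rate(hour_series, "month").to_csv(mdir / f"dpm_rate_month_{label}.csv")
    pd.concat(tidy, ignore_index=True).to_csv(mdir / "detection_series.csv", index=False)
    labels = list(pods)
    comparison = metr.comparison_summary(
        {lab: pods[lab].trains for lab in labels},
        effort,
        {lab: pods[lab].clicks for lab in labels},
    )
    comparison.to_csv(mdir / "comparison_summary.csv", index=False)
    pd.concat(
        [metr.summary_totals(pods[lab].trains, effort, pods[lab].clicks) for lab in labels],
        ignore_index=True,
    ).to_csv(mdir / "summary_totals.csv", index=False)


def _run_foraging(outdir, profiles, effort, s_seed):
    pods = _read_pods(outdir, profiles)
    fdir = outdir / "foraging"
    fdir.mkdir(exist_ok=True)
    for label, pod in pods.items():
        icis = forg.compute_icis(pod.clicks)
        fit = forg.fit_ici_mixture(icis, seed=s_seed)
        with open(fdir / f"mixture_{label}.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=2)
        labeled = forg.classify_clicks(fit, icis[icis["kind"] == "within"])
        labeled.assign(time=pd.to_datetime(labeled["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")).to_csv(
            fdir / f"labels_{label}.csv", index=False
        )
        dpm_h = metr.aggregate_detections(
            pod.trains, "HiModLo", "hour", effort, pod.clicks, clip=True
        )
        bs = forg.buzz_series(labeled, dpm_h)
        bs.hourly.to_csv(fdir / f"buzz_hourly_{label}.csv")
        bs.daily.to_csv(fdir / f"buzz_daily_{label}.csv")


def _run_covariates(outdir, profiles, occ):
    pods = _read_pods(outdir, profiles)
    sun = cov.read_sun_table(outdir / "truth" / "sun_table.csv")
    tide = cov.read_tide_table(outdir / "truth" / "tide_table.csv")
    hours = pd.date_range(occ.start, occ.end, freq="h", inclusive="left")
    labels = list(pods)
    hourly = cov.build_hour_covariates(
        hours, sun, tide, pods[labels[0]].minutes, pods[labels[1]].minutes
    )
    cdir = outdir / "covariates"
    cdir.mkdir(exist_ok=True)
    hourly.to_csv(cdir / "hourly.csv")


def _run_model(outdir, profiles, effort):
    pods = _read_pods(outdir, profiles)
    hourly_cov = pd.read_csv(outdir / "covariates" / "hourly.csv", index_col=0, parse_dates=[0])
    mdir = outdir / "model"
    mdir.mkdir(exist_ok=True)
    for label, pod in pods.items():
        dpm_h = metr.aggregate_detections(
            pod.trains, "HiModLo", "hour", effort, pod.clicks, clip=True
        )
        buzz_hourly = pd.read_csv(
            outdir / "foraging" / f"buzz_hourly_{label}.csv", index_col=0, parse_dates=[0]
        )
        table = tm.build_hourly_table(dpm_h, hourly_cov, buzz_hourly, nall_col=f"nall_{label}")
        table.to_csv(mdir / f"hourly_table_{label}.csv")
        for resp_name, spec in (
            ("occurrence", tm.occurrence_spec()),
            ("foraging", tm.buzz_spec()),
        ):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = tm.fit_additive_model(table, spec)
                eff = tm.effect_table(fit)
                conc = tm.concurvity(fit)
                auc = tm.model_auc(fit)
            eff.to_csv(mdir / f"effects_{resp_name}_{label}.csv")
            meta = fit.metadata()
            meta["auc"] = auc
            meta["concurvity"] = conc.to_dict()
            with open(mdir / f"fit_{resp_name}_{label}.json", "w") as fh:
                json.dump(meta, fh, indent=2, default=float)
            curves = {}
            for b in fit.blocks:
                if b.kind == "smooth":
                    grid = np.linspace(b.xmin, b.xmax, 101)
                    curves[f"{b.name}_x"] = grid
                    curves[f"{b.name}_f"] = fit.predict_smooth(b.name, grid)
            pd.DataFrame(curves).to_csv(mdir / f"smooths_{resp_name}_{label}.csv", index=False)


def compare_report(outdir, profiles=None) -> dict:
    """Collate the per-stage outputs into one comparison report:
    per-filter totals and rates, Kendall agreement, overall and seasonal
    detection ratios, buzz summaries and side-by-side effect tables.
    Writes CSVs and figures under ``<outdir>/report`` and returns the
    headline numbers as a dict."""
    outdir = pathlib.Path(outdir)
    rdir = outdir / "report"
    rdir.mkdir(exist_ok=True)
    comparison = pd.read_csv(outdir / "metrics" / "comparison_summary.csv")
    comparison.to_csv(rdir / "comparison_summary.csv", index=False)
    labels = [c.split("_", 1)[1] for c in comparison.columns if c.startswith("total_")]
    lab_c, lab_f = labels[0], labels[1]

    season_rates = {}
    for lab in labels:
        p = outdir / "metrics" / f"dpm_rate_season_{lab}.csv"
        if p.exists():
            season_rates[lab] = pd.read_csv(p, index_col=0).iloc[:, 0]
    seasonal = pd.DataFrame(season_rates)
    if not seasonal.empty:
        seasonal["ratio"] = seasonal[lab_f] / seasonal[lab_c]
        seasonal.to_csv(rdir / "seasonal_dpm_rates.csv")

    headline = {}
    row = comparison[(comparison.metric == "DPH") & (comparison.grouping == "HiModLo")].iloc[0]
    headline["dph_ratio_himodlo"] = float(row["ratio_f_over_c"])
    row = comparison[(comparison.metric == "DPM") & (comparison.grouping == "HiModLo")].iloc[0]
    headline["dpm_c_over_f_pct"] = 100.0 * row[f"total_{lab_c}"] / max(row[f"total_{lab_f}"], 1)
    row = comparison[(comparison.metric == "DPH") & (comparison.grouping == "Hi")].iloc[0]
    headline["hi_dph_unmatched_f_pct"] = 100.0 * float(row[f"unmatched_{lab_f}"])

    # buzz summaries
    buzz = {}
    for lab in labels:
        p = outdir / "foraging" / f"buzz_hourly_{lab}.csv"
        if p.exists():
            bh = pd.read_csv(p, index_col=0, parse_dates=[0])
            buzz[lab] = {
                "bpm_total": int(bh["bpm"].sum()),
                "mean_buzz_rate": float(bh["buzz_rate"].mean()),
            }
    if buzz:
        pd.DataFrame(buzz).to_csv(rdir / "buzz_summary.csv")

    # side-by-side effect tables when the model stage has run
    for resp in ("occurrence", "foraging"):
        paths = {lab: outdir / "model" / f"effects_{resp}_{lab}.csv" for lab in labels}
        if all(p.exists() for p in paths.values()):
            eff = {lab: pd.read_csv(p, index_col=0) for lab, p in paths.items()}
            side = pd.concat(eff, axis=1)
            side.to_csv(rdir / f"effects_{resp}_side_by_side.csv")

    _figures(outdir, rdir, labels)
    with open(rdir / "headline.json", "w") as fh:
        json.dump(headline, fh, indent=2)
    return headline


def _figures(outdir, rdir, labels):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for lab in labels:
        p = outdir / "metrics" / f"dpm_rate_month_{lab}.csv"
        if p.exists():
            s = pd.read_csv(p, index_col=0).iloc[:, 0]
            ax.plot(s.index, s.values, marker="o", label=f"POD {lab}")
    ax.set_xlabel("month")
    ax.set_ylabel("DPM rate (% of monitored minutes)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(rdir / "monthly_dpm_rate.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    for lab in labels:
        p = outdir / "foraging" / f"buzz_daily_{lab}.csv"
        if p.exists():
            s = pd.read_csv(p, index_col=0, parse_dates=[0])["bph"]
            ax.plot(s.index, s.rolling(14, min_periods=1).mean(), label=f"POD {lab}")
    ax.set_xlabel("date")
    ax.set_ylabel("buzz-positive hours/day (14-day mean)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(rdir / "daily_bph.png", dpi=120)
    plt.close(fig)
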