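# podcompare

Passive acoustic monitoring of harbor porpoise (*Phocoena phocoena*)
relies on autonomous echolocation click loggers. The C-POD and its
successor, the F-POD, are routinely co-deployed when monitoring programs
transition hardware, and the question every such program faces is whether
the two devices tell the same ecological story: do detection-positive
minutes/hours/days (DPM/DPH/DPD) agree, is there a stable conversion
ratio, and do models of occurrence and foraging driven by the two data
streams recover the same environmental relationships?

`podcompare` is an analysis pipeline for exactly this dual-detector
comparison, built around a synthetic-data generator with known ground
truth so every stage is testable without field data:

- **simulate** — an inhomogeneous encounter process (seasonal, diel and
  tidal modulation of the log-rate), click trains with regular
  (ICI ≈ 60 ms) and foraging-buzz (ICI < 10 ms) regimes, a shared
  lognormal-AR(1) ambient noise field (the per-minute `Nall` click-event
  count), and two co-located detectors that thin clicks independently with
  probability `logistic(logit(p_click) + noise_slope·z(Nall) + amp)`,
  where `amp` is a per-train/per-encounter detectability offset shared by
  the co-located devices. Trains are quality-labeled Hi/Mod/Lo by
  completeness; false-positive trains are injected at a configurable rate.
- **metrics** — NClx, DPM, DPH, DPD under the nested Hi ⊂ HiMod ⊂ HiModLo
  quality filters; effort-standardized detection rates
  (100 × positive/monitored bins); the detection ratio `CF = Det_F/Det_C`;
  Kendall tau-b agreement between pods; matched/unmatched positive-bin
  proportions; a validation subsample helper (n random Hi/Mod minutes plus
  every Lo minute).
- **foraging** — inter-click intervals, a hand-written EM fit of a
  univariate Gaussian mixture on log10(ICI) with BIC model selection,
  component-to-behavior mapping (mean ICI < 10 ms ⇒ buzz, largest mean ⇒
  inter-train pause, rest regular), and the buzz series: BPM, daily BPH,
  and the hourly buzz rate 100 × BPM/DPM.
- **covariates** — diel phase from a sun table (morning/day/evening/night
  around civil twilight), signed time to nearest high water, tidal phase
  and range from a tide table, pooled two-pod temperature, hourly Nall.
- **tempmodel** — negative-binomial additive models with log link for the
  hourly responses (DPM per hour 0–60; buzz counts with a log(DPM)
  offset): cyclic P-spline smooths for month and time-to-high-water,
  shrinkage smooths (mgcv `ts`-style null-space penalization) for
  temperature, noise and tidal range, a diel factor (reference "day"),
  smoothing parameters by a Laplace REML-type criterion with penalty
  inflation γ = 1.2, AR(1) residual structure by within-block whitening at
  ρ estimated from the ACF of the ρ = 0 fit, θ by profile likelihood.
  Reported per model: per-term p-values and effect sizes (F-like for
  smooths, t for factor levels) with signs, AIC, % deviance explained,
  AUC of presence vs the predicted probability of a nonzero count, and
  per-term concurvity.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
444-day synthetic co-deployment (or any `--days`):

```
python analysis/01_simulate.py          --out results/run --seed 1
python analysis/02_detection_metrics.py --out results/run --seed 1
python analysis/03_classify_buzzes.py   --out results/run --seed 1
python analysis/04_covariates.py        --out results/run --seed 1
python analysis/05_fit_models.py        --out results/run --seed 1
python analysis/06_compare.py           --out results/run --seed 1
```

On the default 444-day scenario with seed 1 the pipeline reports, among
other things:

```
dpm_c_pct_of_f_himodlo        72.0   # C-POD records 72% of F-POD DPM
dpm_rate_ratio_winter          1.35  # seasonal F/C DPM-rate ratios 1.35-1.42
unmatched_f_dph_hi_pct        37.0   # Hi-filter: 37% of F DPH unseen by C
kendall_tau_dph_himodlo        0.89  # strong rank agreement at hourly scale
buzz_click_pct_c / _f          8.4 / 9.5
night_tvalue_c / _f           -4.1 / -4.3   # fewer detections at night
month_smooth_corr_c_vs_f       0.9997       # same seasonal shape from both pods
```

Reading: the F-like device detects substantially more minutes (the gap
widening under stricter quality filters), yet the two pods' additive
models recover nearly identical seasonal and diel structure — device
sensitivity changes the amount of data, not the ecological signal — while
buzz-click percentages show the sensitivity gap propagating into foraging
metrics.

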