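# Methods

This note documents the models behind `podcompare`, the defaults and why,
the numerical choices, and what the synthetic data can and cannot show.

## Synthetic co-deployment

**Occupancy.** Encounters arrive as an inhomogeneous Poisson process with
log-rate

    log λ(t) = log λ0 + a_m cos(2π (doy − peak)/365.25)
             + log d(phase(t)) + a_t cos(2π Δhigh(t)/12.4206)

thinned against an upper bound, with exponential encounter durations and
overlapping intervals merged. Defaults: λ0 = 0.12 h⁻¹, a_m = 0.7 with a
mid-January peak (detections highest in winter, lowest in early summer),
diel multipliers (morning 0.9, day 1.0, evening 0.8, night 0.6),
a_t = 0.25, mean duration 10 min, 444-day deployment starting 1 April.
The exponential-cosine form keeps multipliers positive and makes the
log-rate sinusoidal — precisely the structure the downstream additive
models assume, so covariate-recovery tests are well-posed.

**Click trains.** Within an encounter, trains alternate with lognormal
inter-train gaps (log10 mean 4.0 ≈ 10 s, sd 0.3). A train is a buzz train
with probability 0.1, otherwise regular; successive ICIs are lognormal on
the log10-ms scale (regular: mean 1.78 ≈ 60 ms; buzz: mean 0.70 ≈ 5 ms;
both sd 0.15). Clicks per train follow a shifted geometric (mean 14,
minimum 2), giving the heavy right tail of short weak trains seen in real
exports. Every click carries its behavior label.

**Detectability heterogeneity.** Each train carries a log-odds
detectability offset `amp = N(0, 1.0) + N(0, 1.5)` (train-level: source
level and beam orientation; encounter-level: range of the animal to the
mooring). The offset is a property of the sound field, so it is shared by
the co-located detectors. Without it, any two detectors saturate the same
minutes whenever several trains occur per minute, and co-deployed devices
could never disagree at the DPM scale the way real C/F pairs do; with it,
whole weak encounters are visible only to the more sensitive device.
Setting `amplitude_sd = encounter_amplitude_sd = 0` recovers pure
binomial thinning (used by the calibration tests).

**Observation model.** A click in a minute with standardized log-Nall z is
detected independently with probability
`logistic(logit(p_click) + noise_slope·z + amplitude_coef·amp)`.
Detected clicks of one true train form one detected train when at least
`min_clicks_train` (default 4) survive; quality (Hi/Mod/Lo) is drawn from
a categorical table keyed on completeness, with the F-like profile's
table skewed toward Hi. False-positive trains are Poisson-injected
(C-like 0.01 h⁻¹, F-like 0.004 h⁻¹ — roughly 1–2% of detected trains,
the magnitude reported for validated field data), default to Lo-heavy
quality, and are labeled `false` in truth. Profiles: C-like p_click 0.30,
noise_slope −0.8; F-like p_click 0.75, noise_slope −0.15. These were
chosen once as a realistic sensitivity gap; all comparison numbers are
emergent, not calibrated.

**Noise and temperature.** Per-minute Nall is a lognormal AR(1) series
(log-sd 0.8, lag-1 0.97 — slowly varying sea state) plus the NBHF clicks
emitted that minute; both pods share it. Temperature is a seasonal
sinusoid (11.5 ± 3.5 °C, March minimum) sampled hourly per pod with small
noise; the covariate stage pools the two pods' hourly means.

**What the generator does not emulate.** Waveforms and propagation;
classifier-specific train segmentation (true train boundaries are known);
inter-device clock drift; memory/duty-cycle limits; animal movement
within an encounter. Passing tests therefore demonstrate the pipeline's
statistical machinery, not field performance of any device.

## Detection metrics

A minute is detection-positive if at least one train of the quality
grouping overlaps it; by default a train occupies every minute from its
first to its last click (`assign="span"`), with a documented
start-minute-only toggle for comparisons against exports that assign
trains to their start minute. Hours count positive minutes (0–60), days
count positive hours (0–24); effort is explicit and unmonitored bins
never enter denominators. Detection rates standardize by effort:
100 × positive/monitored bins per season (spring = Mar–May,
summer = Jun–Aug, autumn = Sep–Nov, winter = Dec–Feb) or month. Kendall
tau-b (tie-corrected) comes from scipy, with exact enumeration for n ≤ 8
without ties and the tie-corrected normal approximation otherwise (no
continuity correction); the test suite checks it against an O(n²)
pair-counting oracle. The detection ratio Det_F/Det_C is undefined (NaN
with a warning) when the denominator is zero.

## Buzz classification

ICIs are computed within trains; gaps from a train's last click to the
next train's first click are tagged as candidate inter-train intervals
and, by default, pooled into the mixture so the pause component is
identifiable (a switch restricts to within-train ICIs). The mixture is a
univariate Gaussian on log10(ICI in ms), fitted by EM (full-precision
log-space E-step, tolerance 1e-8, ≤ 500 iterations, 5 seeded restarts per
K) for K ∈ {2, 3, 4}, selected by BIC; samples beyond 50,000 are
subsampled for speed (parameter recovery saturates far below that).
Components with mean ICI < 10 ms are buzz; the largest-mean component is
the inter-train pause; the rest are regular echolocation. Clicks take the
maximum-posterior component's label, ties breaking toward the lower mean.
A pure 10-ms threshold classifier is provided as a cross-check, and the
suite also cross-checks the EM against scikit-learn's GaussianMixture.
Buzz metrics: BPM (minutes with ≥ 1 buzz-labeled interval), daily BPH,
and hourly buzz rate 100 × BPM/DPM, missing (never zero) when DPM = 0.

## Environmental covariates

Diel phases partition the day: morning = [civil dawn, sunrise + 1 h),
day = [sunrise + 1 h, sunset − 1 h), evening = [sunset − 1 h, civil dusk),
night otherwise; the ±1 h offsets are configurable since published phase
definitions vary. Time to high water is signed (negative before the
nearest high); phase is high/low within ±0.5 h of the event, else
flow/ebb; tidal range is the height difference between the nearest high
and the adjacent low on the timestamp's side. Synthetic sun (sinusoidal
daylight, ~51° N amplitude) and tide (M2 = 12.4206 h alternation with a
14.77-day spring–neap height modulation) tables let the whole pipeline
run standalone; real tables load from CSV with validation (ordering,
alternation). POD temperature is treated as relative and pooled across
the two devices; hourly Nall aggregation defaults to the mean
(median/sum available).

## Hourly additive models

Response: DPM per hour (0–60) with NB error and log link; the foraging
model uses hourly BPM counts with a log(DPM) offset (hours with DPM = 0
drop out), which keeps the response a genuine count — a mode that rounds
the buzz-rate percentage and fits it directly is provided for comparison
with analyses that model the rate itself.

Design: cyclic cubic P-splines (wrapped basis + wrapped second-difference
penalty) for continuous month (k = 12, period 12) and time-to-high-water
(k = 8, period 12.4206 h); cubic P-splines with shrinkage for
temperature, noise and tidal range (k = 10), where the penalty's
null-space eigenvalues are set to 0.1 × the smallest positive eigenvalue
(the `ts` construction), so a single smoothing parameter can remove a
term entirely; diel period as a factor with reference "day". Every
smooth carries a sum-to-zero constraint via projection.

Fitting is penalized IRLS. Smoothing parameters minimize a Laplace
REML-type criterion — penalized deviance + log|X'WX + S_λ| − log|S_λ|₊ —
by block-coordinate descent on log10 λ (coarse grid seed then
Nelder-Mead per term); γ = 1.2 divides the data-fit term (an
effective-sample-size deflation that forces slightly smoother fits).
Deviance GCV with γ-inflated EDF is available as an alternative
criterion; it was not made the default because it retains spurious
structure on null covariates noticeably more often (a known GCV
weakness, reproducible with reference GAM software). θ "auto" is
profiled on a ρ = 0 fit and held fixed; ρ "auto" is the lag-1 ACF of
that fit's Pearson residuals, clipped to [0, 0.99]. AR(1) is handled by
whitening the weighted working model within contiguous hourly blocks
(gaps reset the recursion; the first observation of each block is scaled
by √(1 − ρ²)).

Reporting: per-term EDF (trace of the influence blocks); AIC with Wood's
corrected degrees of freedom 2·tr(F) − tr(F²), which accounts for
smoothing-parameter shrinkage and makes AIC comparisons between nested
models behave; p-values from Wald statistics (chi-square on rounded EDF
for smooths, normal for factor levels); effect sizes as statistic/EDF
(F-like) for smooths and t for factor levels, signs from the average
fitted slope over the observed range; % deviance explained against the
intercept-only NB deviance at the same θ; AUC of presence (y > 0) versus
1 − P_NB(0; μ, θ) with midrank ties; concurvity as the projection R² of
each smooth's fitted component onto the span of the other terms'
columns. Backward selection drops the least significant term with
p ≥ 0.05, keeping each drop only if AIC does not increase, down to an
intercept-only end state if nothing is significant.

Degenerate inputs: all-constant responses give ρ = 0 with a warning;
rank-deficient penalized systems raise naming the failure; single-class
presence makes AUC missing; hours with missing covariates are dropped
from fitting and counted, never silently imputed.

## Problem sizes in the tests

The suite runs the mixture recovery at n = 3,000 ICI samples, buzz-
fraction recovery on 45-day deployments, the detection-ratio recovery on
a 1,000-day two-pod deployment against the exact binomial expectation of
the same observation model, and the additive-model recovery at 10,000
hours; shrinkage and selection batteries use 12–30 seeded replicates at
n = 1,200–2,000. These sizes put Monte-Carlo error well below the
assertion tolerances while keeping the default test run quick.

## Known limitations

The smoothing criterion, basis constructions and df accounting differ in
detail from other GAM implementations, so fitted EDFs and AICs are not
numerically interchangeable with them even on identical data (shapes and
inference agree closely in practice). The null-term suppression rate of
the shrinkage smooths is ~85–90% at n ≈ 2,000–4,000 — matching reference
GAM software under the same conditions — so an occasional null covariate
survives with < 1 EDF. p-values for smooths are Wald approximations
without smoothing-parameter-uncertainty corrections. The buzz-rate model
conditions on detected presence; it does not correct for the detectors'
differing buzz-click capture rates, which is precisely the contrast the
comparison is designed to expose.
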