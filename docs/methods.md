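# Methods

This note documents the models, statistical conventions, numerical
choices, and known limitations of the `reachloop` pipeline, and what
the synthetic-data generator does and does not emulate.

## Data model and conventions

All times are absolute seconds from session start (float64); alignment
to events happens at analysis time, never at storage time. Missing
events are NaN/absent, never sentinels. Hand position is millimeters
along (forward, left, up) with the perch as origin, sampled at 500 Hz.
Sessions serialize to delimited text with full `repr` float precision,
so write→read round-trips are bit-exact and analyses on a re-read
session reproduce in-memory results exactly.

Significance everywhere is Benjamini–Hochberg-controlled q < 0.05. The
BH wrapper passes NaN (untestable) entries through without counting
them as tests.

## Rate estimation and z-scoring

Spike counts are binned at 1 ms on half-open bins and convolved with a
unit-mass Gaussian kernel truncated at ±4σ (σ = 50 ms for
visualization-grade rates, 25 ms for decoding-grade rates and hand
velocity). Binning-then-convolving differs from continuous-time kernel
placement by less than the 1 ms timing resolution. Event alignment
bins with ±4σ padding and crops, so window-edge rates are unbiased.

Z-scores are relative to a named pre-event baseline window, pooled
over trials per unit; the baseline SD is floored at 1e-6 Hz with a
flag, so constant-rate units yield z ≡ 0 rather than infinities.

Hand velocity is per-axis Gaussian smoothing (σ = 25 ms) followed by
an 8th-order central first difference (9-point stencil, exact for
polynomials up to degree 8); the 4 samples at each edge are marked
invalid rather than estimated with one-sided stencils, avoiding silent
bias near window edges.

The multiunit depth profile subtracts each channel's mean before
blanking the 0–6 ms optical-artifact window (the blanked samples are
then neutral for the subsequent filter), high-passes with a zero-phase
4th-order Butterworth at 650 Hz, full-wave rectifies,
pulse-averages, smooths over time (σ = 333 µs) and across depth
(σ = 30 µm, Gaussian weights on the actual channel depths, so the
result is invariant to channel ordering), and averages 6–10 ms after
pulse onset. The filter family/order and kernel truncation are
conventions; only the cutoff and kernel widths are prescribed.

## Event GLM

Intensity model: λ(t) = exp(b + (k_cue ⋆ x_cue)(t) + (k_reach ⋆
x_reach)(t)) on a 1 ms grid, with x the delta trains of cue and lift
times and k expanded in 8 raised-cosine bumps over an 800 ms
post-event window. Bump centers are evenly spaced with half-width
twice the spacing (50% support overlap); the interior sum of bumps is
constant to 1e-9 (partition of unity), so smooth filters are
representable without ripple. An unpenalized intercept (baseline
log-rate) is included: real units have nonzero baselines even though
the bare intensity equation omits it.

Fitting maximizes the Poisson log-likelihood minus (λ_ridge/2)‖w‖² by
damped Newton iterations (step halving on the penalized likelihood),
from a deterministic start (zero weights, intercept at the observed
mean log-rate). Convergence is declared when the gradient ∞-norm falls
below 1e-6 or the line-searched update becomes numerically nil
(< 1e-12): on ~1e6-bin designs the gradient floor is set by float
accumulation, and the second criterion recognizes the numerical
optimum.

**Ridge strength.** The default is λ_ridge = 400 on the 1 ms count
scale, chosen by calibration on synthetic units at the package's
reference conditions (300 trials, 10 Hz baseline): it is the smallest
scanned value at which null-truth units show spurious gain excursions
confined to [0.9, 1.1] across the whole 800 ms window while the median
correlation between fitted and generative gain curves stays above 0.9.
The cost is amplitude shrinkage of strong responses (factor ≈ 0.6 at
these counts); gain-curve *shapes* are preserved, which is what the
downstream norm comparison and visualization use. λ is configurable
per call for data with more trials or higher rates.

Goodness of fit is the R² of the simple regression of the σ = 50 ms
smoothed observed rate on λ(t) (the squared Pearson correlation of the
two concatenated curves; defined as 0 for constant λ). Units with
R² > 0.1 are flagged "modeled". Cue-vs-reach effect sizes are the
Euclidean norms of the reconstructed filters, compared by a two-sided
Wilcoxon signed-rank test.

## Tagging, latency, and response classes

Paired window tests use the Wilcoxon signed-rank on per-event counts
(exact null distribution up to 25 informative pairs — scipy enumerates
it even with ties — normal approximation with continuity correction
beyond), BH across units; fewer than 5 events flags a unit untestable.
All-tied pairs give p = 1 by convention.

The sliding-window latency analysis labels each 10 ms window by its
**end** time, stepped at 1 ms across −30..+50 ms; per lag, per-pulse
window counts are compared by rank-sum against the pooled counts of
all windows fully inside the pre-pulse span, BH across units at each
lag (not across lags — each lag is a separate family, mirroring the
recruitment-curve construction). A unit's latency is its first
significant lag; the recruitment curve is the cumulative fraction
recruited, with a normalized variant dividing by the ever-responsive
fraction. Because lags form 81 overlapping families, a unit's
*earliest* lag is a biased-early order statistic under the null; the
analysis is for population timing, not single-unit inference.

Long-stimulation responses are classified from per-trial rates (so
windows of different lengths are comparable) against the 2 s pre-laser
baseline: a BH-significant full-window change is sustained_up/down by
its sign; otherwise a significant first-100 ms change is
transient_up/down; otherwise none.

## Circular entrainment

Spike phases are 2π·frac((t − laser_on)·f) for spikes 0.5–2.0 s into
each stimulation epoch (excluding the onset transient), phase 0 at
each cycle onset. This phase reference is a convention; only phase
*differences* are reported across populations, so it cancels in the
lag. The Rayleigh p uses the standard finite-n corrected formula
p = exp(√(1 + 4n + 4(n² − Rn²)) − (1 + 2n)); measured type-I error at
α = 0.05 is ~0.05–0.06 (within [0.03, 0.07]) at n = 200. The circular
KDE uses a von Mises kernel with κ = 1/σ², σ = 0.3 (the
Gaussian-equivalent bandwidth convention), evaluated on a 360-point
grid; trapezoidal integration on the periodic grid is spectrally
accurate, so densities integrate to 1 within 1e-6. Population peak
phases are modes of the summed per-unit densities; lags convert to
milliseconds as (deg/360)·(1000/f), reported to one decimal.

## Behavioral effects

Grab endpoints are read at the video frame nearest grab time (≤ 1 ms
discrepancy at 500 Hz). The five measures use: two-sided rank-sum per
axis (endpoint medians), two-sided rank-sum (lift-to-grab duration),
Pearson chi-square without continuity correction (initiation;
first-attempt success among initiated trials), and a two-sided
two-sample F-test per axis (endpoint SD), with degenerate tables
(zero margins) reported as p = 1 with a flag and zero-variance
conditions flagged untestable. Rank-sum p-values are exact for modest
untied samples and tie-corrected-asymptotic otherwise. Across
sessions, BH is applied per measure, with the three axes of the
endpoint and dispersion measures entering as separate tests within
their measure; a session has "any effect" if any q < 0.05.
Cue-to-lift reaction time is deliberately not a measure.

The frame overlay computes per-pixel 90th-percentile intensity
templates per condition and composites control×[1, .5, 0] (orange) +
laser×[0, .5, 1] (blue), clipped to [0, 1].

## Condition comparison

All correlations are computed on baseline z-scores, not raw rates —
raw baselines are correlated across conditions and would inflate
pre-movement correlations. Per-time-point and per-unit Spearman
correlations use BH over time points and over units respectively. The
per-unit permutation test is realized by its large-sample normal
approximation ρ√(n−1) ~ N(0,1), which agrees with a 1000-shuffle
permutation within ±0.02 at 50 samples. The superposition prediction
places each unit's laser-only z curve at t + d for each laser trial's
lift-to-laser delay d and averages; samples shifted out of the
recorded window contribute the unit's baseline z (zero), and such
trials still count in the average.

## Velocity decoding

Channel rates (σ = 25 ms smoothed spike counts, or carried rate
matrices — which receive the same kernel, so both inputs see identical
temporal filtering) are z-scored against the 1.5 s of rest before each
trial start; channels with mean |z| > 100 during movement are dropped
as artifactual. PCA is fit on the lift-aligned trial-averaged control
activity; the decoder regresses each 2 ms velocity sample on the 15
most recent PC-score samples (oldest tap 28 ms back) plus an
intercept, by least squares (least-norm with a flag under rank
deficiency). Lag history may extend before the analysis window — the
recording exists there — so early window samples are not discarded.

Trial inclusion: complete lift→grab sequences only; laser trials must
execute inside the laser window with lift ≥ 300 ms before laser
offset; control trials must complete within 2 s of the cue
(post-delivery sessions also allow lifts up to 0.5 s early). Every 5th
included control trial (time order) is the held-out control-test set.

Dimensionality: fourfold CV over training trials (fold j = trials
j, j+4, …); the selected count is the smallest whose mean held-out MSE
is within 1% (multiplicative) of the overall minimum, with
coefficients averaged across folds. Numerical tie-break: MSEs below
1e-10 of the target variance are clamped before the comparison —
exactly collinear extra dimensions otherwise produce machine-noise
MSE ratios and an arbitrary selection; the clamp is inert for any data
with a genuine noise floor.

The balanced variant trains on all odd laser trials plus an equal
number of regularly spaced control trials — indices ⌊j·N/M⌋ for
j = 0..M−1 (e.g. 6 of 18 → 1-based {1, 4, 7, 10, 13, 16}) — with PCA
from the mean of the two conditions' trial averages and 5 dimensions
fixed. The augmented (CTX+DCN) variant concatenates each region's
selected PC scores and fold-averages its coefficients with the same
fold assignment as the single-region path, so duplicating a region
reproduces the single-region decoder exactly.

Decoder quality is R² = 1 − SSE/SST with the three axes pooled.
Laser-vs-control effects are summarized by the per-axis Spearman
correlation between observed and decoded mean velocity differences
over the lift window; across sessions, a two-sided signed-rank test
addresses zero median correlation.

## CCA

The first four PC dimensions per region, concatenated over all
included control and laser trials in [lift − 100, lift + 300] ms, are
standardized to unit variance per dimension (the "standardized sample
variance" accounting of the classical multivariate treatment) and
mean-centered. CCA is classical whitening + SVD of the cross-
covariance: correlations descend, scores have unit variance, and each
pair's sign is fixed (region-A weight vector's largest-magnitude entry
positive) for reproducibility. The fraction of a region's standardized
variance explained by its i-th canonical variate is ‖corr(X, U_i)‖²/p
— these sum to 1 over the complete set — and the opposite-region
fraction is that value times the squared canonical correlation (each
variate correlates with exactly one variate of the other region).
Within-trial samples are treated as exchangeable (no autocorrelation
correction), matching the concatenation design. The laser-vs-control
comparison runs two CCAs with PCA from the mean of both conditions'
trial averages: one on laser trials only, one on an equal number of
regularly spaced control trials, comparing total opposite-region
variance explained.

## Synthetic sessions: what they emulate, and what they do not

The generator's defaults are the package's reference study conditions:
60 control / 30 laser-cue / 30 laser-only trials at 5 s spacing, a
2 s, 40 Hz laser leading the cue by 50 ms, a 10 Hz pulse-tagging epoch
of 50 pulses before the task, 12 PN / 8 PKJ / 12 DCN single units and
16 CTX / 12 DCN multiunit channels. PN units draw log-normal baselines
(median 10 Hz) and raised-cosine filter weights (SD 0.5); 25% are
pulse-tagged (gain 4 at 6–14 ms latency) and long-laser response
classes are drawn (30% sustained up / 15% down / 10% transient up).
Entrained units use von Mises phases with per-unit MRL around 0.06
(PKJ) and 0.22 (DCN) — the weak-Purkinje / strong-DCN regime — and
preferred phases 95° apart (jitter 15°). Reaction times are a 0.15 s
floor plus an exponential tail (mean 0.30 s): right-skewed, as real
reaction times are, and wide enough that cue and reach filters are
statistically separable — with near-deterministic delays the two
event filters are near-collinear and no estimator could distinguish
them.

Kinematics are minimum-jerk reaches from the perch to per-trial
endpoint draws (target (12, 3, 8) mm, SD 1.0 mm per axis), plus a
smooth bounded positional jitter (0.3 mm) whose derivative is the
velocity noise — bounded jitter rather than integrated velocity noise,
so endpoint scatter does not random-walk across a session. Laser
trials shift the endpoint (+1.5 mm forward), prolong lift-to-grab
(+0.1 s), reduce initiation (−0.10) and first-success (−0.20)
probabilities, and scale endpoint SD (×1.3) — the directions of the
reported behavioral effects, at magnitudes chosen once as realistic
for ~mm-scale reach scatter. The first three latent factors are the
hand velocity (scaled by 20 mm/s per unit); extra factors are smooth
unit-variance processes, optionally shared across regions or rescaled
during laser epochs. Channel rates pass a softplus whose operating
point (baseline 40 Hz against drive swings of a few Hz to ~15 Hz)
keeps rectification near-linear; "noiseless" configurations raise the
operating point so linear decoding is numerically exact.

Poisson spiking is sampled by exact thinning against the grid supremum
(×1.05 margin); entrained-epoch spikes assign uniform cycles and von
Mises phases with concentration solved from A(κ) = I₁(κ)/I₀(κ) = ρ.
Identical seeds give identical sessions.

Not emulated: spike-sorting artifacts and unit drift, correlated
trial-to-trial neural variability beyond the latent factors, video
pixel data (the overlay op takes toy intensity stacks), oscillatory
local field structure other than the stimulation-locked component, and
task-modulated firing in the PKJ/DCN *single units* (they carry
entrainment structure only, so the control-vs-laser z-score
comparison on them correctly centers near zero — that stage's
recovery tests use constructed inputs instead). Passing tests
therefore demonstrate estimator correctness and calibration under the
generative assumptions, not robustness to the full messiness of real
recordings.

## Problem sizes used by the test-suite and acceptance script

GLM recovery uses 20 bump-truth and 3 null units at 300 trials
(12 + 3 in the acceptance script); decoder recovery uses 40-control /
16-laser sessions with 16 channels (10 sessions in tests, 5 in the
script); entrainment calibration uses 35–50 two-second epochs per
unit (~2000 steady-state spikes), 2000 Rayleigh null replicates in
tests (1000 in the script), and 10 units per group for the
population-lag recovery; behavioral calibration uses 50 trials per
condition with 100 power seeds and 200 null sessions in tests (40 and
100 in the script); CCA recovery uses 4-dimensional regions at 4000
samples. These sizes give Monte-Carlo error comfortably inside each
check's tolerance while keeping a full run in minutes on one core.
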