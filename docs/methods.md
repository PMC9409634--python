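# Methods

This note records the models, conventions and numerical choices behind
`hrvpart`, the defaults and why they were chosen, and what the
synthetic-data tests do and do not demonstrate about real recordings.

## NN-series preprocessing

**QRS detection.** Single-lead ECG is smoothed with a 10 ms moving
average, differentiated with a symmetric second-difference stencil
spaced at 20 ms (matched to QRS width, so the R deflection dominates
sample-level noise), squared, and thresholded at 0.4 of the running
maximum over a 2 s window; a 200 ms refractory period keeps the
strongest candidate per burst. All five constants are keyword
parameters. On clean synthetic ECG the detector recovers beat positions
to ±1 sample and RR intervals to one sample period; at 5–10% additive
noise sensitivity and precision stay ≥ 99% (40 ms matching window).

**Artifact rejection.** Manual beat editing is replaced by a
deterministic rule: an interval is kept iff it lies in [300, 2000] ms
and deviates ≤ 20% from the median of the last 5 accepted intervals
(no relative test before the first acceptance). Rejected beats are
dropped, never interpolated, and a series losing more than 20% of its
beats raises a quality error that names the series. The rule is
idempotent by construction (it only references previously *accepted*
beats), which the property tests assert.

**Segment selection** takes the first 300 accepted intervals after an
optional skip; the skip is exposed rather than guessed because nothing
constrains which window of a longer recording an analyst would choose.

## The eleven indices

Time domain: meanNN; SDNN with the n−1 denominator (the convention of
the HRV standards); RMSSD; pNN20 counting successive absolute
differences *strictly* greater than 20 ms (so an exact 20 ms step does
not count — the boundary case is tested).

Frequency domain: the tachogram locates each interval at its cumulative
end-time and is linearly resampled on a uniform 3 Hz grid anchored at
the first beat's end-time (any uniform grid is admissible; the anchor
is logged). Welch periodogram: 256-sample Hann segments, 50% overlap,
per-segment mean removal; band powers integrate the PSD by trapezoid
over LF = [0.04, 0.15) Hz and HF = [0.15, 0.40] Hz, in ms². A
`band_mean` flag reports mean PSD level per band instead of the
integral for comparability with "mean spectral power" phrasing; the
integral is the default because the published Δ values are in ms².
LFn = 100·LF/(LF+HF), HFn its complement (hence ΔLFn = −ΔHFn exactly),
LF/HF the ratio; all three are NaN-flagged when their denominator is
zero.

**DFA α₁.** Integrate the mean-subtracted series, split into
non-overlapping boxes of s = 4…11 samples (remainder discarded),
detrend each box with an order-1 least-squares line, and regress
log F(s) on log s. Plain DFA at these short scales is biased: its
expectation for white noise can be computed exactly (the integrated
profile inside a box has covariance C_ij = min(i,j)+1, so
E[F²(s)] = tr(HCHᵀ)/s with H the detrending projector), and the
implied white-noise slope over scales 4–11 is 0.617, not 0.5. The
estimator therefore applies the modified-DFA finite-size correction by
default, dividing each F(s) by √(E_white[F²(s)]/s): an uncorrelated
series then reads 0.5 in expectation and a spectrally synthesized 1/f
series reads ≈ 0.92–0.95. The correction is analytic (no simulated
reference) and `corrected=False` restores the classic estimator.
Constant input (zero fluctuation) is NaN-flagged.

**SampEn.** m = 2, r = 0.2 × sample SD, Chebyshev distance,
self-matches excluded, with the same N−m template start positions for
lengths m and m+1 (Richman–Moorman), so a strictly alternating series
gives exactly 0. The vectorized implementation is checked for *exact*
equality against a literal O(n²) double-loop oracle. r = 0 or a zero
match count is NaN-flagged with the counts retained.

Δ indices are supine minus standing, element-wise, NaN propagating.
ΔmeanNN is stored in ms like the index; `d_mean_nn_s` reports seconds,
the unit used in clinical tables and by the cohort covariate.

## Group statistics

A variable is treated as normal only if every group passes the
Anderson–Darling test at the 5% critical value (parameters estimated);
groups under 8 observations are inconclusive and force the non-normal
branch. Omnibus: one-way ANOVA (normal), Kruskal–Wallis (otherwise),
Pearson chi-square *without* continuity correction (categorical — this
choice reproduces the published smoking-row p = 0.714 exactly).
All-equal inputs report p = 1 with a degenerate marker. Post hoc
pairwise tests (t, Mann–Whitney, chi-square by the same rule) run
unconditionally; significance flags require both p < 0.05/3 and an
omnibus p < 0.05. Summaries: mean ± SD, median (p25, p75) with
linear-interpolation percentiles, or count (percent).

## Stepwise pre-selection

Bidirectional from the empty model: add the candidate with the smallest
partial-F p-value if ≤ 0.05; after each addition remove included
variables with p > 0.10 (worst first); iterate to a fixed point, ties
broken by (p, name) so the procedure is deterministic. Complete cases
per category model; when n < 10 + k the candidate set is reduced to the
best univariate predictors that fit, with a warning; zero-variance
candidates are dropped with a warning. The 0.05/0.10 thresholds are the
common convention of clinical statistics software and are configurable —
nothing in the underlying study reports the original criteria. Note the
calibration consequence: with p-enter = 0.05, a k-candidate null
category enters nothing with probability 0.95^k (≈ 0.77 for k = 5), and
a strong true predictor is accompanied by a chance extra in ≈ 1 − 0.95^(k−1)
of runs; the tests assert these analytic rates, not an idealized "only
the truth survives".

## Hierarchical partitioning

Subset R² values come from centered cross-product moments (one pass,
then an O(k³) solve per subset), algebraically identical to per-subset
OLS refits (asserted to 1e−10 against a design-matrix oracle); singular
subsets fall back to the pseudoinverse with a warning. The independent
contribution uses the closed-form Shapley weights rather than literal
per-ordering refits, which removes the order dependence that makes
repeat-averaging necessary in order-sensitive implementations;
`partition_with_repeats` (average over random column orders, default
10 repeats, auto-engaged for k > 9) is retained for procedural fidelity
and verifies as exactly order-invariant. Conservation Σ I_j = R²_full
holds to 1e−9; I_j + J_j equals predictor j's univariate R²; negative
I values (suppressors) are reported untruncated. k is capped at 12
(4096 fits — above the largest published model, k = 11). Both
percentage conventions are always emitted (100·I and 100·I/ΣI) because
"% independent explanatory capacity" is used both ways in the
literature; the table row names the convention.

In the pipeline, when the union of per-category selections exceeds
k = 12 the valve and ΔmeanNN selections are kept first and the budget
is filled in category order; the row is marked `trimmed`.

## Synthetic-data generator

**RR series**: mean_nn + LF (0.10 Hz) and HF (0.25 Hz) sinusoids
evaluated at cumulative interval end-times (matching the downstream
tachogram construction) + fractal noise synthesized in the frequency
domain (amplitude ∝ f^(−β/2), uniform random phases, β = 2α − 1, unit
SD, scaled by noise_sd). Defaults (300 beats, mean 900 ms, amp_lf 30,
amp_hf 40 ms, α 0.9, noise 25 ms) give a vagally dominated supine
record of plausible SDNN/RMSSD.

**Orthostatic shift** (supine → standing): −200 ms mean NN, HF
amplitude × 0.4, LF amplitude × 1.5, fractal exponent + 0.3 — chosen to
emulate the published healthy-response magnitudes (ΔmeanNN ≈ 0.2 s) and
sign pattern ΔmeanNN > 0, ΔHFn > 0, ΔLFn < 0, Δα₁ < 0. Group presets
attenuate the shift with disease severity (AVSt: −70 ms, HF × 0.8,
α + 0.08). In full-study simulation each subject additionally jitters
both the supine parameters and the shift itself (e.g. ΔmeanNN SD
90 ms), reproducing the sizeable within-group SDs clinical tables
report; recordings are 330 beats per posture so artifact rejection
leaves a full 300-beat segment.

**Cohort**: three groups (22/73/32 by default) with covariates drawn
from group-specific Gaussians (continuous) / Bernoullis (binary) whose
means are anchored to the published group summaries; AVAi = AVA/BSA and
LVMi = LVM/BSA exactly, PGmax = PGmean × U(1.6, 2.1) so PGmax > PGmean
per subject; AVA means strictly decrease and gradient/velocity means
strictly increase with severity. Missingness is MCAR per cell at
`missing_rate` (default 0 — the default study conditions are complete
so ground-truth recovery is exact; the real mechanism is unknown).

**Outcome ground truth.** Each Δ outcome is intercept + valve_effect ×
valve + Σ covariate effects + Gaussian noise. The population
independent contribution is evaluated by the partitioner itself on a
100 000-row noise-free predictor draw whose outcome sum of squares is
augmented analytically by (n−1)·noise_sd² — no finite noise draw
enters, and the value is memoized. The default Δα₁-like outcome
(AVA + the ten covariables of the corresponding published model) is
calibrated to a population absolute I of ≈ 4.6% with combined
R² ≈ 0.29, the magnitude reported for the AVA–Δα₁ association; the
calibration fixed valve_effect = −0.004 and noise_sd = 0.3575 against
the analytic moments and is not a per-test adjustment. Because AVA is
group-structured and therefore correlated with the effective
covariates, part of its Shapley credit is shared variance — which is
precisely the phenomenon hierarchical partitioning exists to quantify.

**What the generator does not emulate**: baroreflex dynamics,
respiratory sinus arrhythmia coupling to a measured breathing signal,
ectopy morphology, non-Gaussian covariate tails, informative
missingness, and any nonlinear dependence of Δ indices on the valve
parameters. Passing tests therefore demonstrate correctness of the
estimators and the attribution machinery under the stated generating
model, not clinical validity on real recordings.

## Problem sizes and runtime choices

The test suite and the acceptance script use: 2^14-beat series for the
DFA calibration readouts (estimator SD ≈ 0.008), 300-beat series
everywhere else (the clinical segment length), 200 subjects for
sign-pattern rates, 20 seeds × 2000 subjects for ground-truth recovery
(the mean's sampling SD is ≈ 0.08 percentage points), 50 random designs
for the oracle equivalences, and a 127-subject two-run study for
byte-level determinism. These sizes keep every statistical assertion
several standard errors away from its threshold.

## Known limitations

* The Welch segmentation, stepwise thresholds and artifact-rule
  constants are declared conventions, not recovered from any original
  software; all are configurable and echoed into the run log.
* The finite-size DFA correction targets the white-noise expectation;
  strongly anticorrelated signals (α < 0.5) retain a small residual
  bias, and spectrally synthesized 1/f input reads ≈ 0.92 rather than
  1.00 at scales 4–11.
* MBF is a single whole-record periodogram argmax restricted to
  0.05–1.0 Hz; it does not resolve breath-to-breath variation and both
  per-posture and whole-record values are computable where needed.
* Chi-square tests are asymptotic; no exact (Fisher) alternative is
  provided, matching the published analysis rather than small-sample
  best practice.
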