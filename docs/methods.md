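# Methods

This note records the models, conventions and numerical choices behind
`glucoppg`, the points where the design was genuinely open and what was
decided, and what the synthetic generator does and does not emulate.

## Signal model and synthetic generator

A PPG is modelled as the sum of a direct-current (DC) level set by
steady tissue absorption and an alternating (AC) pulsatile component
synchronous with the heartbeat. The generator realises one channel as

    y(t) = DC(g) + AC(g) · p(t) + drift(t) + noise(t)

where `g` is the reference glucose (mmol/L), `p(t)` is a pulse train
with one two-Gaussian pulse per beat — a systolic peak at 0.18 of the
beat period (width 0.07 T) and a dicrotic bump at 0.40 T (relative
amplitude 0.22, width 0.12 T) — `drift` is a slow sinusoid
(0.01–0.05 Hz, amplitude `drift_amp`, default 0.05) and `noise` is white
Gaussian (`noise_sd`, default 0.02 amplitude units). The dicrotic
amplitude is kept well below the adaptive peak-detection threshold so
that the planted systolic peaks — and only they — are detectable; with
noise and drift disabled the peak detector recovers the planted beat
count exactly, which the tests use as a ground-truth round trip.

Glucose couples into the waveform affinely: DC = 1 + 0.05·c·g rises and
AC = max(0.5 − 0.02·c·g, 0) falls with glucose, where `c` is the
dimensionless `coupling` (default 1). The recorded data gives no forward
model from glucose to PPG morphology; these maps are a deliberately
simple stand-in whose only purpose is to plant a recoverable
feature–glucose association, and their slopes are not calibrated to any
subject population.

Beat-to-beat intervals have mean 800 ms, sinusoidal modulation at the
configured LF (0.1 Hz, depth 4 %) and HF (0.25 Hz, depth 3 %)
frequencies plus 10 ms white jitter, floored at 350 ms. The HF depth
shrinks mildly with glucose (−5 % per mmol/L above 5.5, floored at 20 %
of nominal), planting the reduced-vagal-variability association the HRV
features are meant to pick up.

The campaign protocol is a 12-day, three-phase diet: a low-carbohydrate
phase (days 1–4, baseline 4.8 mmol/L), a normal diet (days 5–8,
6.0 mmol/L) and a sugared-drink phase (days 9–12, 7.2 mmol/L) with
post-meal excursions (amplitude 2.5 mmol/L after lunch/dinner in the
last phase, 0.8 otherwise, 0.9 h decay constant), an AR(1) metabolic
disturbance (innovation SD 0.35, coefficient 0.6) and a hard clamp to
`glucose_range` (default 3.5–12 mmol/L). Meals are fixed at 7.5, 12.5
and 18.5 h after midnight. Acquisition rates default to the hardware
values: 1000 Hz for the four 880 nm channels, 50 Hz for the four
1450/1650 nm channels. All randomness flows from one root seed through
`numpy.random.SeedSequence` spawned per subject / measurement / channel,
so a configuration is bit-reproducible.

What the generator does **not** emulate: optical tissue physics
(Lambert–Beer), motion artefacts, contact-pressure variation, sensor
nonlinearity, inter-subject differences in optical response beyond the
seed, and any realistic glucose–PPG transfer. Passing tests therefore
demonstrate that the pipeline recovers plantable structure under its own
stated assumptions — not clinical accuracy on real recordings.

## SSA bit-plane denoising

SSA embeds the series in an L × (N−L+1) Hankel trajectory matrix with
L = 32, so the decomposition always has 32 components; inputs shorter
than 2L are rejected rather than silently shrinking L. The SVD is
computed through the eigendecomposition of the 32 × 32 Gram matrix, and
each elementary matrix is anti-diagonally averaged via a linear
convolution, which keeps the cost linear in N. Summing all components
reproduces the input to machine precision (the identity Σuᵢuᵢᵀ = I holds
for the computed eigenvectors regardless of eigenvalue accuracy), which
the property tests assert at rtol 1e-8.

The per-component noise level is estimated as
σ = median(|xₜ₊₁ − xₜ|)/(0.6745·√2) — a parameter-free robust white-noise
SD that ignores the component's smooth content. Quantisation is
symmetric fixed point: 1 sign bit + 12 magnitude bits, full scale
FS = max|component| (FS = 1 for an all-zero component),
q = FS/2¹², round-to-nearest, codes clipped to ±(2¹²−1). The noise bit
count is b = ⌊log₂(σ/q)⌋ clamped to [0, 12], with b = 0 whenever σ < q.
Zeroing b bit-planes changes a value by at most q/2 + (2ᵇ−1)·q except at
the clipped full-scale sample, where the b = 1 round trip attains its
2·FS/2¹² bound exactly.

After bit-plane cleaning the components are summed and a second SSA pass
(same L) keeps the eigentriple of largest singular value. At the fast
sampling rates the 32-sample window spans a few tens of milliseconds, so
this leading component acts as an adaptive low-pass that preserves the
~800 ms pulse; at 50 Hz the window spans ~640 ms and the pulse AC is
partly absorbed into the retained trend. That is acceptable here because
the slow channels only contribute mean/variance features, but it is a
known limitation of keeping a single component: with window choices
close to the beat period the procedure can suppress the very AC it is
meant to clean.

Because every step except quantisation is linear and the quantisation
grid scales with each component's own full scale, the denoiser is
covariant under amplitude scaling up to small rounding differences
(asserted at relative deviation ≤ 1e-3 for scales 0.1–10).

## Feature extraction

Peaks are local maxima above a sliding 5-second mean + 0.3 SD threshold,
separated by at least 0.333 s (180 bpm). PP intervals outside
333–1500 ms are discarded; the surviving intervals' timestamps are
rebuilt cumulatively so the tachogram stays self-consistent. Frequency
features interpolate the tachogram with a cubic spline onto a uniform
4 Hz grid (mean removed) and use a Welch periodogram (segment
min(256, N), 50 % overlap); band powers are trapezoidal integrals over
[0, 0.04), [0.04, 0.15) and [0.15, 0.4) Hz and total power spans
[0, Nyquist]. The tachogram must span at least 30 s. Normalised LF/HF
use the LF+HF denominator; HF = 0 makes LF/HF the finite sentinel 1e6 so
downstream fits stay finite. Heart-rate statistics use sample (n−1)
variance/SD, a 1-bpm-bin mode (ties to the lowest bin), non-excess
kurtosis m₄/m₂² and skewness m₃/m₂^1.5 with the zero-variance convention
skew = kurt = 0, and the unscaled median absolute deviation. NN50 counts
successive differences strictly greater than 50 ms; pNN50 divides by the
number of differences. Absorption features (category 3) are computed on
the denoised waveforms, matching the pipeline order in which denoising
precedes extraction; the same applies to the HRV channels. The meal-time
feature measures back to the latest meal at or before the acquisition,
wrapping across midnight to the previous day's last meal when needed.

## Normalisation and polynomial smoothing

Feature columns are scaled to unit energy (gain 1/√Σv²); test columns
reuse the training gains and are never smoothed, since smoothing
requires the reference glucose. All cubic fits are performed on an
abscissa affinely rescaled to [−1, 1] — unit-energy columns are of order
1/√N and their cubes would otherwise destroy the conditioning — and the
coefficients are mapped back exactly by polynomial composition. The L2
fit uses a rank-aware least-squares solve (minimum-norm with a warning
when rank-deficient). The L1 and L∞ problems are solved as linear
programs with scipy's HiGHS backend: per-point slack variables for L1, a
single scalar slack for L∞. A degenerate all-identical abscissa falls
back to the optimal constant (mean / median / midrange respectively).

Smoothing the reference fits one cubic of glucose on each feature column
(rows sorted by ascending glucose, stable, the same permutation shared
across columns) and averages the fitted vectors. The per-column fits all
use the *original* glucose vector — parallel, not chained — because a
chained variant would make the result depend on the arbitrary column
order. Smoothing the features fits each column against glucose
independently and replaces it by its fitted values. A column whose fit
fails is skipped (reference) or left unsmoothed (features) with a
warning.

## Fusion

The training set is re-split 2/3 : 1/3 (new-train / validation). Per
criterion, the new-train features are smoothed, the 25 highest
forest-importance features selected (ties to the lower index), a
100-tree seeded random forest trained, and per-point absolute validation
errors recorded. Validation points are sorted by ascending reference
glucose and each point's winning criterion noted (exact ties resolved by
the fixed priority L1 > L2 > L∞).

The accumulate-probability walk keeps per-criterion counts since the
last reset and evaluates the running fractions only once
`min_region_points` (default 3) points have accumulated — the literal
rule would otherwise fire on the first point, where the fraction is
always 1. When the largest fraction exceeds ε = 0.6 the region closes at
the current point (boundary = midpoint to the next glucose value), takes
the dominating criterion's label, and the counts reset. Tail points form
a final region labelled by plurality. A partition in which every region
carries the same label is informationless and collapses to a single
region. At prediction time the mean of the three per-criterion estimates
is only a locator: it selects the region (out-of-range locators clamp to
the outer regions) and the region's criterion supplies the returned
estimate.

A caveat worth stating: region selection is greedy on a small validation
set, and each constituent forest sees only two-thirds of the training
rows. On clean synthetic tables, where raw features are already
reliable, the fused model therefore tracks the best of its three
constituents but does not beat an unsmoothed baseline trained on the
full training set; the fusion's advantage materialises when features and
references are unreliable enough for smoothing to pay for the data it
costs. The test suite asserts the mechanism property (fused MAE at or
below the constituent mean in most seeds, exact equality under
single-criterion dominance), and the acceptance script reports both the
fused and baseline metrics without adjustment.

## Evaluation

R is the Pearson product-moment correlation (reported as 0 with a
warning for constant sequences); MAE ± SD uses the SD of the *absolute*
errors, matching the MAE±SD presentation; RMSE is the quadratic mean of
the signed errors; MARD divides each absolute error by its reference.
Clarke zones follow the original 1987 inequalities after converting to
mg/dL (×18.018, from the 180.18 g/mol molar mass of glucose): zone A is
|err| ≤ 20 % of reference or both values below 70 mg/dL; E is
hypo-read-as-hyper or vice versa (ref ≥ 180 & est ≤ 70, or ref ≤ 70 &
est ≥ 180); C and D are the standard upper/lower wedges; B is the
remainder. Zone checks run in the order A, E, C, D, so boundary points
land in the earlier-checked (clinically better for A) zone.

## Problem sizes and reproducibility

Tests run on scaled-down campaigns (2 subjects, 10–20 measurements,
40 s records, 250 Hz fast rate) chosen so the whole suite completes in
well under a minute of compute per module while still spanning ≥ 30 s
tachograms. The acceptance script uses 2 subjects × 36 measurements with
40 s records at the full 1000/50 Hz rates, 100 random optimiser
instances, 50 smoothing-recovery trials per criterion and 20 SSA/
bit-plane draws. Every stochastic quantity is driven by the script's
`--seed`; derived seeds stay below 2³¹.

Known limitations: no validation against real recordings; the
glucose–PPG coupling is invented; single-component SSA retention can
suppress AC content at low sampling rates; the SVR/GP baselines use
library-default hyperparameters and are not tuned; the fusion region
rule is sensitive to small validation sets.
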