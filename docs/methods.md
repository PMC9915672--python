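# Methods

## The measurement model

The package treats a recording as a set of neurons imaged at 30 Hz while
1-s sounds at seven pressure levels (0, 30, 50, 60, 70, 80, 90 dB SPL) are
combined with three optogenetic conditions (no, medium, high laser power),
10 trials per combination, presented with ≥ 5 s between stimuli.  All
response quantities are in ΔF/F_std units: fluorescence minus the mean of
the 1-s pre-stimulus baseline, divided by the baseline's standard deviation
(sample sd, ddof = 1).  This normalization is invariant to positive affine
rescaling of raw fluorescence, which the tests assert.

### Response windows

A trial's scalar response is the mean ΔF/F_std over a 1-s window.  Two
window policies exist because they answer different questions:

- **optimal** (per neuron and stimulus condition): the window start on the
  frame grid in [0, 4] s post-onset that maximizes
  d′ = |μ_win − μ_base| / sqrt((σ²_win + σ²_base)/2) across trials, with
  the 1-s pre-stimulus baseline as reference.  Used for single-cell
  statistics (sparseness), where each cell's own response timing matters.
- **fixed** (one start per recording): the start maximizing the number of
  neurons with a significant windowed response to at least one of the 21
  stimulus combinations (paired t-test of windowed vs baseline response
  across the 10 trials, Bonferroni-corrected over the 21 conditions,
  corrected p < 0.01).  Used for population vectors, curve fits and
  decoding, where all cells must be read in the same window.

Numerical choices: candidate starts are every frame in [0, 4] s so the
window ends by 5 s; ties, including numerical near-ties of d′ (within
1e-12 of the maximum), resolve to the earliest start.  The d′ baseline is
the pre-stimulus second, consistent with the ΔF/F_std definition; the
post-onset [4, 5] s segment would be a defensible alternative but mixes
late response into the reference.  The Bonferroni correction is the
conservative default since the correction procedure is otherwise
unconstrained.  One behavior worth knowing: the responsive-neuron count is
a plateau, not a peak — when responses are strong, many window starts make
the same neurons significant, and the earliest-tie rule then returns the
left edge of the plateau rather than the center of the response epoch.
The tests therefore assert the oracle property (the returned start attains
the maximal count and lies inside the response epoch) rather than a single
"true" start.

### Interneuron tagging

The red (activity-independent) channel is regressed on the green channel
with one pooled OLS slope across all cells and frames — any shared
modulation is GCaMP bleedthrough — and each cell's mean corrected red
fluorescence is z-scored against the background red level and sd; cells
above 2 are tagged.  A constant green signal makes the slope undefined; it
is set to 0 with a warning.

## Sparseness

Lifetime sparseness per neuron and laser:
S = (1 − (Σrᵢ/n)²/(Σrᵢ²/n)) / (1 − 1/n) with rᵢ the mean response at the
i-th nonzero level minus the same-laser silence response, negative rᵢ
rectified to zero, n = 6.  Neurons with no positive rᵢ are excluded (S is
undefined); S = 0 for equal responses, 1 for a one-hot profile, and it is
invariant to positive scaling.

Activity sparseness per level and laser: the fraction of neurons whose
mean response does not exceed their reference (same-laser silence by
default, or no-laser silence) by more than a threshold.  The threshold is
the sd across neurons of the mean response to silence with no laser —
neuron means, not pooled trials, because the reference quantity is a
population profile of mean responses; trial pooling would inflate the
threshold with within-neuron noise.  With the no-laser reference the
(no laser, 0 dB) entry is 100% by construction and is omitted.

## Population geometry

The mean population vector at (level, laser) has one entry per neuron:
its trial-mean fixed-window response.  Separation angles use
silence-referenced vectors (same-laser 0 dB vector subtracted), so the
angle measures how differently the population distributes its response
across cells, independent of overall gain.  Vector lengths use the raw
mean vectors of the two levels; the silence offset cancels in the
difference.  Zero-norm vectors make the angle undefined; such pairs are
dropped from summaries, never imputed.  Across recordings, per-pair values
are averaged unweighted (population size does not weight a recording).

## Response-level curve fits

Curves are the per-level trial means ± s.e.m. at one laser power.  The
monotonicity index uses the curve normalized so |max| ≤ 1 (the index is
affine-invariant, so this only guards numerics): MI < 0.3 nonmonotonic
(Gaussian fit), MI > 0.7 monotonic (sigmoid fit), in between ambiguous —
both models are fit and the higher McFadden R² wins.

The objective is 1 − R²_McFadden = Σ(y−mean)²/sem² ÷ Σ(grand−mean)²/sem²,
oriented so the full model's weighted error is the numerator: this is the
only orientation in which minimizing improves the fit, and it pins the
intercept-only model at exactly 1 and a perfect interpolant at 0 (both
asserted).  sems are floored at 1e-6 × max(|mean|, 1) to avoid infinite
weights.  Minimization is Powell from 16 random starts per curve, sampled
uniformly from y₀ ∈ [min − range, max], y_range ∈ (0, 2·range],
x₀/x_mean ∈ [0, 90], Δx/σ ∈ [1, 45]; widths are kept positive with a
penalty rather than bounds.  A start "converges" when the optimizer
terminates successfully with finite parameters; at least two convergent
starts are required to characterize a cell.  Gaussian winners with mean
outside [10, 80] dB are recharacterized with the sigmoid fit (a peak
beyond the sampled range is indistinguishable from monotonic tuning).
A fit is accepted when R² > 0.8 and the interpolated error ≥ 0.25: the
analytic model is compared against the piecewise-linear interpolant of its
own values at the seven sampled levels, both evaluated on the sampled plus
six intermediate levels (15, 40, 55, 65, 75, 85 dB), with an R²-style
score; low values flag curves that swing between the sampled levels.

Recovery behavior, measured by the acceptance tests: with the experiment's
trial structure (10 trials per level, trial noise 10% of the amplitude
range) and tuning parameters dispersed 20% around the population means
with midpoints inside the sampled range (35–70 dB), ≥ 90% of accepted fits
recover the midpoint/mean within 5 dB and the range within 20%.  Two
identifiability limits shape this design: midpoints outside the sampled
range are unrecoverable in principle, and if the 10%-of-range noise is
placed on the *means* directly (rather than on trials, whose averaging
shrinks the s.e.m. by √10), the estimator's intrinsic variance alone
exceeds the 20% range tolerance for any fitting method — a shallow sigmoid
over seven points simply does not pin its parameters that tightly.  Peaks
planted below the sampled range (2–8 dB) classify as nonmonotonic, fit as
Gaussians with out-of-range means, and are recharacterized — planting 5%
yields a 5% ± 2% refit fraction.  Peaks planted *above* 80 dB instead look
monotonic from the outset (MI near 1) and go straight to the sigmoid, so
they never enter the refit path.

## Level decoding

Per laser condition, the 70 trial vectors are projected onto the smallest
number of principal components capturing 70% of variance (PCA fit once on
the condition's trials; fitting within folds would be more conservative,
and the fit-once choice follows the analysis pipeline this package
mirrors).  For each level, its 10 trials are oversampled to 60 by sampling
a Gaussian KDE (Scott bandwidth) fit to them; when the trial covariance is
singular — duplicate trials, or more retained dimensions than trials — a
diagonal-bandwidth kernel (resampling plus per-dimension Scott-scaled
jitter) substitutes.  The balanced 120 trials are scored with a linear SVM
(C = 1, not tuned) under stratified 10-fold cross-validation; the reported
accuracy is the mean validation accuracy.

Chance is 0.5 for the balanced two-class design, and the permutation
baseline (`shuffle_labels=True`) permutes the labels of the 120 trials fed
to the SVM, yielding 0.50 within Monte-Carlo error.  Shuffling *upstream*
of the oversampling would not return chance: a KDE-resampled class is more
concentrated than the same number of independent trials, and that
resampling footprint alone is linearly decodable (measured at ~0.6–0.7 on
level-free data).  For the same reason, "no level information" and "0.5
accuracy" are not synonymous for the full pipeline; the tests assert the
footprint band explicitly.  Also note that perfect decoding of separated
clusters additionally requires each class to be a convex-hull vertex in
the PCA space — a central cluster is not one-vs-rest linearly separable no
matter how tight.

## The two-cell model

An analytic population of one sigmoid cell (y₀ = −0.12, y_range = 0.88,
x₀ = 55 dB, Δx = 11 dB with no activation) and one Gaussian cell
(y₀ = −0.04, y_range = 0.54, x_mean = 50 dB, σ = 13 dB), each parameter
set to the mean fitted value of the corresponding recorded population.
Activation changes only the parameters that change significantly in the
data: SST moves the sigmoid midpoint to 68 dB and scales the Gaussian to
y₀ = −0.07, y_range = 0.27; VIP scales the sigmoid range to 1.43 and the
Gaussian to y_range = 0.86, x_mean = 54 dB, σ = 17 dB.  Responses are
evaluated at 0–90 dB in 1-dB steps; angles use 0 dB-subtracted vectors,
lengths raw ones.  Mean condition differences average over unordered level
pairs (s₁ < s₂, diagonal excluded) within 1–90 or 30–90 dB; this
convention reproduces all eight summary values to their printed precision,
so no alternative (ordered pairs, diagonal included) was needed.

Gain regimes come from a least-squares line of laser-on vs laser-off
response over the level grid: slope below 1 − 0.05 is divisive, above
1 + 0.05 multiplicative; intercept below −0.02 a.u. subtractive, above
+0.02 additive; labels combine when both axes deviate (e.g. VIP on the
monotonic cell: slope 1.63 with intercept +0.075 → "multiplicative and
additive"; the pure multiplicative description applies only to
silence-referenced responses, where the offset term cancels).

## The synthetic-data generator

`generate_population` draws each neuron's tuning parameters from
independent Gaussians centered on the two-cell model's no-activation means
with sd = 20% of each mean (population heterogeneity without invented
correlations); widths are floored at 1 dB and Gaussian means clipped to
[10, 80] dB.  The laser effect applies the two-cell parameter shifts of
the configured interneuron class — fully at high power, half at medium, a
plain linear interpolation in the absence of measured medium-power
parameters; a control configuration applies no shift.  Trials are tuning
means plus i.i.d. Gaussian noise (default sd 0.15 ΔF/F_std, homoscedastic;
a heteroscedastic option scales noise with response magnitude but is off
by default).  All randomness flows from per-neuron substreams keyed by
(seed, stream, neuron), so populations are bit-reproducible and stable
under subsetting.

`generate_traces` wraps each trial response in a difference-of-exponentials
calcium kernel (τ_rise = 0.05 s, τ_decay = 1.0 s, onset delay 0.3 s) on a
1-s baseline + 5-s post-onset frame grid at 30 Hz, scaled so the mean
ΔF/F_std over the first post-onset second equals the tabled response;
baseline noise is white with unit ΔF/F_std variance.  Windowed re-extraction
therefore recovers the table up to a noise floor of ~√(2/30) ≈ 0.26
ΔF/F_std (window mean plus baseline-mean estimation error), which the
round-trip tests assert.  `generate_channel_signals` builds green signals
with per-cell offsets and fluctuation, and red = 0.3 × green + background
(level 20, sd 2) + a 6σ elevation for tagged cells.

What the generator does *not* emulate: correlated noise across neurons and
trials, slow drift and motion artifacts, level-dependent response latency,
bursty GCaMP nonlinearity, and any network interaction between interneurons
and pyramidal cells.  Passing tests therefore demonstrate that the analysis
chain is correct and directionally sensitive under the assumed statistical
structure, not that it is robust to every artifact of real recordings.

## Problem sizes and determinism

Default test and acceptance runs use 6–200 neurons, 200 curves per fit-
recovery class and a handful of permutation seeds for the decoder — sizes
chosen so the full suite exercises every stage end-to-end in a few minutes
on one core.  Every stochastic step takes a seed (config fields or function
arguments); identical seeds give bit-identical tables, fits, KDE draws and
fold assignments.

## Known limitations

- The fixed-window plateau behavior (above) means the chosen start is a
  convention, not an estimate of response latency.
- The PCA-before-folds choice leaks marginal covariance across folds;
  accuracies are accordingly optimistic by a small margin.
- McFadden weighting treats per-level s.e.m.s as known; with 10 trials they
  are themselves noisy, and very small sample s.e.m.s over-weight their
  levels.
- The gain-regime thresholds (±0.05 slope, ±0.02 a.u. intercept) are
  conventions for labeling; near-threshold regimes are sensitive to the
  fitted level range.
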