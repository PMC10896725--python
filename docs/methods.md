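# Methods

This note documents the models, algorithms, and numerical choices behind
`gazemem`, and what the synthetic-data generator does and does not emulate.

## Orientation geometries

The stimulus space is the canonical 16-orientation grid: angles
11.25° + k·22.5° (k = 0…15), measured anticlockwise from the positive
x-axis with object-upright at 90°. The grid excludes the cardinal axes and
splits evenly into eight near-cardinal and eight near-diagonal
orientations (each 11.25° from its nearest axis).

Bias geometries are parameterised by B ∈ [−1, 1] and built in angle space:
each orientation is shifted along the shortest circular path toward its
nearest diagonal (B ≥ 0) or nearest cardinal (B < 0) by a fraction |B| of
that path, then mapped to unit-circle coordinates. Working in angle space
(rather than interpolating coordinates) keeps the blended orientations
usable as angles in the psychometric model, and the unit radius is
irrelevant to any correlation-based statistic. The 16×16 Euclidean
distance matrix of the blended points is the model RDM; row i is the model
RDV for orientation i. Model–model similarity is the Pearson correlation
over the 120 upper-triangle entries (standard RSA vectorisation). With
this construction the circle correlates 0.765 with either square geometry
and the two squares correlate 0.343 with each other; the circle–square
value is a single number because the attraction grouping is a 2-step
circular shift of the repulsion grouping and circle distances are
shift-invariant.

Tie-break: for angles exactly between two axis targets (impossible on the
canonical grid) the anticlockwise target wins.

## Single-trial RSA

For trial i at time t the empirical RDV is the vector of Euclidean
distances between gaze(i, t) and the per-orientation trial averages
computed with trial i held out. Encoding is the Pearson correlation of
this 16-vector with the model RDV anchored at trial i's orientation; the
self-distance entry (model prediction 0) is included. Averaging the
trial × time matrix over trials gives the conventional cross-validated RSA
time course; the implementation is an algebraically exact vectorisation of
the per-trial hold-out (verified against a from-scratch reference to
1e−10 in the tests).

Missing cells: if an orientation average is undefined at a time point
(every trial of that orientation invalid after hold-out), the correlation
uses the available entries when ≥ 8 of 16 remain, otherwise the value is
missing. Balanced designs make this rare; the threshold is half the RDV
length, enough variance for a meaningful correlation.

The within/between-object variant forms the 16 averages separately per
object (3 objects), yielding one within-object RDV (own object, with
hold-out) and two between-object RDVs per trial; the two between
correlations are averaged. No temporal smoothing is applied anywhere in
the RSA core; data are processed at native resolution, and smoothing
appears only where a downstream statistic specifies it (Bayes-factor time
courses).

Summaries: trials can be binned by encoding strength of one item in a
window (default: 250–1,000 ms after Stimulus 2 onset, 8 equal-count bins —
the bin count is a free choice, configurable) to read out concurrent
encoding of the other item; the bias contrast correlates each trial's RDV
with the repulsion (B = 1), attraction (B = −1), and circle (B = 0) model
RDVs and summarises repulsion-minus-attraction over the last second of
each delay; mnemonic-distance summaries fit a least-squares slope across
the four distance levels (S2@Test1, S1@Test1, S2@Test2, S1@Test2) per
participant.

## Psychometric model

The remembered orientation is the B-blended angle of the true orientation.
Given a probe rotated ±6.43° from the true orientation, the probability of
a clockwise report is logistic in the signed circular difference
d = remembered − probe: P = 1/(1 + exp(−d/s)). Internally d is converted
to radians and s is dimensionless on the printed grid (0.01…1, step 0.01);
at this scale the ±6.43° ≈ 0.112 rad probe offset with s ≈ 0.11 yields
~73% accuracy, matching the empirical scale of such tasks. The oblique
parameter c multiplies s by exp(c) for the eight near-cardinal
orientations (a fixed property of the grid).

Fitting is exhaustive grid search over the 201 × 100 × 101 grid with a
least-squares objective on per-trial 0/1 responses (trials in the same
orientation × probe-offset cell share predictions, so the SSE is
accumulated from cell counts — identical optimum, ~30× faster). Ties
break toward smaller |B|, then smaller s, then smaller |c|. All-identical
response sets are fitted but flagged degenerate.

Recovery properties (measured by simulation): at n = 10,000 trials, B̂ and
ŝ recover to within one grid step; ĉ is the log of a ratio of two noise
estimates and carries sd ≈ 0.03–0.08 per fit depending on the generative
point, so single-fit ĉ is only accurate to a few grid steps — replicate
averaging is required for grid-step accuracy in c.

## Preprocessing

Per participant: gaze is zero-centred on the grand mean over all valid
samples of all trials (computed once, before rejection, and not
recomputed); samples strictly farther than 100 px (2.17° at the default
60 cm / 2,560 px screen viewed at 62 cm) from the zero-centre are marked
invalid. Epochs are [−500, 5850] ms around Stimulus 1 onset and
[−500, 2850] ms around Cue 2 onset (second epoch only for trials with a
second test), windows inclusive at both ends (3,176 samples per epoch-1
trial at 500 Hz). Pixel↔degree conversion uses the full-angle formula
2·atan(extent/2/distance) with pixel pitch from the screen width; this
reproduces 8 px → 0.17° and 100 px → 2.17°. y increases upward internally
so geometric angles match object orientations. Participant QC excludes
anyone not above chance on either memory test (one-sided exact binomial
vs 50%, α = 0.05) or with > 15% of samples rejected in any epoch.

## Microsaccade detection

Speed = Euclidean distance between consecutive samples, smoothed with a
7 ms Gaussian kernel (interpreted as the kernel SD; the smoothed trace is
both thresholded and scanned). Events are maximal runs above 5× the
trial-median speed; onset/endpoint are the first/last suprathreshold
samples, direction and amplitude come from the gaze positions bracketing
the run, and a detection within 100 ms (onset-to-onset) of the previous
accepted event is discarded. Runs shorter than 2 samples are treated as
noise; a zero-median trial (e.g. constant position) yields no detections.
Thresholding operates in raw px/sample (the 5× rule is unit-free);
amplitudes are converted to visual degrees for reporting. Direction
analyses use four windows (300–1,000 ms after each stimulus onset, the
post-cue delay-1 period, and 300 ms after Cue 2 to the end of delay 2),
correlate saccade direction with the currently relevant orientation
(Jammalamadaka–SenGupta circular correlation), and Rayleigh-test the
directions after rotating each saccade by (90° − orientation).

## Statistical inference

Cluster permutation: one-sample t per time point; clusters are maximal
sign-consistent runs exceeding the two-sided α = 0.05 cluster-forming
threshold; the cluster statistic is the sum of t values; the null is the
maximum absolute cluster sum over sign-flip resamples (default 20,000;
2,000 at desk scale), exploiting that flipped-sample t values depend only
on the flipped sums and the sign-invariant second moments (so the
permutation core is a single matrix product per chunk). p values include
the observed statistic (+1/+1), so p ≥ 1/(n_perm+1). Measured family-wise
false-positive rate under a pure-noise null (30 × 500, 1,000 replicates):
≈ 0.04–0.05.

Bayes factors use the JZS default-prior formulation: Cauchy prior (scale
0.707) on the standardised effect, truncated to the hypothesised direction
for one-tailed tests, marginal likelihood by numerical integration of the
noncentral-t density. Time courses are Gaussian-smoothed (50 ms SD) before
testing, with NaN-aware weight renormalisation. The 2×2 repeated-measures
ANOVA is computed from within-participant contrast scores (F(1, n−1) = t²
of the contrast, verified against an independent implementation), with a
generalised eta-squared effect size. The "kernel = SD" reading of the 7 ms
and 50 ms Gaussian kernels, and the exact Bayes-factor recipe, are
genuinely open choices; both are isolated behind single parameters.

## Synthetic-data generator

The generator defines the study conditions for all tests. Trial structure:
Stimulus 1 at 0 ms (500 ms), Stimulus 2 at 1,000 ms (500 ms), auditory
Cue 1 at 2,000 ms (350 ms), Test 1 at 5,850 ms; epoch 2: Cue 2 at 0 ms,
Test 2 at 2,850 ms. Designs are balanced (each ordered object pair equally
often, each stimulus cued first equally often, second test on exactly half
the trials); orientations are uniform i.i.d. draws from the 16-grid.

Gaze is a sum of: (1) orientation-encoding offsets — each stimulus
contributes gain_k(t) · r · u(θ_k), with r = 0.12° (≈ 5.5 px; pattern
diameter ≈ 0.24°), θ_k the bias-blended orientation (generative bias
`bias_B_gen`, default 0), and gains implementing a raised-cosine transient
(onset +300 ms, peak +650 ms, exponential decay τ = 900 ms), additive
concurrency of both items, a linear post-cue ramp for the cued item
(+500 ms after cue to test), and a linear fade-out of the uncued item
(gone by +1,500 ms); (2) an object-specific phase rotation (objects at 0°,
120°, 240°, weight 0.8 by default) applied to the transient component only
— delay-period ramping encoding is object-independent by construction,
which is what makes the within/between contrast and its BF time course
informative; (3) a mean-reverting random-walk drift (step 0.1 px,
pullback 0.002/sample); (4) white noise of 0.1 px/sample, emulating a
heavily low-pass-filtered research eye tracker; (5) microsaccade-like
steps (rate 1.2 Hz, amplitude 0.4° lognormal, 14 ms raised-cosine rise),
direction von Mises-locked (κ = 2, probability 0.6) to the currently
relevant orientation — never before Stimulus 1 onset + 300 ms — with
partial return saccades (probability 0.5, 150–400 ms later); and
(6) optional blink artifacts (200–500 px excursions of 100–300 ms) with a
ground-truth log. At these settings, velocity-threshold detection of the
injected saccades achieves recall ≈ 0.95 with no false positives.

Behavioural reports are drawn from the psychometric model with
per-mnemonic-level parameters: B = (0.100, 0.115, 0.130, 0.150) — bias
grows with unattended storage, grand mean ≈ 0.124 — c = −0.292, and
s = (0.114, 0.129, 0.172, 0.190), solved in closed form so the expected
accuracies hit the reported scale (≈ 73% on Test 1, ≈ 67% on Test 2,
second stimulus better than first, monotone decline over the four levels).

What the generator does **not** emulate: oculomotor physiology (main
sequence, drift statistics), participant idiosyncrasies, pupil or blink
dynamics beyond a crude excursion, stimulus-evoked reflexive saccades, or
the closed-loop fixation feedback of a real experiment. Passing tests
therefore demonstrate that the analysis recovers effects of the stated
form and calibrates correctly under a null — not that real data contain
such effects.

## Problem sizes and defaults

Test-suite and reproduction-script scales are the package's own defaults:
16 synthetic participants × 128 trials at 50 Hz for effect reproduction,
48–96 trials at 500 Hz for saccade detection, 50 replicates × 10,000
trials for parameter recovery, and 1,000 pure-noise experiments
(30 × 500, n_perm = 2,000) for the family-wise error measurement. The
pipeline default (20 × 256 at 500 Hz, n_perm = 2,000) completes in a few
minutes on one CPU.

## Known limitations

* The Bayes-factor recipe and Gaussian-kernel parameterisation are
  plausible defaults, not reverse-engineered certainties.
* ĉ (oblique effect) is information-limited at realistic trial counts;
  treat single-participant ĉ values as noisy.
* The within/between contrast assumes the 3-object design; other object
  set sizes work but the between average changes meaning.
* The cluster test controls family-wise error over time within one
  condition; testing several conditions requires an explicit display
  threshold adjustment by the user.
* Generalised eta-squared in the 2×2 ANOVA follows the contrast-based
  formulation; other η² variants will differ.
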