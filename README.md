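# gazemem

Gaze-pattern geometry analysis of visuospatial working memory.

During attempted fixation, gaze position is not perfectly still: miniature
eye movements (drift and microsaccades, well below 1° of visual angle) can
systematically reflect the content of visual working memory. `gazemem`
implements an analysis pipeline for dual retro-cue orientation
working-memory experiments in which two oriented objects are memorised, one
is cued and tested, and (on half the trials) the other is cued and tested
afterwards. The pipeline quantifies, sample by sample, how strongly the
remembered orientation is encoded in 2-D gaze position, in what format
(object-specific vs object-independent), and with what categorical bias
(repulsion from, or attraction to, the cardinal axes).

It is aimed at cognitive scientists analysing eye-tracking data from
fixation-controlled memory tasks, and ships with a synthetic-data generator
that emulates the full trial structure, so every stage is testable without
any recorded data.

## The core methods

**Single-trial representational similarity analysis (RSA).** The 16
stimulus orientations (11.25°–348.75° in 22.5° steps, avoiding the cardinal
axes) are modelled as evenly spaced points on a circle. For each trial and
time point, the empirical representational dissimilarity vector (RDV) holds
the 16 Euclidean distances between the current trial's gaze position and
leave-one-out trial-average gaze positions per orientation. Orientation
encoding is the Pearson correlation ρ between this RDV and the model RDV
(the chord distances 2 sin(Δθ/2) anchored at the trial's orientation).
Averaged over trials this reproduces conventional trial-averaged RSA while
retaining single-trial variability. A within/between-object variant forms
the averages separately per object to measure the format of the code.

**Cardinal-bias geometry.** A mixture parameter B ∈ [−1, 1] blends the
circle with "square" geometries: B = 1 collapses every orientation onto its
nearest diagonal (repulsion), B = −1 onto its nearest cardinal
(attraction). The distance structures of the three extreme models correlate
r = 0.77 (circle vs either square) and r = 0.34 (square vs square), so
repulsion-minus-attraction correlation contrasts quantify bias in gaze.

**Bias-mixture psychometrics.** 2-AFC reports ("rotate clockwise or
anticlockwise?", probe offset ±6.43°) follow a logistic choice rule
P(clockwise) = 1/(1 + exp(−d/s)) on the circular difference d between the
B-blended remembered orientation and the probe, with an oblique-effect
parameter c scaling the noise near cardinal axes
(s_near-cardinal = exp(c)·s_near-diagonal). (B, s, c) are fitted by
exhaustive grid search (B −1…1, s 0.01…1, c −0.5…0.5; step 0.01) with least
squares.

**Microsaccade detection.** Gaze is converted to a speed trace (Euclidean
distance between consecutive samples, 7 ms Gaussian smoothing); saccades
are runs above 5× the trial-median speed, with a 100 ms refractory
interval, and their directions are analysed with circular statistics
(Rayleigh tests, circular–circular correlation with stimulus orientation).

**Inference.** Sign-flip cluster-based permutation tests (sum-of-t cluster
statistic, max-statistic null), one-sample t tests with Cohen's d, 2×2
repeated-measures ANOVA, and JZS Bayes-factor time courses (BF01,
one-tailed, 50 ms Gaussian smoothing).

## Worked example

Run a complete synthetic experiment (10 participants × 192 trials, 100 Hz,
2,000 sign-flip permutations) from the command line:

```bash
cat > demo.yaml <<EOF
synthetic: {n_trials: 192, sampling_rate: 100.0}
n_participants: 10
n_perm: 2000
EOF
gazemem all --config demo.yaml --seed 3 --out demo_out
```

which prints:

```
gazemem analysis report
========================================
participants analysed: 10 (excluded: 1)

stim1_cued: 3 cluster(s), 1 significant
  480-5850 ms, sum t = 6496.1, p = 0.0005
stim2_cued: 1 cluster(s), 1 significant
  1290-5850 ms, sum t = 6145.9, p = 0.0045
bias contrast delay1: t(8) = 0.16, p = 0.4400, d = 0.05
bias contrast delay2: t(8) = -0.10, p = 0.5378, d = -0.03
accuracy slope over mnemonic distance: t(8) = -5.16, p = 0.0008629
mean psychometric parameters: B = 0.114, s = 0.133, c = -0.259
```

Reading the numbers: orientation encoding of the cued stimulus is
cluster-significant from shortly after stimulus onset through the delay
(p_cluster = 0.0005 at the 1/(n_perm+1) floor region); the
repulsion-vs-attraction gaze contrast is null, as it must be — the default
generator places no bias in the gaze patterns; behavioural accuracy
declines across the four mnemonic-distance levels (negative slope,
t(8) = −5.16); and the fitted psychometric parameters recover the
generator's cardinal repulsion (B ≈ 0.11 > 0) and oblique effect (c < 0).
One synthetic participant was excluded by the preregistered-style QC rule
(above-chance binomial test on both memory tests).

The same stages are available as a library:

```python
from gazemem import simulate, preprocess, rsa, inference

cfg = simulate.SyntheticConfig(n_trials=256, seed=0)
ds = simulate.generate_dataset(cfg)
ds = preprocess.zero_center(ds)
ds, rej = preprocess.reject_artifacts(ds)          # > 100 px from centre
enc = rsa.single_trial_encoding(ds.epochs[1],      # trial x time Pearson r
                                ds.trials["ori_idx_1"].to_numpy())
```

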