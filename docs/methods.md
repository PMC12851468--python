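# Methods

This note documents the models, statistical procedures, and design choices
implemented in `neurorsa`, in the order the analysis runs.

## Problem setting

Intracranial EEG experiments of visual object processing ask how distinct
stimulus attributes — low/high-level **visual** structure, **semantic**
content, and intrinsic **memorability** — are represented across brain
regions. Each attribute is summarised as a feature embedding over the
stimulus set (in practice extracted from task-optimised neural networks; in
this package, synthesised with known ground truth). The analyses relate the
geometry of these feature spaces to the geometry of multichannel neural
responses via representational similarity analysis (RSA), complemented by
per-channel linear encoding models, group-level proportion statistics, and
population state-space dynamics.

Because the kind of patient data these analyses were designed for is not
publicly distributable, the package ships a synthetic-data generator whose
every tuning parameter is recorded, so each downstream procedure can be
validated against known truth: null calibration (false-positive rates near
the nominal α) and parameter recovery (truly tuned channels found, with the
right attribute and latency).

## Synthetic data generator

**Stimulus set.** `n_categories × n_per_category` stimuli (default 50 × 10)
with one category label each. Provisional memorability scores are Beta(2, 2)
draws; they are replaced once the memorability embedding exists (below).

**Feature spaces.** Three embeddings with controlled mutual structure:

- *Visual*: category means drawn N(0, 1) per dimension, plus within-category
  noise with SD 0.9 (units of the mean spread). This puts category
  separability in a moderate regime (silhouette roughly 0.2–0.4) — clustered
  enough to mimic real category structure, not so strong that every
  statistic saturates.
- *Semantic*: a calibrated mixture. A single scalar `u` interpolates from an
  independent *unclustered* Gaussian space (`u = −1`), through an independent
  *clustered* space on the same category partition (`u = 0`), to a pure
  projection of the visual space (`u = +1`). `u` is solved by
  one-dimensional root finding **on the realised matrices** so that the
  Spearman correlation between the visual and semantic RDM upper triangles
  hits the requested target. The negative branch exists because two
  category-clustered spaces on the same partition are *intrinsically*
  positively RDM-correlated: a zero target is attainable only by relaxing
  the clustering of the second space.
- *Memorability*: `a · (visual projection) + b · (semantic projection) +
  c · independent noise`, with `(a, b)` solved by bounded least squares on
  the realised RDM correlations against the two remaining targets and
  `c = sqrt(1 − a² − b²)`. Infeasible target triples (e.g. strong
  visual–memorability and semantic–memorability coupling with independent
  visual/semantic spaces) raise an explicit error. The feasibility
  tolerance scales as `max(0.05, 2/√n)` because the sampling noise of an
  RDM correlation has effective sample size `n` (stimuli), not the pair
  count — upper-triangle entries share row effects.

Projection maps between spaces use random orthonormal columns so mixing
weights act on comparable scales. All matrices are standardised to zero
column mean and unit RMS.

**Memorability score.** The first principal-component score of the
memorability space, rescaled to [0, 1]. This makes the embedding vary
primarily along a single dimension that *is* the score, which is exactly
the regime in which a scalar-predictor ("simple") encoding model is the
appropriate comparison to the latent-component model.

**Default cross-correlation targets** are (0.4, 0.3, 0.2) for
(visual–semantic, visual–memorability, semantic–memorability): mutually
correlated feature spaces are the realistic regime for embeddings derived
from natural images. Ground-truth *recovery and specificity* checks instead
use (0, 0, 0): with correlated spaces, a channel tuned to one attribute is
genuinely (not spuriously) correlated with the other attributes' RDMs, so
attribute specificity is only a well-posed question for decorrelated
spaces. This is a property of the scientific question, not of the
implementation.

**Recordings.** Per channel: 1/f-power background noise (spectral shaping
of white noise, unit SD) plus, for each trial, a band-limited (70–170 Hz)
noise carrier multiplied by a trial envelope. The envelope is a rectangular
window of `response_duration` (default 0.5 s) with 50 ms raised-cosine
ramps, shifted by `onset_latency` (default 0.1 s), and scaled by
`σ_inband · effect_size · (1 + z)`, where `z` is the standardised projection
of the shown stimulus onto the channel's tuning axis and `σ_inband` the
analytic in-band SD of the background. `effect_size` is therefore the
evoked-envelope amplitude in units of the background's high-gamma floor;
amplitudes are floored at zero. Trials present each stimulus once in seeded
random order, 1 s on-screen, inter-stimulus interval uniform in
[0.5, 0.75] s. Default sampling rate is 1000 Hz (2000 Hz supported) —
Nyquist comfortably above the 170 Hz band edge at half the simulation cost.

What the generator does *not* model: volume conduction and channel
covariance, line noise and artifacts, epileptiform activity, repetition
effects, non-Poisson spiking statistics. Passing tests therefore certify
the statistical machinery (calibration, recovery, invariances), not
robustness to the messiness of clinical recordings.

**Spike trains.** Inhomogeneous Poisson: per trial the rate is constant at
`max(0, baseline + gain · z)` inside the analysis window (default
0.25–1.25 s), with uniform spike times. Used to exercise the single-neuron
path (firing-rate response matrices) through the same RDM machinery.

## Signal processing

High-gamma power (HGP) is the magnitude of the Hilbert analytic signal of
the 70–170 Hz band, extracted with a 4th-order Butterworth filter applied
forward–backward (zero phase, reflective padding). Epochs span −0.5 to
1.5 s around stimulus onset. All windows are half-open `[t0, t1)` on the
sample grid with the onset sample belonging to t ≥ 0, so sample counts are
bit-exact (2000 samples for a 2 s epoch at 1000 Hz).

Responses are the mean envelope in 0.1–0.6 s, averaged over repeats of the
same stimulus. A channel is **visually responsive** when a two-sided paired
t-test across trials (response-window mean vs baseline-window mean,
baseline −0.5–0 s) gives p < 0.05; zero-variance differences give p = 1. No
multiplicity correction is applied at this screening stage, and the choice
of a t-test (rather than, say, a signed-rank test) is a design decision —
the screening is deliberately simple and its false-positive rate is
verified empirically against the generator's null. Sliding-window binning
uses mean-over-window bins whose centers start at the earliest center fully
inside the epoch (span 2 s, width 0.3 s, step 0.02 s → 86 bins).
Normalised HGP is a per-channel z-score against trial-pooled baseline
statistics.

## RDMs and RSA

Feature RDMs use Euclidean distance between embedding rows (cosine distance
available as a control). Scalar-channel RDMs are absolute response
differences (the one-dimensional Euclidean case); population RDMs are
Euclidean distances between multichannel response vectors. The vectorised
form is the row-major upper triangle (i < j), fixed so permutation tests
are reproducible.

RDM agreement is Spearman correlation of the upper triangles (average ranks
for ties; Pearson available). Significance uses a **Mantel permutation
test**: a random stimulus relabelling is applied jointly to the rows and
columns of one RDM, default 1000 times; the p-value is `(1 + #{null ≥
observed}) / (1 + n_perm)`, which is valid (never zero) and one-sided
toward positive structure match by default — channel selection asks whether
a channel *encodes* a feature space.

Two implementation points make the permutation machinery fast without
changing its definition. First, the rank transform commutes with stimulus
relabelling (the multiset of upper-triangle values is unchanged), so ranks
are computed once and each permutation is a gather plus a dot product.
Second, for per-channel selection the Mantel null is symmetric in *which*
RDM is relabelled; the implementation permutes the feature RDM and shares
one permutation set across all channels of an analysis, reducing the null
for all channels to one matrix product per permutation block. Sharing
permutations across channels leaves each channel's marginal p-value exact.

**Partial RSA** residualises the (rank-transformed) target and neural
vectors on the control vectors (with intercept) and correlates the
residuals; collinear controls, or a target fully explained by the
controls, raise an explicit error. The permutation null relabels the
neural RDM's stimuli and recomputes the full statistic each time.

**Time-resolved RSA** correlates each channel's per-bin RDM (bins: 300 ms
window, 20 ms step) with the feature RDM, then per bin runs a two-sided
paired t-test across channels against each channel's mean baseline-bin
correlation, applies Benjamini–Hochberg FDR across the bins of that one
analysis, and keeps only runs of ≥ 5 consecutive significant bins (the
run-length rule reads "longer than 5 bins (100 ms)" at a 20 ms step as
≥ 5). Onset is the first kept bin center, peak the kept bin with maximal
group-mean correlation. The FDR family (bins within one channel-set ×
feature analysis) is the smallest family that controls the quantity
actually reported; a per-bin Mantel variant is intentionally not the
default because the paired-t path is the stated procedure.

## Encoding models

One feature space at a time (never combined — collinear spaces of different
dimensionality would confound the coefficients): `R = Xβ + ε` per channel.
High-dimensional spaces use latent-component (partial-least-squares)
regression, `n_components = min(20, dim, train − 1)` by default (the latent
dimensionality is not identified by any reported value; 20 comfortably
covers the synthetic spaces' structure and the choice is configurable).
A scalar predictor (the memorability score) uses ordinary least squares.
Predictors are standardised with training-split statistics only. At full
rank the latent model reproduces ordinary least squares, which is used as
an oracle test.

Significance is permutation-based: each of the (default 1000) null runs
shuffles the stimulus labels of `R`, draws a fresh 50/50 split, fits on
train, and records the Pearson correlation between predicted and observed
test responses. The observed statistic is, by default, the held-out
correlation of a single seeded unshuffled split — the same construction as
one null iteration, so observed and null values are exchangeable under the
null hypothesis and the implicit test level is the nominal 5% (verified
empirically). Averaging the observed statistic over several splits is
available as an option; it reduces split variance but deflates the
observed statistic's null variance relative to the single-split null,
which makes the test conservative. The model is significant when the
observed statistic exceeds the 95th percentile of the null.

## Group statistics

Selection proportions are tested against the 5% chance rate with the
**strict exceedance** binomial probability `P(X > k) = 1 − CDF(k)`; this
convention is applied uniformly. Method comparisons (RDM-based vs linear
selection among the same channels) use Pearson's χ² on the 2 × 2 count
table, 1 df, without continuity correction. BH-FDR is the step-up
procedure. The subsampling control draws `⌊0.75 N⌋` channels without
replacement (1000 iterations) and checks that the observed selected
percentage lies inside the central 95% interval of the subsampled
distribution; the resampling unit is the channel, with the participant
stratification left to the caller's grouping.

## Population dynamics

Stimuli are split into top-k and bottom-k memorability (default k = 50 of
500; ties broken by stable stimulus order). Normalised envelopes are binned
(200 ms window, 20 ms step), averaged per condition and channel, and the
concatenated condition × bin matrix is centred by channel means (no
variance scaling — channels share units after normalisation) and projected
onto the first three principal components. The divergence statistic is the
time-summed Euclidean distance between the two condition trajectories in
the retained components — the simplest scalar consistent with "distinct
trajectories"; no canonical choice exists, and outputs label it as a design
choice. Its null reassigns the pooled stimuli to two groups of the original
sizes, refitting the PCA inside every permutation.

## Pipeline, determinism, and problem sizes

`run_all` composes the stages on simulated (or user-supplied) data and
writes every intermediate table plus a manifest (config hash, per-stage
seeds, library versions). All randomness derives from one seed through
named `SeedSequence` substreams, so identical configurations produce
byte-identical text outputs.

The default simulated study uses 200 stimuli in 20 categories and
26 channels across five regions; the validation suite raises this to the
full 500-stimulus, 50-category geometry (200 channels for null
calibration) where the statistical claim depends on scale. These sizes are
the package's default study conditions; every size is configurable.

## Known limitations

- The generator's channels are linear in a single attribute projection;
  mixed-selectivity and nonlinear tuning are not modelled.
- Baseline-window conventions in the source literature are ambiguous
  (−0.5–0 s vs −0.5 to −0.02 s); the package uses [−0.5, 0) throughout.
- Whether per-channel selection should use the Mantel permutation or a
  parametric rank-correlation test is not pinned down by the procedure
  description; the Mantel test is used for coherence with the population
  analyses.
- The divergence scalar and the latent-component count are design choices
  (flagged above); conclusions that depend on them should be checked at
  alternative settings, which the configuration exposes.
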