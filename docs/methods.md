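# Methods

This note documents the modeling choices behind `microsem`: the analysis
pipeline itself, the synthetic cohort generator that serves as its test
bed, the numerical conventions, and the places where the underlying
method description leaves genuine freedom.

## 1. Pipeline

**Preprocessing.** Input EEG is assumed artifact-cleaned (visual
rejection and ICA are upstream concerns).  The package applies average
referencing (idempotent, exact), a zero-phase band-pass FIR (default
0.1–40 Hz; window-method design of order ≈ 3·fs/low-edge, capped by the
record length, applied forward–backward so the phase is exactly zero),
and non-overlapping windowing (`⌊T/window⌋` segments, remainder
discarded; overlap is configurable but 0 by default — the windowing
convention used throughout).

**Microstate core.** GFP is the per-sample channel standard deviation;
clustering samples are topographies at *strict* interior GFP maxima
(plateaus and endpoints excluded).  Backfitting assigns each sample the
template with the largest absolute spatial correlation on
channel-demeaned vectors.  Polarity invariance is used everywhere — a
map and its negation express the same generator configuration, the
universal resting-state convention.  A literal audit mode
(`mode="literal"`, argmin |VᵀV − VᵀΓ|) is kept because that form
appears in some descriptions of the method, but it is dimensionally odd
and not the default.  No temporal smoothing or minimum-duration
rejection is applied to label sequences: smoothing would distort the
run-length and n-gram statistics that the semantic features depend on.
(A zero-GFP sample has no defined direction; it inherits the previous
label and is logged.)

**Dual-template extraction.** Stage 1 clusters each subject's
normalized GFP-peak maps with DBSCAN (Euclidean metric).  The radius and
density threshold are adapted on a deterministic grid — radius over the
{5, 10, …, 95} percent quantiles of the pairwise-distance distribution,
crossed with minPts ∈ {5, 10, 20} — accepting the first combination
that yields exactly four clusters with at least minPts members each.
Noise points are excluded from the cluster means.  Peak sets larger than
`max_maps` (default 1500) are deterministically subsampled before the
quadratic distance computation.  A subject whose search fails falls back
to a seeded polarity-invariant K-means (logged).  Stage 2 pools each
group's candidate maps and runs a hand-written K-means with absolute
spatial correlation as similarity: members anti-correlated with their
center contribute sign-flipped to the center update, an emptied cluster
is re-seeded from the most dissimilar member, and the best of 20 seeded
restarts (by within-cluster |r| sum, which is non-decreasing over
iterations) is kept.  Class labels A–D are made reproducible by an
optimal one-to-one assignment (Hungarian algorithm over −|r|) against a
fixed built-in reference set; any reference can be substituted.

**Features.** The default vector is 49-dimensional:

| block    | dims | content                                                            |
|----------|------|--------------------------------------------------------------------|
| quality  | 16   | msc, gev, err, w on the HC-template fit and on the SCZ-template fit, plus SCZ/HC ratios (denominator floored at 1e-12) and SCZ−HC differences |
| semantic | 21   | the 12 ordered non-self 2-gram frequencies, 4 named 3-gram frequencies (ABA, BAB, BCB, CBC), 4 1-gram frequencies, total run rate — on the HC-template sequence |
| temporal | 12   | MD, OPS, TCR per class on the HC-template sequence                 |

Every layout choice is held in `FeatureConfig` and persisted in the
feature-matrix schema, because the method's original description gives
inconsistent totals for the blocks (39 vs. 16+21+12 = 49 vs. a 42-unit
classifier input); the package therefore treats the layout as
configuration with the documented default rather than guessing a single
"true" composition.  Subsequence statistics are counted on the
**run-compressed** sequence — this is forced by the stated equivalence
between the length-1 frequency distribution and OPS, and it makes
self-pairs (AA) impossible, which is why only non-self 2-grams appear.

Quality metric conventions: `msc` is a *mean* (a bare sum over samples
could not be a percentage); `gev` uses the standard Σ G_t² denominator
with the signed correlation (the printed Σ G_t variant is retained as
`gev_variant="literal"` for audits); `err` uses unit-norm templates and
floors each per-sample residual at 0; `w` reads the ambiguous
denominator as |S_k|, normalizes member maps (so the statistic is
amplitude-free) and sign-aligns them to the assigned template.  `w` is
computed over **all** samples by default: the ordered-pair sum has the
closed form `2m Σ‖x‖² − 2‖Σx‖²`, so the computation is O(T·N) and the
low-GFP samples — precisely the ones whose labels are
template-sensitive — contribute.  A GFP-peaks-only variant
(`dispersion_domain="peaks"`) is available.

**Evaluation.** Stratified 10-fold CV at segment level mixes subjects
(the within-mix protocol); leave-one-pair-out holds out one patient and
one control per round with a hard train/test subject-overlap assertion.
Features are z-scored with statistics fitted on training data only
(toggleable; KNN/SVM over mixed units — ms, fractions, squared
potentials — is meaningless otherwise).  Classifier defaults: KNN
(Euclidean, 10 neighbours), SVM (Gaussian kernel, kernel scale 6 read as
the bandwidth-divisor convention, gamma = 1/36), MLP (hidden 32×16,
tanh; input layer sized to the actual feature dimension).  Ablation
importance pre-trains a model on a stratified split, sets a block's raw
columns to 1 in the held-out data, passes them through the training-time
scaler, and reports the accuracy drop; ablations are independent, hence
order-invariant.  Metrics treat SCZ as the positive class
(sensitivity = recalled patients, specificity = recalled controls).

## 2. Synthetic cohort generator

No generative model is prescribed by the method itself; everything in
`microsem.synthetic` is an explicit stand-in, designed to realize the
qualitative group differences the method targets while keeping every
parameter inspectable.

* **Topographies.** Channels are abstract (no electrode geometry is
  used anywhere in the pipeline).  Four base maps are smoothed random
  zero-mean unit-norm vectors, orthonormalized and then blended with a
  shared component so every pair correlates at |r| = 0.35 — canonical
  microstate maps are far from orthogonal, and this shared structure is
  what makes low-power samples genuinely ambiguous.  The SCZ set
  diverges in classes B and D: a perturbed map is rotated toward an
  orthogonal direction by strength·π/2, so the between-group |r| is
  exactly cos(strength·π/2); default strengths realize |r| = 0.68 (B)
  and 0.86 (D), the magnitudes reported for real patient/control
  template pairs.
* **Label process.** A semi-Markov chain: states follow a 4×4
  row-stochastic matrix with zero diagonal; run lengths are geometric
  (memoryless, matching first-order Markov semantics; a fixed-length
  option exists for deterministic tests) with per-class mean durations —
  HC: 90/90/95/105 ms, SCZ: 88/85/110/82 ms (class C dwells longer,
  D shorter, all within the 80–150 ms range typical of microstates).
  The HC transition matrix is uniform; the SCZ matrix multiplies
  selected entries (B→A, B→C up; C→A, C→B down; row A adjusted to shape
  the stationary distribution) and renormalizes.  The multipliers were
  chosen by stationary-distribution analysis so that the seven 2-gram
  frequencies BA, BC, DA, DB, DC (up) and CA, CB (down) all shift with
  the intended sign in expectation.
* **A note on an arithmetic constraint.** On the run-compressed domain
  the D-row 2-gram frequencies sum to the run-frequency of D, so
  f(DA), f(DB), f(DC) cannot all rise while the 1-gram frequency of D
  falls.  The generator therefore expresses "reduced class D" through
  shorter durations (lower MD_D and TCR_D) together with a mildly
  *raised* D run-frequency; any data set exhibiting all of the reported
  shifts simultaneously would violate this identity.
* **Rendering.** Each sample is envelope × active template + noise.
  The envelope is per-sample lognormal (median 1, log-sd 0.55) smoothed
  with a 7-sample moving average, giving a GFP with genuine local peaks
  and severalfold power fluctuation as in real EEG; the matched-fit
  msc/gev this produces sit near the low-to-mid-90s / high-80s percent
  range reported for real recordings, which served as the calibration
  anchor.  Sensor noise is i.i.d. Gaussian per channel
  (sd 0.08 in unit-norm-template units, putting the GFP-peak SNR near
  3), re-referenced to the channel average so rendered EEG stays
  average-referenced exactly.  Per-subject variability: mean-one
  lognormal multipliers on state durations (log-sd 0.15) and overall
  amplitude (log-sd 0.10).
* **What passing tests show — and don't.**  The generator validates
  *mechanics*: oracle-exact computations, noise-free exact-fit limits,
  parameter recovery at a stated SNR, and the matched-beats-mismatched
  quality ordering.  It omits artifacts (ocular/muscle), non-stationarity,
  volume-conduction structure in the noise, electrode geometry, and any
  biophysical source model.  Perfect synthetic classification therefore
  does **not** predict clinical accuracy; it establishes that the
  pipeline extracts exactly the differences it was given.

## 3. Numerical conventions and degenerate inputs

Seeded determinism end to end (NumPy `SeedSequence` spawning; identical
spec + seed ⇒ byte-identical cohorts, templates, folds).  Template maps
are zero-meaned and unit-normed at construction; K-means convergence is
center shift < 1e-8 (sign-invariant distance) with a 100-iteration cap;
quality ratios floor their denominator at 1e-12; empty classes
contribute 0 to w (logged); a window longer than a record yields an
empty segment list (logged) rather than an error; a monotone-GFP
segment yields an empty peak set.  Sub-second run-length truncation at
segment ends is the only place the semi-Markov process is cut.

## 4. Problem sizes

The reference validation cohort is 14 + 14 subjects × 120 s at 250 Hz
(the cohort size and recording style of the public eyes-closed
schizophrenia dataset this method family targets, scaled to two minutes
per subject).  Quality-ordering and semantic-sign analyses use 100 and
200 segments per group (10 s and 20 s); the feature-family comparison
uses 4 s windows, where temporal estimates are noisy enough for the
families to separate — at 20 s windows every feature family saturates
on this synthetic cohort, so the operating-point comparison is reported
at both scales by the acceptance script.

## 5. Known limitations

* DBSCAN parameter adaptation is a deterministic grid walk; the
  original description says only that parameters are "adjusted", so
  other schedules are equally admissible.
* Whether per-subject clustering should use raw or normalized maps is
  unstated in the source method; normalization (making Euclidean
  distance a correlation distance) is used here and documented.
* The semantic/temporal blocks default to the HC-template sequence;
  computing them on both sequences (or the better-fitting one) is a
  one-line configuration change, and group-difference analyses of
  syntax should use matched-template sequences — mismatched backfitting
  injects boundary-glitch grams that reflect fit quality rather than
  syntax.
* The MLP is a small fixed architecture; no hyperparameter search is
  provided by design.
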