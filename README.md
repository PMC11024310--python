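# microsem — dual-template EEG microstate semantic modeling

`microsem` implements a resting-state EEG analysis pipeline for
schizophrenia (SCZ) recognition built on **microstate analysis**: the
decomposition of multichannel EEG into a sequence of quasi-stable scalp
potential topographies (classes A–D).  Its two distinctive ingredients
are

* a **dual-template strategy** — separate four-map template sets
  Γ₁…Γ₄ are extracted for the healthy (HC) and the patient (SCZ) group
  (per-subject density-based clustering of GFP-peak topographies,
  re-clustered per group with a polarity-invariant K-means), and every
  EEG segment is backfitted against *both* sets.  How much better one
  set fits than the other is itself diagnostic; and
* **semantic (n-gram) features** — the run-compressed microstate label
  sequence is decomposed into overlapping subsequences of length
  *l* = 1…3, whose frequencies and mean durations carry syntax
  information beyond classic per-class statistics.

The package is aimed at EEG researchers who want a fully testable
implementation of this pipeline: a synthetic-cohort generator with known
ground truth stands in for clinical data, so every stage — from GFP-peak
extraction to cross-subject classification — is validated against
independent oracles.

## The model

For an average-referenced segment `V = (V_1 … V_T)`, `V_t ∈ R^N`:

* **GFP** `G_t = sqrt( Σ_i (v_i(t) − v̄(t))² / N )` — the per-sample
  channel standard deviation; topographies at strict local GFP maxima
  (`G_{t−1} < G_t > G_{t+1}`) are the clustering samples.
* **Backfitting** `L_t = argmax_k |V_tᵀΓ_k| / (‖V_t‖‖Γ_k‖)` —
  polarity-invariant assignment of each sample to its most similar
  template.
* **Temporal features** per class: mean duration (MD, ms), occurrences
  per second (OPS, 1/s), time coverage ratio (TCR).
* **Semantic features** on the run-compressed sequence of `N_s` runs:
  `f_i = Occ_i / (N_s − l + 1)` and `d_i = Tt_i / (l · Occ_i)` for every
  length-`l` subsequence `i`.
* **Quality features** of each fit: mean absolute spatial correlation
  `msc`, global explained variance
  `gev = Σ_t (G_t c_t)² / Σ_t G_t²` (with `c_t` the spatial correlation
  to the assigned template), mean residual energy
  `err = Σ_t (V_tᵀV_t − (Γ_{L_t}ᵀV_t)²) / (N T)`, and within-class
  dispersion `w` (mean pairwise squared distance among a class's
  unit-normalized member maps).  The default feature vector is
  16 quality + 21 semantic + 12 temporal = 49 dimensions.

Classifiers (KNN, RBF-SVM, MLP) are evaluated under a within-mix
stratified 10-fold protocol and a cross-subject leave-one-pair-out
protocol (one patient + one control held out per round), with set-to-1
block ablations measuring feature-family importance.

## Worked example

```python
import numpy as np
import microsem as m

# a 14+14-subject synthetic cohort, 120 s per subject at 250 Hz
spec = m.default_spec(seed=0)
cohort = m.simulate_cohort(spec, subjects_per_group=14, duration_s=120, seed=0)
records = [c.record for c in cohort]

# two-stage template extraction per group (DBSCAN -> K-means)
ref = spec.templates_by_group["HC"]
hc_t = m.fit_group_templates([r for r in records if r.group == "HC"],
                             "HC", seed=0, reference=ref)
scz_t = m.fit_group_templates([r for r in records if r.group == "SCZ"],
                              "SCZ", seed=0, reference=ref)
print("between-group template |r|:",
      dict(zip(m.STATES, np.round(m.template_correlation(hc_t, scz_t), 3))))

# dual backfitting + 49-dim features on 20 s windows
segments = [s for r in records for s in m.segment(r, 20.0)]
X, names, blocks, y, subjects = m.feature_matrix(segments, hc_t, scz_t)
print(f"feature matrix: {X.shape[0]} segments x {X.shape[1]} features")

knn = m.ClassifierConfig(kind="knn", seed=0)
res = m.kfold_eval(X, y, knn, k=10, seed=0)
print(f"10-fold KNN: accuracy {res.accuracy:.3f}, "
      f"sensitivity {res.sensitivity:.3f}, specificity {res.specificity:.3f}")

_, lopo = m.leave_one_pair_out(X, y, subjects, knn)
print(f"leave-one-pair-out: accuracy {lopo.accuracy:.3f}")
```

Output:

```
between-group template |r|: {'A': 1.0, 'B': 0.68, 'C': 1.0, 'D': 0.86}
feature matrix: 168 segments x 49 features
10-fold KNN: accuracy 1.000, sensitivity 1.000, specificity 1.000
leave-one-pair-out: accuracy 1.000
```

The fitted group templates recover the generator's topographies,
including the injected class-B/D divergence (|r| = 0.68 / 0.86); with
the synthetic group differences at their reference levels the cohort is
cleanly separable at 20 s windows.  At short windows (e.g. 4 s) the
temporal-feature baseline degrades (~94 % accuracy) while the full
feature set stays at 100 %, showing the added value of the quality and
semantic families.

A CLI mirrors the library: `microsem simulate | preprocess |
fit-templates | features | evaluate` (see `microsem --help`).

## Applying to real data

The pipeline reads EDF (`microsem.io.read_edf`, via mne) or plain
CSV-matrix + JSON-sidecar records.  Artifact rejection and ICA are
upstream responsibilities; `preprocess` provides average-referencing,
the 0.1–40 Hz zero-phase FIR band-pass, and non-overlapping windowing.
With a downloaded clinical dataset the same five CLI steps reproduce the
full protocol; see `docs/methods.md` for parameter guidance and for
what the synthetic validation does and does not establish.
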