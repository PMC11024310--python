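"""Microstate feature families: temporal, semantic (n-gram), quality.

Temporal features are the classic per-class statistics (mean duration,
occurrence per second, time coverage ratio).  Semantic features are
frequencies and mean durations of length-l subsequences counted on the
run-compressed label sequence — counting on runs (not raw samples) is
what makes the length-1 frequency distribution equivalent to the OPS
ranking, and makes self-pairs (AA) impossible.  Quality features compare
how well the two template sets of the dual-template strategy fit one and
the same segment: mean spatial correlation, global explained variance,
residual energy and within-class dispersion, plus their ratios and
differences across the two fits.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (N_STATES, STATES, LabelSequence, TemplateSet,
                   compress_runs, extract_peak_maps, gfp)
from .dual import DualSequences
from .preprocess import EEGSegment

#: The 12 ordered non-self state pairs, fixed feature order.
NON_SELF_2GRAMS: tuple[str, ...] = tuple(
    a + b for a in STATES for b in STATES if a != b)

#: The named length-3 subsequences used as default semantic features.
DEFAULT_3GRAMS: tuple[str, ...] = ("ABA", "BAB", "BCB", "CBC")

QUALITY_METRIC_NAMES = ("msc", "gev", "err", "w")


@dataclass
class TemporalFeatures:
    """Per-class MD (ms), OPS (1/s) and TCR (fraction), ordered A-D."""

    md_ms: np.ndarray
    ops_per_s: np.ndarray
    tcr: np.ndarray

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.md_ms, self.ops_per_s, self.tcr])


def temporal_features(seq: LabelSequence) -> TemporalFeatures:
    """Classic microstate time parameters from the run-length view.

    MD_k = mean run length of class k in ms (0 if the class is absent);
    OPS_k = runs of class k per second; TCR_k = fraction of samples in k
    (the TCRs sum to 1).
    """
    runs = compress_runs(seq)
    ms_per_sample = 1000.0 / seq.fs
    duration_s = seq.n_samples / seq.fs
    md = np.zeros(N_STATES)
    ops = np.zeros(N_STATES)
    tcr = np.zeros(N_STATES)
    for k in range(N_STATES):
        lengths = np.array([n for s, n in runs if s == k], dtype=float)
        if lengths.size:
            md[k] = lengths.mean() * ms_per_sample
            ops[k] = lengths.size / duration_s
            tcr[k] = lengths.sum() / seq.n_samples
    return TemporalFeatures(md_ms=md, ops_per_s=ops, tcr=tcr)


@dataclass
class GramStats:
    occ: int
    f: float
    tt_ms: float
    d_ms: float


@dataclass
class SubsequenceStats:
    """Statistics of all observed l-grams over the run-compressed sequence.

    Frequencies are occurrence counts over the (N_s - l + 1) sliding
    positions, so they sum to 1 over the K^l possible grams (unobserved
    grams contribute 0 and are omitted from the table).  The mean duration
    of a gram is its total participating run time divided by l times its
    occurrence count.
    """

    l: int
    n_runs: int
    table: dict[str, GramStats] = field(default_factory=dict)

    def f(self, gram: str) -> float:
        g = self.table.get(gram)
        return 0.0 if g is None else g.f

    def occ(self, gram: str) -> int:
        g = self.table.get(gram)
        return 0 if g is None else g.occ


def subsequence_stats(seq: LabelSequence, l: int) -> SubsequenceStats:
    """Sliding count of overlapping l-grams over the run sequence."""
    runs = compress_runs(seq)
    n_runs = len(runs)
    if not 1 <= l <= n_runs:
        raise ValueError(f"l={l} must lie in [1, {n_runs}] (number of runs)")
    ms_per_sample = 1000.0 / seq.fs
    states = [s for s, _ in runs]
    durations_ms = [n * ms_per_sample for _, n in runs]
    occ: dict[str, int] = {}
    tt: dict[str, float] = {}
    n_positions = n_runs - l + 1
    for i in range(n_positions):
        gram = "".join(STATES[s] for s in states[i:i + l])
        occ[gram] = occ.get(gram, 0) + 1
        tt[gram] = tt.get(gram, 0.0) + sum(durations_ms[i:i + l])
    table = {
        g: GramStats(occ=c, f=c / n_positions, tt_ms=tt[g],
                     d_ms=tt[g] / (l * c))
        for g, c in occ.items()
    }
    return SubsequenceStats(l=l, n_runs=n_runs, table=table)


@dataclass
class QualityMetrics:
    """Fit quality of one label sequence against its template set."""

    msc: float  # mean absolute spatial correlation, [0, 1]
    gev: float  # global explained variance, [0, 1]
    err: float  # mean residual energy per channel-sample
    w: float    # within-class dispersion of normalized member maps

    def as_vector(self) -> np.ndarray:
        return np.array([self.msc, self.gev, self.err, self.w])


def quality_metrics(segment: EEGSegment, seq: LabelSequence,
                    templates: TemplateSet, gev_variant: str = "standard",
                    dispersion_domain: str = "all") -> QualityMetrics:
    """Compute msc / gev / err / w for one (segment, sequence, templates).

    msc is the mean over samples of the absolute spatial correlation with
    the assigned template.  gev (standard variant) is
    sum_t (G_t c_t)^2 / sum_t G_t^2 with c_t the signed correlation;
    ``gev_variant="literal"`` uses a bare sum_t G_t denominator (audit
    variant of a printed form that is dimensionally inconsistent).  err is
    the mean non-negative residual energy (V'V - (Gamma'V)^2) / (N T) with
    unit-norm templates.  w sums, over classes, the mean ordered-pair
    squared distance between the class's unit-normalized member maps
    (sign-aligned to the template); an empty class contributes 0.
    ``dispersion_domain="peaks"`` restricts w to GFP-peak samples.
    """
    x = segment.data
    n_ch, n_t = x.shape
    if seq.n_samples != n_t:
        raise ValueError("sequence length does not match segment")
    xd = x - x.mean(axis=0, keepdims=True)
    norms = np.maximum(np.linalg.norm(xd, axis=0), 1e-12)
    g = gfp(x)
    tmaps = templates.maps[seq.labels]            # (T, n_ch)
    proj = np.einsum("tc,ct->t", tmaps, xd)       # Gamma' V (demeaned)
    corr = proj / norms
    msc = float(np.mean(np.abs(corr)))
    if gev_variant == "standard":
        gev = float(np.sum((g * corr) ** 2) / np.sum(g ** 2))
    elif gev_variant in ("literal",):
        gev = float(np.sum((g * np.abs(corr)) ** 2) / np.sum(g))
    else:
        raise ValueError(f"unknown gev variant {gev_variant!r}")
    raw_proj = np.einsum("tc,ct->t", tmaps, x)
    resid = np.maximum(np.einsum("ct,ct->t", x, x) - raw_proj ** 2, 0.0)
    err = float(resid.sum() / (n_ch * n_t))
    if dispersion_domain == "peaks":
        idx = extract_peak_maps(x).peak_indices
    elif dispersion_domain == "all":
        idx = np.arange(n_t)
    else:
        raise ValueError(f"unknown dispersion domain {dispersion_domain!r}")
    w = 0.0
    members_all = (xd[:, idx] / norms[idx]).T     # unit-norm maps
    signs = np.sign(corr[idx])
    signs[signs == 0] = 1.0
    members_all = members_all * signs[:, None]
    lab = seq.labels[idx]
    for k in range(N_STATES):
        members = members_all[lab == k]
        m = members.shape[0]
        if m == 0:
            continue
        # ordered-pair identity: sum_{i,j} ||x_i - x_j||^2
        #   = 2 m sum_i ||x_i||^2 - 2 ||sum_i x_i||^2
        s = members.sum(axis=0)
        total = 2.0 * m * float(np.einsum("ij,ij->", members, members))
        total -= 2.0 * float(s @ s)
        w += total / m
    return QualityMetrics(msc=msc, gev=gev, err=err, w=w)


@dataclass
class FeatureConfig:
    """Layout configuration for assembled feature vectors.

    The default layout is 16 quality + 21 semantic + 12 temporal = 49
    dimensions; every choice below is recorded in the vector metadata so
    serialized feature matrices are self-describing.
    """

    semantic_sequence: str = "HC"     # template group whose sequence feeds
    temporal_sequence: str = "HC"     # the semantic / temporal blocks
    trigrams: tuple[str, ...] = DEFAULT_3GRAMS
    bigrams: tuple[str, ...] = NON_SELF_2GRAMS
    ratio_floor: float = 1e-12
    gev_variant: str = "standard"
    dispersion_domain: str = "all"

    def __post_init__(self) -> None:
        for g in list(self.bigrams) + list(self.trigrams):
            if any(ch not in STATES for ch in g):
                raise ValueError(f"unknown state in gram {g!r}")
            if any(a == b for a, b in zip(g, g[1:])):
                raise ValueError(
                    f"gram {g!r} repeats a state; impossible on the "
                    f"run-compressed domain")


@dataclass
class FeatureVector:
    """Named, block-structured features for one segment.

    ``blocks`` maps block names to explicit column-index lists (quality
    sub-blocks interleave across the hc/scz/ratio/diff layout, so index
    lists rather than slices).
    """

    values: np.ndarray
    names: list[str]
    blocks: dict[str, list[int]]

    def __post_init__(self) -> None:
        if len(self.names) != self.values.size:
            raise ValueError("names/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    def block(self, name: str) -> np.ndarray:
        return self.values[np.asarray(self.blocks[name])]

    def metadata(self) -> dict:
        return {
            "names": list(self.names),
            "blocks": {k: list(map(int, v)) for k, v in self.blocks.items()},
        }


def quality_features(dual: DualSequences, segment: EEGSegment,
                     hc_t: TemplateSet, scz_t: TemplateSet,
                     config: FeatureConfig | None = None,
                     ) -> tuple[np.ndarray, list[str]]:
    """The 16-dim quality block: per-set metrics, ratios and differences.

    Layout: the four metrics on the HC-template sequence, the four on the
    SCZ-template sequence, the four SCZ/HC ratios (denominator floored)
    and the four SCZ - HC differences.
    """
    cfg = config or FeatureConfig()
    qh = quality_metrics(segment, dual.seq_by_template_group["HC"], hc_t,
                         gev_variant=cfg.gev_variant,
                         dispersion_domain=cfg.dispersion_domain).as_vector()
    qs = quality_metrics(segment, dual.seq_by_template_group["SCZ"], scz_t,
                         gev_variant=cfg.gev_variant,
                         dispersion_domain=cfg.dispersion_domain).as_vector()
    ratios = qs / np.maximum(qh, cfg.ratio_floor)
    diffs = qs - qh
    values = np.concatenate([qh, qs, ratios, diffs])
    names = ([f"q_{m}_hcseq" for m in QUALITY_METRIC_NAMES]
             + [f"q_{m}_sczseq" for m in QUALITY_METRIC_NAMES]
             + [f"q_{m}_ratio" for m in QUALITY_METRIC_NAMES]
             + [f"q_{m}_diff" for m in QUALITY_METRIC_NAMES])
    return values, names


def semantic_features(seq: LabelSequence, config: FeatureConfig | None = None,
                      ) -> tuple[np.ndarray, list[str]]:
    """The 21-dim semantic block (default layout).

    The 12 ordered non-self 2-gram frequencies, the named 3-gram
    frequencies (default ABA, BAB, BCB, CBC), the 4 length-1 frequencies
    and the total run rate (runs per second).
    """
    cfg = config or FeatureConfig()
    runs = compress_runs(seq)
    n_runs = len(runs)
    s1 = subsequence_stats(seq, 1)
    s2 = subsequence_stats(seq, 2) if n_runs >= 2 else None
    s3 = subsequence_stats(seq, 3) if n_runs >= 3 else None
    values = []
    names = []
    for g in cfg.bigrams:
        values.append(s2.f(g) if s2 else 0.0)
        names.append(f"s_f2_{g}")
    for g in cfg.trigrams:
        values.append(s3.f(g) if s3 else 0.0)
        names.append(f"s_f3_{g}")
    for st in STATES:
        values.append(s1.f(st))
        names.append(f"s_f1_{st}")
    values.append(n_runs / seq.duration_s)
    names.append("s_run_rate")
    return np.asarray(values), names


def assemble_features(segment: EEGSegment, dual: DualSequences,
                      hc_t: TemplateSet, scz_t: TemplateSet,
                      config: FeatureConfig | None = None) -> FeatureVector:
    """Concatenate quality | semantic | temporal blocks (default 49 dims)."""
    cfg = config or FeatureConfig()
    qv, qn = quality_features(dual, segment, hc_t, scz_t, cfg)
    sv, sn = semantic_features(
        dual.seq_by_template_group[cfg.semantic_sequence], cfg)
    tf = temporal_features(dual.seq_by_template_group[cfg.temporal_sequence])
    tv = tf.as_vector()
    tn = ([f"t_md_{s}" for s in STATES] + [f"t_ops_{s}" for s in STATES]
          + [f"t_tcr_{s}" for s in STATES])
    values = np.concatenate([qv, sv, tv])
    names = qn + sn + tn

    def cols(prefix: str) -> list[int]:
        return [j for j, n in enumerate(names) if n.startswith(prefix)]

    blocks: dict[str, list[int]] = {
        "quality": list(range(len(qn))),
        "semantic": list(range(len(qn), len(qn) + len(sn))),
        "temporal": list(range(len(qn) + len(sn), len(names))),
    }
    for m in QUALITY_METRIC_NAMES:
        blocks[f"quality_{m}"] = cols(f"q_{m}_")
    blocks["semantic_f2"] = cols("s_f2_")
    blocks["semantic_f3"] = cols("s_f3_")
    blocks["semantic_f1"] = cols("s_f1_") + cols("s_run_rate")
    for t in ("md", "ops", "tcr"):
        blocks[f"temporal_{t}"] = cols(f"t_{t}_")
    return FeatureVector(values=values, names=names, blocks=blocks)


def feature_matrix(segments: list[EEGSegment], hc_t: TemplateSet,
                   scz_t: TemplateSet, config: FeatureConfig | None = None,
                   mode: str = "correlation",
                   ) -> tuple[np.ndarray, list[str], dict[str, list[int]],
                              np.ndarray, list[str]]:
    """Assemble the cohort feature matrix.

    Returns (X, feature names, block slices, y, subject ids) where y is 1
    for SCZ segments and 0 otherwise.
    """
    from .dual import build_dual_sequences
    rows, y, subjects = [], [], []
    names: list[str] = []
    blocks: dict[str, slice] = {}
    for seg in segments:
        dual = build_dual_sequences(seg, hc_t, scz_t, mode=mode)
        fv = assemble_features(seg, dual, hc_t, scz_t, config)
        rows.append(fv.values)
        names, blocks = fv.names, fv.blocks
        y.append(1 if seg.group == "SCZ" else 0)
        subjects.append(seg.subject_id)
    return np.vstack(rows), names, blocks, np.asarray(y), subjects


def brute_force_gram_counts(states: str, l: int) -> dict[str, int]:
    """Independent n-gram counting oracle: enumerate every window (tests)."""
    out: dict[str, int] = {}
    for i in range(len(states) - l + 1):
        g = states[i:i + l]
        out[g] = out.get(g, 0) + 1
    return out
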