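"""Dual-template extraction: per-subject DBSCAN, per-group K-means.

Stage 1 clusters each subject's GFP-peak topographies with DBSCAN
(density-based, resilient to outlying maps), adapting radius and density
threshold until exactly four clusters form; the cluster means are that
subject's candidate templates.  Stage 2 pools the candidates of each
group and re-clusters them with a polarity-invariant K-means (similarity
= absolute spatial correlation) into the group's four microstate
templates.  Fitting every segment against both groups' template sets
yields the dual label sequences whose quality difference carries the
group signal.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import DBSCAN

from .core import (N_STATES, LabelSequence, PeakMapSet, TemplateSet,
                   assign_labels, extract_peak_maps, _normalize_maps)
from .preprocess import EEGRecord, EEGSegment

logger = logging.getLogger(__name__)

#: Deterministic DBSCAN search schedule: radius quantiles (percent of the
#: pairwise-distance distribution) crossed with density thresholds.
RADIUS_QUANTILES = tuple(range(5, 100, 5))
MINPTS_GRID = (5, 10, 20)


class AdaptiveClusteringError(RuntimeError):
    """DBSCAN search budget exhausted without exactly four clusters."""

    def __init__(self, closest_count: int):
        super().__init__(
            f"no (r, minPts) combination yielded 4 clusters "
            f"(closest achieved: {closest_count})")
        self.closest_count = closest_count


@dataclass
class CandidateTemplates:
    """One subject's four candidate maps from the density-based stage."""

    subject_id: str
    maps: np.ndarray  # (4, n_channels), zero-mean unit-norm
    dbscan_params_used: tuple[float, int]
    n_search_iterations: int


def _signed_mean(members: np.ndarray) -> np.ndarray:
    """Average maps after sign-aligning each member to the first one."""
    signs = np.sign(members @ members[0])
    signs[signs == 0] = 1.0
    m = (members * signs[:, None]).mean(axis=0)
    return m


def subject_templates(peak_maps: PeakMapSet, r0: float | None = None,
                      minpts0: int = 5, max_iter: int = 60,
                      max_maps: int = 1500, seed: int = 0) -> CandidateTemplates:
    """Adaptive DBSCAN over one subject's normalized GFP-peak maps.

    Walks a deterministic grid (radius = quantiles of the pairwise
    Euclidean distance distribution x minPts in {minpts0, 10, 20}) and
    accepts the first combination producing exactly four clusters, each
    with at least minPts members.  Noise points are excluded from the
    cluster means.  If ``r0`` is given it is tried first.  Very large
    peak sets are deterministically subsampled to ``max_maps`` before the
    quadratic distance computation.
    """
    maps = np.asarray(peak_maps.maps, dtype=float)
    if maps.shape[0] < 4 * minpts0:
        raise ValueError(
            f"need at least {4 * minpts0} peak maps, got {maps.shape[0]}")
    maps = _normalize_maps(maps)
    if maps.shape[0] > max_maps:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(maps.shape[0], size=max_maps, replace=False))
        maps = maps[keep]
    dist = squareform(pdist(maps))
    radii = np.percentile(dist[np.triu_indices_from(dist, k=1)],
                          RADIUS_QUANTILES)
    minpts_grid = list(dict.fromkeys([minpts0, *MINPTS_GRID]))
    schedule: list[tuple[float, int]] = []
    if r0 is not None:
        schedule.append((float(r0), minpts0))
    schedule.extend((float(r), mp) for r in radii for mp in minpts_grid)
    closest = 0
    for it, (r, mp) in enumerate(schedule[:max_iter], start=1):
        labels = DBSCAN(eps=r, min_samples=mp,
                        metric="precomputed").fit_predict(dist)
        ids, counts = np.unique(labels[labels >= 0], return_counts=True)
        if len(ids) == 4 and counts.min() >= mp:
            centers = np.stack([_signed_mean(maps[labels == c]) for c in ids])
            centers = _normalize_maps(centers)
            n_noise = int(np.sum(labels < 0))
            if n_noise:
                logger.debug("%d noise maps excluded from candidate means",
                             n_noise)
            return CandidateTemplates(
                subject_id="", maps=centers,
                dbscan_params_used=(float(r), int(mp)),
                n_search_iterations=it)
        if abs(len(ids) - 4) < abs(closest - 4) or closest == 0:
            closest = len(ids)
    raise AdaptiveClusteringError(closest)


def _polarity_kmeans(x: np.ndarray, seed: int, n_init: int = 20,
                     max_iter: int = 100, tol: float = 1e-8,
                     k: int = N_STATES) -> tuple[np.ndarray, float]:
    """K-means with absolute-correlation similarity over unit-norm maps.

    Members anti-correlated with their center contribute sign-flipped to
    the center update; an emptied cluster is re-seeded from the member
    most dissimilar to all current centers.  Returns (centers, objective)
    of the best restart, where the objective is the within-cluster
    absolute-correlation sum (non-decreasing across iterations).
    """
    rng = np.random.default_rng(seed)
    best_centers, best_obj = None, -np.inf
    n = x.shape[0]
    for _ in range(n_init):
        centers = x[rng.choice(n, size=k, replace=False)].copy()
        for _ in range(max_iter):
            sim = np.abs(x @ centers.T)          # (n, k)
            assign = np.argmax(sim, axis=1)
            for c in range(k):
                if not np.any(assign == c):
                    worst = int(np.argmin(sim.max(axis=1)))
                    logger.debug("re-seeding empty cluster %d", c)
                    assign[worst] = c
            new_centers = centers.copy()
            for c in range(k):
                members = x[assign == c]
                signs = np.sign(members @ centers[c])
                signs[signs == 0] = 1.0
                m = (members * signs[:, None]).sum(axis=0)
                m -= m.mean()
                nm = np.linalg.norm(m)
                if nm > 1e-300:
                    new_centers[c] = m / nm
            shift = max(min(np.linalg.norm(new_centers[c] - centers[c]),
                            np.linalg.norm(new_centers[c] + centers[c]))
                        for c in range(k))
            centers = new_centers
            if shift < tol:
                break
        obj = float(np.abs(x @ centers.T).max(axis=1).sum())
        if obj > best_obj:
            best_obj, best_centers = obj, centers
    return best_centers, best_obj


def group_templates(candidates: list[CandidateTemplates], group: str,
                    seed: int = 0, n_init: int = 20) -> TemplateSet:
    """Pool the group's candidate maps and K-means them into 4 templates.

    Similarity is absolute spatial correlation (polarity-invariant);
    centers are zero-meaned and unit-normed.  Deterministic under a fixed
    seed (best of ``n_init`` seeded restarts).
    """
    if len(candidates) < 2:
        raise ValueError("need candidates from at least 2 subjects")
    x = _normalize_maps(np.vstack([c.maps for c in candidates]))
    centers, _ = _polarity_kmeans(x, seed=seed, n_init=n_init)
    # channel names are carried by the caller's template sets; use generic
    names = [f"ch{i:02d}" for i in range(x.shape[1])]
    return TemplateSet(centers, names, group_tag=group)


def canonical_labels(templates: TemplateSet,
                     reference: TemplateSet | None = None) -> TemplateSet:
    """Relabel a template set A-D to best match a reference set.

    Solves the one-to-one assignment maximizing total absolute spatial
    correlation over the 4! possible labelings (via the Hungarian
    algorithm).  Without an explicit reference a fixed built-in reference
    set for the same channel count is used, so labelings are reproducible
    across runs and cohorts.
    """
    if reference is None:
        reference = default_reference(templates.n_channels)
    if templates.n_channels != reference.n_channels:
        raise ValueError("channel count mismatch with reference")
    sim = np.abs(reference.maps @ templates.maps.T)  # (ref k, candidate j)
    _, cols = linear_sum_assignment(-sim)
    out = TemplateSet(templates.maps[cols], list(templates.channel_names),
                      templates.group_tag)
    return out


def default_reference(n_channels: int) -> TemplateSet:
    """Fixed built-in labeling reference (deterministic per channel count)."""
    from .synthetic import make_group_templates
    hc, _ = make_group_templates(n_channels=n_channels,
                                 perturb_strength=0.0,
                                 perturb_classes=frozenset(),
                                 seed=20240404)
    return TemplateSet(hc.maps, list(hc.channel_names), "synthetic")


def template_correlation(set1: TemplateSet, set2: TemplateSet) -> np.ndarray:
    """Per-class |Pearson r| between corresponding maps of two sets.

    Assumes aligned labels (run :func:`canonical_labels` first if not).
    Zero-mean unit-norm maps make Pearson r the plain dot product.
    """
    return np.abs(np.einsum("kc,kc->k", set1.maps, set2.maps))


@dataclass
class DualSequences:
    """The two label sequences of one segment (HC and SCZ template sets)."""

    seq_by_template_group: dict[str, LabelSequence]

    def __post_init__(self) -> None:
        lens = {s.n_samples for s in self.seq_by_template_group.values()}
        if len(lens) > 1:
            raise ValueError("dual sequences must have equal length")

    @property
    def pairing_types(self) -> dict[str, str]:
        return {g: s.pairing_type for g, s in self.seq_by_template_group.items()}


def build_dual_sequences(segment: EEGSegment, hc_templates: TemplateSet,
                         scz_templates: TemplateSet,
                         mode: str = "correlation") -> DualSequences:
    """Backfit one segment against both template sets.

    For a segment of known group the two sequences carry the matched and
    mismatched pairing types (e.g. an HC segment yields HH and SH); for
    unknown data both are tagged unknown.
    """
    return DualSequences({
        "HC": assign_labels(segment, hc_templates, mode=mode),
        "SCZ": assign_labels(segment, scz_templates, mode=mode),
    })


def fit_group_templates(records: list[EEGRecord], group: str,
                        r0: float | None = None, minpts0: int = 5,
                        seed: int = 0, max_maps: int = 1500,
                        reference: TemplateSet | None = None) -> TemplateSet:
    """Full stage-1 + stage-2 template extraction for one group.

    Each record's GFP-peak maps go through the adaptive DBSCAN; a subject
    whose density search fails falls back to a seeded polarity-invariant
    K-means with K=4 (logged).  The pooled candidates are re-clustered by
    :func:`group_templates` and canonically labeled A-D.
    """
    cands: list[CandidateTemplates] = []
    for i, rec in enumerate(records):
        peaks = extract_peak_maps(rec.data, list(rec.channel_names))
        try:
            cand = subject_templates(peaks, r0=r0, minpts0=minpts0,
                                     max_maps=max_maps, seed=seed + i)
        except AdaptiveClusteringError as e:
            logger.warning("subject %s: %s; falling back to K-means",
                           rec.subject_id, e)
            maps = _normalize_maps(peaks.maps)
            if maps.shape[0] > max_maps:
                rng = np.random.default_rng(seed + i)
                maps = maps[np.sort(rng.choice(maps.shape[0], max_maps,
                                               replace=False))]
            centers, _ = _polarity_kmeans(maps, seed=seed + i, n_init=5)
            cand = CandidateTemplates(rec.subject_id, _normalize_maps(centers),
                                      (np.nan, minpts0), 0)
        cand.subject_id = rec.subject_id
        cands.append(cand)
    ts = group_templates(cands, group, seed=seed)
    ts = TemplateSet(ts.maps, list(records[0].channel_names), group)
    return canonical_labels(ts, reference)


def brute_force_label_assignment(templates: TemplateSet,
                                 reference: TemplateSet) -> tuple[int, ...]:
    """Exhaustive 4!-search for the optimal labeling (test oracle).

    Returns the permutation p with row k of the relabeled set =
    templates.maps[p[k]].
    """
    sim = np.abs(reference.maps @ templates.maps.T)
    best, best_val = None, -np.inf
    for perm in itertools.permutations(range(N_STATES)):
        val = sum(sim[k, perm[k]] for k in range(N_STATES))
        if val > best_val:
            best, best_val = perm, val
    return best
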