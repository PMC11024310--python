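"""Microstate core operations: GFP, GFP-peak map extraction, backfitting.

The central objects are the four-map template set (canonical microstate
classes A-D) and the per-sample label sequence obtained by assigning every
EEG sample to its most spatially similar template.  Spatial similarity is
polarity-invariant absolute correlation, the resting-state convention: a
topography and its sign-flipped counterpart express the same generator
configuration.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EEGSegment

logger = logging.getLogger(__name__)

#: Canonical microstate class labels, in fixed order.
STATES: tuple[str, ...] = ("A", "B", "C", "D")
N_STATES = len(STATES)

#: Pairing taxonomy: (template group, data group) -> sequence type.
#: First letter encodes the template group, second the data group;
#: SS/HH are the matched pairings, SH/HS the mismatched ones.
_GROUP_CODE = {"HC": "H", "SCZ": "S"}


def pairing_type(template_group: str, data_group: str) -> str:
    """Sequence pairing type (SS/SH/HS/HH) or ``unknown``."""
    t = _GROUP_CODE.get(template_group)
    d = _GROUP_CODE.get(data_group)
    if t is None or d is None:
        return "unknown"
    return t + d


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Zero-mean each map across channels, then scale to unit norm."""
    maps = np.asarray(maps, dtype=float)
    maps = maps - maps.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(maps, axis=-1, keepdims=True)
    if np.any(norms < 1e-300):
        raise ValueError("cannot normalize an all-constant map")
    return maps / norms


@dataclass
class TemplateSet:
    """Exactly four labeled microstate maps (A-D) plus a group tag.

    Maps are stored as a (4, n_channels) array; rows are zero-mean and
    unit-norm (enforced at construction), ordered as :data:`STATES`.
    """

    maps: np.ndarray
    channel_names: list[str]
    group_tag: str = "synthetic"  # {"HC", "SCZ", "synthetic"}

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.shape != (N_STATES, len(self.channel_names)):
            raise ValueError(
                f"expected maps of shape (4, {len(self.channel_names)}), "
                f"got {self.maps.shape}"
            )
        self.maps = _normalize_maps(self.maps)

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def map_for(self, state: str) -> np.ndarray:
        return self.maps[STATES.index(state)]

    def relabeled(self, perm: np.ndarray) -> "TemplateSet":
        """Return a copy whose row k holds the map previously at perm[k]."""
        return TemplateSet(self.maps[np.asarray(perm)], list(self.channel_names),
                           self.group_tag)


@dataclass
class LabelSequence:
    """Per-sample microstate labels for one segment under one template set."""

    labels: np.ndarray  # int array, values index STATES
    fs: float
    template_group: str = "unknown"
    data_group: str = "unknown"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D array")

    @property
    def pairing_type(self) -> str:
        return pairing_type(self.template_group, self.data_group)

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def duration_s(self) -> float:
        return self.labels.size / self.fs

    def as_states(self) -> str:
        """Label track as a string over 'ABCD'."""
        return "".join(STATES[i] for i in self.labels)


@dataclass
class PeakMapSet:
    """Topographies at strict local maxima of the GFP curve."""

    maps: np.ndarray          # (n_peaks, n_channels)
    peak_indices: np.ndarray  # strictly increasing, strictly interior
    channel_names: list[str] = field(default_factory=list)

    @property
    def n_peaks(self) -> int:
        return self.maps.shape[0]


def gfp(data: np.ndarray | EEGSegment) -> np.ndarray:
    """Global field power: per-sample standard deviation across channels.

    GFP(t) = sqrt( sum_i (v_i(t) - vbar(t))^2 / N ), the population std of
    the instantaneous potential map.  Invariant to adding any constant to
    all channels at a time point.
    """
    x = data.data if isinstance(data, EEGSegment) else np.asarray(data, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (n_channels >= 2, n_samples) matrix")
    return x.std(axis=0, ddof=0)


def extract_peak_maps(segment: EEGSegment | np.ndarray,
                      channel_names: list[str] | None = None) -> PeakMapSet:
    """Extract topographies at strict interior local maxima of the GFP.

    A sample t qualifies iff G(t-1) < G(t) > G(t+1); endpoints are never
    included.  A monotone GFP curve yields an empty set.
    """
    if isinstance(segment, EEGSegment):
        x = segment.data
        names = list(segment.channel_names)
    else:
        x = np.asarray(segment, float)
        names = channel_names or [f"ch{i}" for i in range(x.shape[0])]
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples to define interior peaks")
    g = gfp(x)
    interior = np.arange(1, g.size - 1)
    is_peak = (g[interior] > g[interior - 1]) & (g[interior] > g[interior + 1])
    idx = interior[is_peak]
    if idx.size == 0:
        logger.info("GFP has no strict interior maxima; empty peak set")
    return PeakMapSet(maps=x[:, idx].T.copy(), peak_indices=idx,
                      channel_names=names)


def assign_labels(segment: EEGSegment, templates: TemplateSet,
                  mode: str = "correlation") -> LabelSequence:
    """Backfit a segment against a template set (winner-take-all).

    mode="correlation" (default): each sample gets the label of the
    template with the largest absolute spatial correlation
    |V_t' Gamma_k| / (||V_t|| ||Gamma_k||), computed on channel-demeaned
    vectors, hence polarity-invariant.

    mode="literal": audit variant assigning
    argmin_k |V_t'V_t - V_t'Gamma_k| on the raw vectors.  Kept because it
    is the printed form of the assignment rule in some descriptions of the
    method, although it is dimensionally odd.

    Zero-spread samples (GFP 0) inherit the previous sample's label (the
    first sample falls back to class A) and are logged.
    """
    if list(segment.channel_names) != list(templates.channel_names):
        if segment.n_channels != templates.n_channels:
            raise ValueError("segment/template channel count mismatch")
    x = segment.data
    xd = x - x.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(xd, axis=0)
    if mode == "correlation":
        score = np.abs(templates.maps @ xd)  # (4, T); templates unit-norm
        labels = np.argmax(score, axis=0)
    elif mode == "literal":
        vv = np.einsum("it,it->t", x, x)
        vg = templates.maps @ x
        labels = np.argmin(np.abs(vv[None, :] - vg), axis=0)
    else:
        raise ValueError(f"unknown assignment mode {mode!r}")
    dead = np.flatnonzero(norms < 1e-12)
    if dead.size:
        logger.warning("%d zero-norm samples inherit previous label", dead.size)
        for t in dead:
            labels[t] = labels[t - 1] if t > 0 else 0
    return LabelSequence(labels=labels, fs=segment.fs,
                         template_group=templates.group_tag,
                         data_group=segment.group)


def compress_runs(seq: LabelSequence | np.ndarray) -> list[tuple[int, int]]:
    """Run-length encode a label track into maximal (state, length) runs.

    Adjacent runs always have distinct states and the lengths sum to the
    sequence length.
    """
    labels = seq.labels if isinstance(seq, LabelSequence) else np.asarray(seq)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(labels[s]), int(e - s)) for s, e in zip(starts, ends)]


def expand_runs(runs: list[tuple[int, int]]) -> np.ndarray:
    """Inverse of :func:`compress_runs`."""
    if not runs:
        raise ValueError("empty run list")
    return np.repeat([s for s, _ in runs], [n for _, n in runs]).astype(np.int8)
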