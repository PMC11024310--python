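"""Classification and evaluation harness.

Protocols: stratified 10-fold cross-validation at segment level (the
within-mix protocol), leave-one-pair-out across subjects (one patient +
one control held out per round), a window-length sweep running the full
pipeline per window, and set-to-1 ablation importance of feature blocks.
Feature standardization (z-score) is fitted on training data only and is
part of the pre-trained model, so ablated features pass through the
training-time scaler.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.model_selection import StratifiedKFold, train_test_split

from .core import TemplateSet
from .features import FeatureConfig, feature_matrix
from .preprocess import EEGRecord, segment as cut_segments

logger = logging.getLogger(__name__)


@dataclass
class ClassifierConfig:
    """Classifier family and hyperparameters.

    Defaults: KNN with Euclidean distance and 10 neighbours; SVM with a
    Gaussian kernel of kernel scale 6 (inputs divided by the scale before
    the RBF, i.e. gamma = 1/scale^2); MLP with hidden layers 32 x 16 and
    tanh activation (the input layer is sized to the actual feature
    dimension).  Standardization is on by default because the feature
    blocks mix units (ms, fractions, squared potentials).
    """

    kind: str = "knn"  # {"knn", "svm", "mlp"}
    knn_neighbors: int = 10
    svm_kernel_scale: float = 6.0
    mlp_hidden: tuple[int, int] = (32, 16)
    standardize: bool = True
    seed: int = 0

    def build(self) -> Pipeline:
        if self.kind == "knn":
            clf = KNeighborsClassifier(n_neighbors=self.knn_neighbors,
                                       metric="euclidean")
        elif self.kind == "svm":
            clf = SVC(kernel="rbf", gamma=1.0 / self.svm_kernel_scale ** 2,
                      random_state=self.seed)
        elif self.kind == "mlp":
            clf = MLPClassifier(hidden_layer_sizes=self.mlp_hidden,
                                activation="tanh", max_iter=800,
                                random_state=self.seed)
        else:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        steps = []
        if self.standardize:
            steps.append(("scale", StandardScaler()))
        steps.append(("clf", clf))
        return Pipeline(steps)


@dataclass
class FoldMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    tn: int
    fp: int
    fn: int


@dataclass
class EvalResult:
    """Pooled metrics plus per-fold breakdown for one protocol run.

    Sensitivity = correctly identified patients / true patients;
    specificity is the analogue for non-patients.  The positive class is
    SCZ (label 1).
    """

    accuracy: float
    sensitivity: float
    specificity: float
    protocol: str
    per_fold: list[FoldMetrics] = field(default_factory=list)
    window_s: float | None = None


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> FoldMetrics:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    p, n = tp + fn, tn + fp
    return FoldMetrics(
        accuracy=(tp + tn) / max(p + n, 1),
        sensitivity=tp / p if p else float("nan"),
        specificity=tn / n if n else float("nan"),
        tp=tp, tn=tn, fp=fp, fn=fn,
    )


def _assert_no_leakage(train_ids: set, test_ids: set) -> None:
    overlap = train_ids & test_ids
    if overlap:
        raise RuntimeError(f"train/test leakage: {sorted(overlap)[:5]} ...")


def kfold_eval(x: np.ndarray, y: np.ndarray, config: ClassifierConfig,
               k: int = 10, seed: int = 0) -> EvalResult:
    """Stratified k-fold CV with per-fold standardization; pooled metrics."""
    x = np.asarray(x, float)
    y = np.asarray(y, int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"need at least k={k} samples per class, "
                         f"got {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold: list[FoldMetrics] = []
    pooled_true, pooled_pred = [], []
    for tr, te in skf.split(x, y):
        _assert_no_leakage(set(tr), set(te))
        model = config.build()
        model.fit(x[tr], y[tr])
        pred = model.predict(x[te])
        per_fold.append(_confusion(y[te], pred))
        pooled_true.append(y[te])
        pooled_pred.append(pred)
    pooled = _confusion(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    return EvalResult(accuracy=pooled.accuracy, sensitivity=pooled.sensitivity,
                      specificity=pooled.specificity, protocol="kfold",
                      per_fold=per_fold)


def leave_one_pair_out(x: np.ndarray, y: np.ndarray, subjects: list[str],
                       config: ClassifierConfig,
                       ) -> tuple[list[EvalResult], EvalResult]:
    """Cross-subject protocol: hold out one (patient, control) pair per round.

    Pair i is the i-th SCZ subject with the i-th HC subject (sorted ids);
    no segment of a held-out subject ever appears in training.  Returns
    the per-pair results and the average.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, int)
    subjects = np.asarray(subjects)
    scz_subj = sorted(set(subjects[y == 1]))
    hc_subj = sorted(set(subjects[y == 0]))
    if len(scz_subj) != len(hc_subj):
        raise ValueError("leave-one-pair-out needs equal subject counts "
                         f"per group, got {len(scz_subj)} vs {len(hc_subj)}")
    for s in np.unique(subjects):
        if np.sum(subjects == s) == 0:  # pragma: no cover - defensive
            raise ValueError(f"subject {s} has zero segments")
    results: list[EvalResult] = []
    for pair_i, (ps, hs) in enumerate(zip(scz_subj, hc_subj)):
        test_mask = (subjects == ps) | (subjects == hs)
        _assert_no_leakage(set(subjects[~test_mask]), set(subjects[test_mask]))
        model = config.build()
        model.fit(x[~test_mask], y[~test_mask])
        pred = model.predict(x[test_mask])
        fm = _confusion(y[test_mask], pred)
        results.append(EvalResult(
            accuracy=fm.accuracy, sensitivity=fm.sensitivity,
            specificity=fm.specificity, protocol="leave_one_pair_out",
            per_fold=[fm]))
        logger.debug("pair %d (%s, %s): acc %.3f", pair_i, ps, hs, fm.accuracy)
    avg = EvalResult(
        accuracy=float(np.mean([r.accuracy for r in results])),
        sensitivity=float(np.mean([r.sensitivity for r in results])),
        specificity=float(np.mean([r.specificity for r in results])),
        protocol="leave_one_pair_out",
    )
    return results, avg


def window_sweep(records: list[EEGRecord], hc_t: TemplateSet,
                 scz_t: TemplateSet, window_grid_s: list[float],
                 config: ClassifierConfig, k: int = 10, seed: int = 0,
                 feature_config: FeatureConfig | None = None,
                 ) -> dict[float, EvalResult]:
    """Run the full pipeline per window length; accuracy-vs-length table."""
    if not window_grid_s:
        raise ValueError("empty window grid")
    out: dict[float, EvalResult] = {}
    for w in window_grid_s:
        segs = [s for rec in records for s in cut_segments(rec, w)]
        x, _, _, y, _ = feature_matrix(segs, hc_t, scz_t, feature_config)
        res = kfold_eval(x, y, config, k=k, seed=seed)
        res.window_s = float(w)
        out[float(w)] = res
    return out


def ablation_importance(x: np.ndarray, y: np.ndarray,
                        blocks: dict[str, list[int]],
                        config: ClassifierConfig, seed: int = 0,
                        test_size: float = 0.3,
                        ) -> dict[str, dict[str, float]]:
    """Set-to-1 block importance with a pre-trained classifier.

    A classifier is trained once on a stratified training split.  For each
    block, the block's raw feature columns in the held-out set are set to
    the constant 1 and re-scored with the pre-trained model (including its
    training-time scaler); importance = full accuracy - ablated accuracy.
    Ablations are independent, so importances do not depend on evaluation
    order.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, int)
    xtr, xte, ytr, yte = train_test_split(
        x, y, test_size=test_size, stratify=y, random_state=seed)
    model = config.build()
    model.fit(xtr, ytr)
    acc_full = _confusion(yte, model.predict(xte)).accuracy
    report: dict[str, dict[str, float]] = {
        "__full__": {"accuracy": acc_full, "importance": 0.0}}
    n_cols = x.shape[1]
    for name, cols in blocks.items():
        cols = np.asarray(cols, int)
        if cols.size == 0 or cols.min() < 0 or cols.max() >= n_cols:
            raise ValueError(f"unknown or invalid block {name!r}")
        x_abl = xte.copy()
        x_abl[:, cols] = 1.0
        acc = _confusion(yte, model.predict(x_abl)).accuracy
        report[name] = {"accuracy": acc, "importance": acc_full - acc}
    return report
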