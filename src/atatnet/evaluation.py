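"""Evaluation protocol and brain-network group-difference analyses.

Covers the repeated stratified five-fold cross-validation with accuracy,
sensitivity, specificity and F1; the ROI-importance procedure (shield one
ROI, re-score the classifier, rank by ascending shielded accuracy); and the
altered-connectivity analysis between diagnostic groups (difference of group
mean FBNs, 90%-quantile threshold on altered strength, top-2% and top-5
reduced/increased edge lists).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._autodiff import no_grad
from .gcc import rescale_pearson
from .phantom import Subject
from .training import ATATModel, ModelConfig, TrainConfig, Trainer

__all__ = [
    "compute_metrics", "cross_validate", "roi_importance",
    "AlteredConnectivityResult", "altered_connectivity", "shield",
]


def compute_metrics(y_true: Sequence[int], y_pred: Sequence[int],
                    positive: int = 1) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and F1 from an explicit confusion table.

    ``positive`` names the label treated as the positive class (by default the
    later disease stage).  Degenerate denominators yield 0 with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty prediction set")
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reported as 0",
                          RuntimeWarning, stacklevel=3)
            return 0.0
        return num / den

    acc = (tp + tn) / y_true.size
    sen = _ratio(tp, tp + fn, "sensitivity")
    spe = _ratio(tn, tn + fp, "specificity")
    precision = _ratio(tp, tp + fp, "precision")
    f1 = 0.0 if precision + sen == 0 else 2 * precision * sen / (precision + sen)
    return {"ACC": acc, "SEN": sen, "SPE": spe, "F1": f1,
            "TP": tp, "TN": tn, "FP": fp, "FN": fn}


def _default_train(model: ATATModel, train_subjects: list[Subject],
                   train_config: TrainConfig) -> None:
    Trainer(model, train_subjects, train_config).fit()


def cross_validate(subjects: list[Subject], model_config: ModelConfig,
                   train_config: TrainConfig, n_folds: int = 5, n_repeats: int = 10,
                   seed: int = 0, path: str = "generated",
                   train_fn: Callable | None = None) -> pd.DataFrame:
    """Repeated stratified k-fold cross-validation with one model fit per fold.

    Returns one row per (repeat, fold) with the four metrics; aggregate with
    ``df[["ACC", "SEN", "SPE", "F1"]].agg(["mean", "sem"])``.
    """
    labels = np.array([s.label for s in subjects])
    classes = sorted(set(labels.tolist()))
    counts = {c: int(np.sum(labels == c)) for c in classes}
    if min(counts.values()) < n_folds:
        raise ValueError(f"every class needs at least {n_folds} members for "
                         f"{n_folds}-fold stratification, got {counts}")
    positive = max(classes)  # later disease stage is the positive class
    train_fn = train_fn or _default_train
    seeds = np.random.SeedSequence(seed).generate_state(n_repeats * (n_folds + 1))
    rows = []
    k = 0
    for repeat in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(seeds[k] % (2 ** 31)))
        k += 1
        for fold, (train_idx, test_idx) in enumerate(skf.split(labels, labels)):
            cfg = ModelConfig(**{**model_config.__dict__,
                                 "seed": int(seeds[k] % (2 ** 31))})
            tcfg = TrainConfig(**{**train_config.__dict__,
                                  "seed": int(seeds[k] % (2 ** 31))})
            k += 1
            model = ATATModel(cfg)
            train_fn(model, [subjects[i] for i in train_idx], tcfg)
            y_true = [subjects[i].label for i in test_idx]
            y_pred = [model.predict(subjects[i], path=path) for i in test_idx]
            metrics = compute_metrics(y_true, y_pred, positive=positive)
            rows.append({"repeat": repeat, "fold": fold, **metrics})
    return pd.DataFrame(rows)


# -------------------------------------------------------------- ROI shielding

def shield(series: np.ndarray, adjacency: np.ndarray, roi: int
           ) -> tuple[np.ndarray, np.ndarray]:
    """Zero ROI ``roi``'s series row and adjacency row/column (diagonal kept 1)."""
    s = np.array(series, copy=True)
    a = np.array(adjacency, copy=True)
    s[roi, :] = 0.0
    a[roi, :] = 0.0
    a[:, roi] = 0.0
    a[roi, roi] = 1.0
    return s, a


def roi_importance(model: ATATModel, test_subjects: list[Subject],
                   path: str = "generated") -> pd.DataFrame:
    """Shield each ROI in turn and rank ROIs by ascending shielded accuracy.

    The most important ROIs are those whose removal hurts classification the
    most (lowest shielded accuracy, hence first after the ascending sort).
    Returns a DataFrame with 1-based ``roi`` indices, ``shielded_acc`` and
    ``rank`` (1 = most important), sorted ascending by accuracy with index
    order breaking ties.
    """
    model.eval()
    n_rois = model.config.n_rois
    pairs = []
    with no_grad():
        for subj in test_subjects:
            if path == "generated":
                f_g = model.generate(subj.volume, subj.embeddings)
                f = np.asarray(f_g.data, dtype=np.float64)
                a = np.asarray(model.cl(f_g).data, dtype=np.float64)
            else:
                f = subj.f_e
                a = rescale_pearson(subj.a_e)
            pairs.append((f, a, subj.label))
        accs = []
        for roi in range(n_rois):
            y_true, y_pred = [], []
            for f, a, label in pairs:
                fs, as_ = shield(f, a, roi)
                probs = np.asarray(model.gcc(as_, fs).data)
                y_true.append(label)
                y_pred.append(model.classes_[int(np.argmax(probs))])
            accs.append(float(np.mean(np.asarray(y_true) == np.asarray(y_pred))))
    frame = pd.DataFrame({"roi": np.arange(1, n_rois + 1), "shielded_acc": accs})
    frame = frame.sort_values(["shielded_acc", "roi"], kind="stable").reset_index(drop=True)
    frame["rank"] = np.arange(1, n_rois + 1)
    return frame


# ------------------------------------------------------ altered connectivity

@dataclass
class AlteredConnectivityResult:
    """Group-difference analysis of mean FBNs (direction: group A -> group B)."""

    difference: np.ndarray                       # mean(A) - mean(B)
    threshold: float                             # 90% quantile of |off-diag D|
    reduced_edges: list[tuple[int, int, float]] = field(default_factory=list)
    increased_edges: list[tuple[int, int, float]] = field(default_factory=list)
    top_edges: list[tuple[int, int, float]] = field(default_factory=list)
    top5_reduced: list[tuple[int, int, float]] = field(default_factory=list)
    top5_increased: list[tuple[int, int, float]] = field(default_factory=list)


def altered_connectivity(group_a: Sequence[np.ndarray], group_b: Sequence[np.ndarray],
                         quantile: float = 0.9, top_fraction: float = 0.02,
                         top_k: int = 5) -> AlteredConnectivityResult:
    """Difference of group-mean FBNs with quantile thresholding and top edge lists.

    Each unordered ROI pair is counted once (upper triangle).  The threshold
    is the ``quantile`` (default 90%) order statistic of the absolute altered
    strengths, with linear interpolation; edges at or above it survive and
    are partitioned by sign (negative difference = reduced, positive =
    increased).  ``top_edges`` holds the ceil(top_fraction * n_pairs) largest
    |difference| edges; ties break lexicographically on (i, j).
    """
    group_a = [np.asarray(m, dtype=np.float64) for m in group_a]
    group_b = [np.asarray(m, dtype=np.float64) for m in group_b]
    if not group_a or not group_b:
        raise ValueError("both groups need at least one matrix")
    shape = group_a[0].shape
    for m in group_a + group_b:
        if m.shape != shape:
            raise ValueError("all connectivity matrices must share one shape")
    diff = np.mean(group_a, axis=0) - np.mean(group_b, axis=0)
    n = shape[0]
    iu, ju = np.triu_indices(n, k=1)
    values = diff[iu, ju]
    absvals = np.abs(values)
    threshold = float(np.quantile(absvals, quantile))
    surviving = absvals >= threshold
    # rank by |difference| descending, ties by (i, j) lexicographic
    order = np.lexsort((ju, iu, -absvals))

    def _edges(mask: np.ndarray) -> list[tuple[int, int, float]]:
        return [(int(iu[k]), int(ju[k]), float(values[k])) for k in order if mask[k]]

    reduced = _edges(surviving & (values < 0))
    increased = _edges(surviving & (values > 0))
    n_top = int(np.ceil(top_fraction * len(values)))
    top = _edges(np.ones_like(surviving))[:n_top]
    return AlteredConnectivityResult(
        difference=diff, threshold=threshold,
        reduced_edges=reduced, increased_edges=increased, top_edges=top,
        top5_reduced=reduced[:top_k], top5_increased=increased[:top_k])
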