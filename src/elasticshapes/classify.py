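"""Distance-based k-NN classification with stratified holdout replicates.

The classifier works directly on a precomputed shape-distance matrix: a
test object receives the majority label of its k nearest training objects.
Evaluation follows the resampling design of outline-classification studies:
many stratified train/test splits, weighted F1 per replicate, and a normal
95% confidence interval over replicates.  Also provided: tuning k over a
grid, and scoring of *unlabeled* partitions (expert-style sorting into
anonymous groups) against ground truth by optimal group-to-class matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score as _sk_f1

__all__ = [
    "DistanceMatrix",
    "SplitPlan",
    "ClassifierConfig",
    "EvaluationReport",
    "DistanceKNN",
    "stratified_splits",
    "knn_predict",
    "weighted_f1",
    "evaluate",
    "tune_k",
    "partition_f1",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise shape distances with object identifiers."""

    values: np.ndarray
    object_ids: list
    method_tag: str = ""

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.object_ids) != V.shape[0]:
            raise ValueError("object_ids must match matrix size")
        if np.any(V < -1e-9) or not np.all(np.isfinite(V)):
            raise ValueError("distances must be finite and non-negative")
        V = 0.5 * (V + V.T)  # symmetrize on load
        np.fill_diagonal(V, 0.0)
        self.values = np.maximum(V, 0.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.object_ids, columns=self.object_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, method_tag: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(float), list(df.index.astype(str)), method_tag)


@dataclass
class SplitPlan:
    """Stratified train/test index sets over replicates."""

    replicates: list  # list of (train_idx, test_idx) integer arrays
    n_replicates: int
    seed: int
    stratified: bool = True


@dataclass
class ClassifierConfig:
    k: int = 5
    k_grid: tuple = tuple(range(3, 13))

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class EvaluationReport:
    f1_mean: float
    f1_ci95: tuple
    per_replicate_f1: list
    confusion: pd.DataFrame
    best_k: int

    def to_dict(self) -> dict:
        return {
            "f1_mean": self.f1_mean,
            "f1_ci95": list(self.f1_ci95),
            "per_replicate_f1": list(self.per_replicate_f1),
            "best_k": self.best_k,
        }


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def _train_counts_from_fraction(class_sizes: pd.Series, fraction: float) -> dict:
    """Largest-remainder allocation of round(fraction * n) training slots."""
    total = int(round(fraction * class_sizes.sum()))
    raw = class_sizes * fraction
    base = np.floor(raw).astype(int)
    base = base.clip(lower=1)
    remainder = total - base.sum()
    if remainder > 0:
        order = (raw - np.floor(raw)).sort_values(ascending=False).index
        for cls in list(order)[: int(remainder)]:
            if base[cls] < class_sizes[cls] - 1:
                base[cls] += 1
    return {c: min(int(base[c]), int(class_sizes[c]) - 1) for c in class_sizes.index}


def stratified_splits(
    labels,
    train_fraction: float | None = None,
    train_counts: int | dict | None = None,
    n_replicates: int = 100,
    seed: int = 0,
) -> SplitPlan:
    """Stratified holdout replicates.

    Per replicate, the configured number of training objects per class is
    sampled without replacement (proportional to class size when a
    ``train_fraction`` is given); the remainder forms the test set.  Every
    class keeps at least one object on each side.
    """
    labels = pd.Series(list(labels))
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValueError("every class needs at least 2 members")
    if (train_fraction is None) == (train_counts is None):
        raise ValueError("give exactly one of train_fraction or train_counts")
    if train_fraction is not None:
        if not 0 < train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        counts = _train_counts_from_fraction(sizes, train_fraction)
    elif isinstance(train_counts, dict):
        counts = {c: int(train_counts[c]) for c in sizes.index}
    else:
        counts = {c: int(train_counts) for c in sizes.index}
    for c, cnt in counts.items():
        if cnt < 1 or cnt >= sizes[c]:
            raise ValueError(
                f"class {c!r} has {sizes[c]} members; cannot train on {cnt} and still test"
            )
    rng = np.random.default_rng(seed)
    replicates = []
    by_class = {c: np.flatnonzero(labels.to_numpy() == c) for c in sizes.index}
    for _ in range(n_replicates):
        train: list[int] = []
        for c in sizes.index:
            train.extend(rng.choice(by_class[c], size=counts[c], replace=False))
        train_idx = np.sort(np.array(train, dtype=int))
        mask = np.ones(len(labels), dtype=bool)
        mask[train_idx] = False
        replicates.append((train_idx, np.flatnonzero(mask)))
    return SplitPlan(replicates, n_replicates, seed, stratified=True)


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------


class DistanceKNN:
    """k-nearest-neighbour classifier on a precomputed distance matrix.

    scikit-learn style: ``fit(D_train, y)`` stores training labels (D_train
    is ignored beyond shape checks — the metric lives in the matrix), and
    ``predict(D_test_train)`` classifies rows of test-to-train distances.

    Majority vote among the k nearest training objects; a tie between
    classes is broken in favour of the tied class whose single nearest
    neighbour is closest.  Equal distances at the k-th neighbour are
    resolved by stable training order, so predictions are deterministic.
    """

    def __init__(self, k: int = 5):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k}

    def set_params(self, **params) -> "DistanceKNN":
        for key, v in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, v)
        return self

    def fit(self, D_train: np.ndarray, y) -> "DistanceKNN":
        y = np.asarray(y)
        D_train = np.asarray(D_train, dtype=float)
        if D_train.shape[1] != len(y):
            raise ValueError("training matrix columns must match labels")
        if self.k > len(y):
            raise ValueError(f"k={self.k} exceeds {len(y)} training objects")
        self.classes_ = np.unique(y)
        self.y_ = y
        return self

    def predict(self, D_test_train: np.ndarray) -> np.ndarray:
        if not hasattr(self, "y_"):
            raise RuntimeError("DistanceKNN is not fitted")
        D = np.atleast_2d(np.asarray(D_test_train, dtype=float))
        preds = []
        for row in D:
            order = np.argsort(row, kind="stable")[: self.k]
            votes = self.y_[order]
            classes, counts = np.unique(votes, return_counts=True)
            top = counts.max()
            tied = classes[counts == top]
            if len(tied) == 1:
                preds.append(tied[0])
            else:
                # nearest single neighbour among the tied classes wins
                best_cls, best_d = None, np.inf
                for cls in tied:
                    dmin = row[order][votes == cls].min()
                    if dmin < best_d:
                        best_d, best_cls = dmin, cls
                preds.append(best_cls)
        return np.asarray(preds)


def knn_predict(D, train_indices, train_labels, test_indices, k: int) -> np.ndarray:
    """Functional wrapper over :class:`DistanceKNN` for index-based use."""
    V = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    train_indices = np.asarray(train_indices, dtype=int)
    test_indices = np.asarray(test_indices, dtype=int)
    if np.intersect1d(train_indices, test_indices).size:
        raise ValueError("train and test indices overlap")
    clf = DistanceKNN(k=k).fit(V[np.ix_(train_indices, train_indices)], train_labels)
    return clf.predict(V[np.ix_(test_indices, train_indices)])


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def weighted_f1(true_labels, predicted_labels) -> float:
    """Support-weighted mean of per-class F1 = 2PR/(P+R)."""
    t = np.asarray(list(true_labels))
    p = np.asarray(list(predicted_labels))
    if t.size == 0 or t.shape != p.shape:
        raise ValueError("label sequences must be non-empty and equal length")
    return float(_sk_f1(t, p, average="weighted", zero_division=0))


def evaluate(D, labels, plan: SplitPlan, cfg: ClassifierConfig | int) -> EvaluationReport:
    """Replicate-wise weighted F1 plus a pooled confusion matrix.

    The 95% CI is the normal approximation mean +- 1.96 sd / sqrt(R) over
    replicates; confusion counts are pooled over all replicates' test
    predictions.
    """
    if isinstance(cfg, int):
        cfg = ClassifierConfig(k=cfg)
    labels = np.asarray(list(labels))
    V = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    if V.shape[0] != len(labels):
        raise ValueError("distance matrix and labels disagree in size")
    classes = np.unique(labels)
    scores = []
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    for train_idx, test_idx in plan.replicates:
        pred = knn_predict(V, train_idx, labels[train_idx], test_idx, cfg.k)
        truth = labels[test_idx]
        scores.append(weighted_f1(truth, pred))
        pooled += _sk_confusion(truth, pred, labels=classes)
    scores_arr = np.asarray(scores)
    mean = float(scores_arr.mean())
    half = 1.96 * scores_arr.std(ddof=1) / np.sqrt(len(scores_arr)) if len(scores_arr) > 1 else 0.0
    confusion = pd.DataFrame(pooled, index=classes, columns=classes)
    return EvaluationReport(mean, (mean - half, mean + half), scores, confusion, cfg.k)


def tune_k(D, labels, plan: SplitPlan, k_grid=range(3, 13)) -> int:
    """k in the grid maximizing mean weighted F1 (ties -> smallest k)."""
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("empty k grid")
    best_k, best_f1 = None, -1.0
    for k in sorted(k_grid):
        f1 = evaluate(D, labels, plan, ClassifierConfig(k=k)).f1_mean
        if f1 > best_f1 + 1e-12:
            best_k, best_f1 = k, f1
    return int(best_k)


def partition_f1(truth_labels, partition) -> float:
    """Score an unlabeled partition against ground-truth classes.

    ``partition`` maps object -> anonymous group (dict) or is a sequence of
    group ids aligned with ``truth_labels``.  Each group is matched
    one-to-one to a distinct class so that the weighted F1 is maximal
    (linear assignment over per-pair weighted-F1 contributions), and that
    F1 is returned.  This mirrors how an expert's unlabeled sorting of
    objects into folders is compared with the true classification.
    """
    if isinstance(partition, dict):
        objects = list(partition.keys())
        groups = np.asarray([partition[o] for o in objects])
        if isinstance(truth_labels, dict):
            truth = np.asarray([truth_labels[o] for o in objects])
        else:
            raise ValueError("with a dict partition, truth_labels must also be a dict")
    else:
        truth = np.asarray(list(truth_labels))
        groups = np.asarray(list(partition))
    if truth.shape != groups.shape or truth.size == 0:
        raise ValueError("partition must cover exactly the labelled objects")
    classes = np.unique(truth)
    group_ids = np.unique(groups)
    if len(group_ids) > len(classes):
        raise ValueError("more groups than ground-truth classes")
    n = truth.size
    # weight[g, c]: weighted-F1 contribution if group g is named class c
    W = np.zeros((len(group_ids), len(classes)))
    for gi, g in enumerate(group_ids):
        in_g = groups == g
        for ci, c in enumerate(classes):
            in_c = truth == c
            overlap = np.sum(in_g & in_c)
            denom = in_g.sum() + in_c.sum()
            W[gi, ci] = (in_c.sum() / n) * (2 * overlap / denom) if denom else 0.0
    rows, cols = linear_sum_assignment(-W)
    return float(W[rows, cols].sum())
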