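"""K-nearest-neighbour classification with repeated stratified holdout.

The classifier is deliberately plain KNN (default k = 10, Euclidean distance):
a query is assigned the majority label among its k nearest training rows.
Tie-breaks are fixed for determinism: a majority tie falls to the label of the
single nearest neighbour, and neighbours at exactly equal distance are taken
in training-row order (stable sort).

Validation is repeated stratified holdout: a fraction (default 0.2) of rows is
held out for testing, stratified so each stratum keeps roughly its original
class share, and the split/fit/score cycle is repeated (default 10 times) with
sub-seeded partitions; scores are then averaged. Stratification defaults to
(label, subject) so every subject contributes to both sides of every split —
the cross-subject regime — with plain label stratification available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import distance as _sd
from scipy.stats import rankdata

from .entropy import META_COLUMNS
from .metrics import ConfusionMatrix, EvaluationSummary, confusion, summarize

POSITIVE_CLASS = "positive"

#: Distance names accepted for the KNN metric.
SUPPORTED_METRICS = (
    "cityblock",
    "chebyshev",
    "correlation",
    "cosine",
    "euclidean",
    "hamming",
    "jaccard",
    "mahalanobis",
    "minkowski",
    "seuclidean",
    "spearman",
)


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """sqrt(sum((x_i - y_i)^2)) between two equal-length feature vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((x - y) ** 2)))


def _pairwise(queries: np.ndarray, train: np.ndarray, metric: str) -> np.ndarray:
    if metric == "spearman":
        # rank-transform rows, then correlation distance of the ranks
        qr = np.apply_along_axis(rankdata, 1, queries)
        tr = np.apply_along_axis(rankdata, 1, train)
        return _sd.cdist(qr, tr, metric="correlation")
    if metric not in SUPPORTED_METRICS:
        raise ValueError(f"unsupported metric {metric!r}; one of {SUPPORTED_METRICS}")
    return _sd.cdist(queries, train, metric=metric)


@dataclass
class KNNModel:
    """A fitted KNN classifier: stored training rows, labels, k and metric."""

    k: int = 10
    metric: str = "euclidean"
    _X: np.ndarray | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if not 1 <= self.k <= X.shape[0]:
            raise ValueError(f"k = {self.k} outside [1, {X.shape[0]}]")
        self._X, self._y = X, y
        return self

    @property
    def is_fitted(self) -> bool:
        return self._X is not None

    def predict(self, queries: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise ValueError("model is not fitted")
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        if queries.shape[1] != self._X.shape[1]:
            raise ValueError(
                f"query has {queries.shape[1]} features, model expects {self._X.shape[1]}"
            )
        d = _pairwise(queries, self._X, self.metric)
        # stable sort: equal distances resolve to the earlier training row
        order = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        out = np.empty(queries.shape[0], dtype=self._y.dtype)
        for i, nbrs in enumerate(order):
            labels, counts = np.unique(self._y[nbrs], return_counts=True)
            winners = labels[counts == counts.max()]
            if winners.size == 1:
                out[i] = winners[0]
            else:
                out[i] = self._y[nbrs[0]]  # majority tie -> nearest neighbour
        return out


def knn_predict(model: KNNModel, query: np.ndarray) -> str:
    """Label of a single query vector under the fitted model."""
    return model.predict(np.atleast_2d(query))[0]


@dataclass(frozen=True)
class SplitSpec:
    """Repeated-holdout parameters.

    stratify_keys picks the stratification columns: ("label", "subject") keeps
    each subject's class balance in both sets; ("label",) stratifies on class
    alone.
    """

    holdout_fraction: float = 0.2
    repetitions: int = 10
    seed: int = 0
    stratify_keys: tuple[str, ...] = ("label", "subject")

    def __post_init__(self) -> None:
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout fraction must lie in (0, 1)")
        if self.repetitions < 1:
            raise ValueError("at least one repetition required")
        bad = set(self.stratify_keys) - set(META_COLUMNS)
        if bad or not self.stratify_keys:
            raise ValueError(f"stratify keys must be metadata columns, got {self.stratify_keys}")


def holdout_split(
    table: pd.DataFrame, spec: SplitSpec, repetition_index: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One stratified train/test partition, deterministic in (seed, repetition).

    Within each stratum the test share is ``round(n * fraction)`` but at least
    one row; train and test are disjoint and jointly exhaust the table.
    Repetition r draws from a generator seeded ``seed + r``.
    """
    if table.empty:
        raise ValueError("cannot split an empty table")
    rng = np.random.default_rng(spec.seed + repetition_index)
    test_idx: list[np.ndarray] = []
    for key, grp in table.groupby(list(spec.stratify_keys), sort=True):
        n = len(grp)
        if n < 2:
            raise ValueError(f"stratum {key!r} has {n} row(s); need >= 2 to split")
        n_test = min(max(1, round(n * spec.holdout_fraction)), n - 1)
        perm = rng.permutation(n)
        test_idx.append(grp.index.to_numpy()[perm[:n_test]])
    test_index = np.concatenate(test_idx)
    mask = table.index.isin(test_index)
    return table.loc[~mask], table.loc[mask]


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def _matrix(table: pd.DataFrame, cols: list[str]) -> np.ndarray:
    X = table[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains missing or non-finite values")
    return X


def evaluate_once(
    train: pd.DataFrame,
    test: pd.DataFrame,
    k: int = 10,
    metric: str = "euclidean",
    positive_class: str = POSITIVE_CLASS,
) -> ConfusionMatrix:
    """Fit KNN on the train rows, predict the test rows, tally the 2x2 matrix."""
    cols = feature_columns(train)
    model = KNNModel(k=k, metric=metric).fit(
        _matrix(train, cols), train["label"].to_numpy()
    )
    pred = model.predict(_matrix(test, cols))
    return confusion(list(test["label"]), list(pred), positive_class)


def repeated_holdout(
    table: pd.DataFrame,
    spec: SplitSpec,
    k: int = 10,
    metric: str = "euclidean",
    positive_class: str = POSITIVE_CLASS,
) -> EvaluationSummary:
    """Run the split/fit/score cycle ``spec.repetitions`` times and summarise."""
    labels = table["label"].unique()
    if len(labels) < 2:
        raise ValueError("training requires at least two classes")
    matrices = []
    for r in range(spec.repetitions):
        train, test = holdout_split(table, spec, repetition_index=r)
        matrices.append(
            evaluate_once(train, test, k=k, metric=metric, positive_class=positive_class)
        )
    return summarize(matrices)
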