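"""Feature-selecting linear SVM with nested-CV model-size selection.

The estimator wraps a soft-margin linear SVM in a feature-selection loop:

1. Partition the cohort into k stratified folds.
2. For each fold, rank features by mRMR on the training portion only, then
   record held-out accuracy when the SVM uses the top r = 1..r_max features.
3. Aggregate to an accuracy curve (mean a_r, sd sigma_r over folds) and pick
   the smallest r whose ``a_r + sigma_r`` reaches the high-water mark
   ``max_r a_r`` (the one-standard-deviation rule: prefer the most
   parsimonious model statistically indistinguishable from the best).
4. Re-rank on the full cohort and train the final linear model on the top
   r* features.

The public surface follows the statsmodels convention: build a
:class:`FeatureSelectingSVM` from data, call :meth:`~FeatureSelectingSVM.fit`
and get a :class:`FSSVMResults` carrying the selected probes, weights, the
accuracy curve and a ``summary()`` table.  The underlying steps are also
exposed as plain functions (:func:`stratified_folds`,
:func:`train_linear_svm`, :func:`accuracy_curve`, :func:`select_r_star`,
:func:`fit_fs_svm`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .datamodel import ExpressionMatrix, LabeledDataset, LinearModel
from .infotheory import RankedFeatures, mrmr_rank

__all__ = [
    "AccuracyCurve",
    "FeatureSelectingSVM",
    "FSSVMResults",
    "FittedFSSVM",
    "stratified_folds",
    "train_linear_svm",
    "predict",
    "accuracy_curve",
    "select_r_star",
    "fit_fs_svm",
]

DEFAULT_FOLDS = 10
DEFAULT_R_MAX = 18
DEFAULT_C = 1.0  # soft-margin constant of the reference SMO configuration
DEFAULT_POOL = 100


# ---------------------------------------------------------------------------
# Cross-validation plumbing


def stratified_folds(d: LabeledDataset, k: int, seed: int) -> list[list[str]]:
    """Partition sample ids into k balanced, class-stratified folds.

    Samples are shuffled within class by a seeded generator and dealt
    round-robin with a running fold pointer, so fold sizes differ by at most
    one and per-class counts across folds differ by at most one.  The same
    seed always yields the same partition.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > d.n_samples:
        raise ValueError(f"cannot split {d.n_samples} samples into {k} folds")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    ptr = 0
    for cls in (True, False):
        idx = np.flatnonzero(d.y == cls)
        if idx.size == 0:
            name = "positive" if cls else "negative"
            raise ValueError(f"{name} class is empty")
        for i in rng.permutation(idx):
            folds[ptr % k].append(int(i))
            ptr += 1
    ids = d.matrix.sample_ids
    return [[ids[i] for i in f] for f in folds]


def _fold_index_sets(d: LabeledDataset, folds: list[list[str]]) -> list[np.ndarray]:
    pos = {s: i for i, s in enumerate(d.matrix.sample_ids)}
    return [np.asarray([pos[s] for s in f], dtype=int) for f in folds]


# ---------------------------------------------------------------------------
# Linear SVM


def train_linear_svm(
    d: LabeledDataset, feature_subset: Sequence[str], c_param: float = DEFAULT_C
) -> LinearModel:
    """Fit a soft-margin linear SVM on the named feature subset.

    Returns the separator as a :class:`LinearModel` (weights plus threshold);
    prediction is the sign of ``w . x + w0`` with ties to the positive class.
    """
    features = list(feature_subset)
    if not features:
        raise ValueError("feature subset is empty")
    idx = [d.matrix.feature_index(f) for f in features]
    X = d.matrix.values[idx].T  # samples x features
    y = d.y.astype(int)
    if y.min() == y.max():
        raise ValueError("training data contains a single class")
    clf = SVC(kernel="linear", C=c_param)
    clf.fit(X, y)
    # classes_ is [0, 1]; positive decision_function -> class 1 (positive)
    return LinearModel(
        features=features,
        weights=clf.coef_[0].copy(),
        threshold=float(clf.intercept_[0]),
        training_stage=d.matrix.stage,
        provenance=f"linear SVM, C={c_param}, n={d.n_samples}",
    )


def predict(m: LinearModel, x) -> np.ndarray:
    """Classify samples with a linear model (positive iff ``w.x + w0 >= 0``)."""
    return m.predict(x)


# ---------------------------------------------------------------------------
# Accuracy curve and the 1-SD rule


@dataclass
class AccuracyCurve:
    """Held-out accuracy as a function of model size r.

    ``mean[i]`` and ``sd[i]`` aggregate the k per-fold accuracies obtained
    with the top ``r_values[i]`` features; ``sd`` is the sample standard
    deviation (divisor k-1).
    """

    r_values: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    folds: int
    fold_accuracies: np.ndarray | None = None  # (k, r_max)
    fold_rankings: list[RankedFeatures] | None = None

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (self.r_values.size == self.mean.size == self.sd.size):
            raise ValueError("r_values, mean and sd must align")
        if np.any(self.sd < 0):
            raise ValueError("standard deviations must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r": self.r_values, "mean_accuracy": self.mean, "sd_accuracy": self.sd}
        )


def select_r_star(curve: AccuracyCurve) -> int:
    """Smallest r whose mean + sd reaches the high-water-mark mean accuracy.

    ``r* = min { r : a_r + sigma_r >= max_r' a_r' }``.  The maximizing r
    always qualifies, so a solution exists; when several r qualify the
    smallest (most parsimonious) wins.
    """
    if curve.mean.size == 0:
        raise ValueError("empty accuracy curve")
    high_water = curve.mean.max()
    ok = curve.mean + curve.sd >= high_water
    return int(curve.r_values[np.argmax(ok)])


def accuracy_curve(
    d: LabeledDataset,
    r_max: int = DEFAULT_R_MAX,
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
    c_param: float = DEFAULT_C,
    pool_size: int | None = DEFAULT_POOL,
    redundancy_weight: float = 1.0,
) -> AccuracyCurve:
    """Nested-CV accuracy curve: per-fold mRMR ranking, then SVM at each r.

    The ranking for fold i uses only the training portion S_-i, so no
    information from the held-out fold leaks into feature selection.
    """
    if r_max < 1 or r_max > d.matrix.n_features:
        raise ValueError(f"r_max must be in 1..{d.matrix.n_features}")
    folds = stratified_folds(d, k, seed)
    fold_idx = _fold_index_sets(d, folds)
    n = d.n_samples
    acc = np.zeros((k, r_max))
    rankings: list[RankedFeatures] = []
    pool = None if pool_size is None else min(pool_size, d.matrix.n_features)
    if pool is not None and pool < r_max:
        pool = r_max
    for i, test_idx in enumerate(fold_idx):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_ds = d.subset_samples(np.flatnonzero(train_mask))
        test_ds = d.subset_samples(test_idx)
        ranking = mrmr_rank(
            train_ds, top_k=r_max, pool_size=pool, redundancy_weight=redundancy_weight
        )
        rankings.append(ranking)
        test_frame = test_ds.matrix.to_frame()
        for r in range(1, r_max + 1):
            model = train_linear_svm(train_ds, ranking.top(r), c_param=c_param)
            pred = model.predict(test_frame) == "positive"
            acc[i, r - 1] = float(np.mean(pred == test_ds.y))
    return AccuracyCurve(
        r_values=np.arange(1, r_max + 1),
        mean=acc.mean(axis=0),
        sd=acc.std(axis=0, ddof=1),
        folds=k,
        fold_accuracies=acc,
        fold_rankings=rankings,
    )


# ---------------------------------------------------------------------------
# Model / Results objects


class FeatureSelectingSVM:
    """Feature-selecting linear SVM over a labeled expression cohort.

    Parameters
    ----------
    dataset
        Z-score-stage cohort (or housekeeping log-ratio stage for the
        reduced single-sample variant).
    r_max
        Largest model size examined by the accuracy curve.
    n_folds
        Stratified cross-validation folds (k).
    c_param
        Soft-margin constant of the linear SVM.
    pool_size
        mRMR redundancy pool (top features by relevance); ``None`` = exact
        greedy over all features.
    redundancy_weight
        Weight of the mRMR redundancy penalty; 0 gives pure relevance
        ranking.

    Examples
    --------
    >>> est = FeatureSelectingSVM(cohort, r_max=10)        # doctest: +SKIP
    >>> res = est.fit(seed=7)                              # doctest: +SKIP
    >>> print(res.summary())                               # doctest: +SKIP
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        r_max: int = DEFAULT_R_MAX,
        n_folds: int = DEFAULT_FOLDS,
        c_param: float = DEFAULT_C,
        pool_size: int | None = DEFAULT_POOL,
        redundancy_weight: float = 1.0,
    ) -> None:
        if dataset.matrix.stage not in ("zscore", "log_actb"):
            raise ValueError(
                "expected a standardized cohort (stage 'zscore' or 'log_actb'), "
                f"got stage {dataset.matrix.stage!r}; run the normalization chain first"
            )
        self.dataset = dataset
        self.r_max = int(r_max)
        self.n_folds = int(n_folds)
        self.c_param = float(c_param)
        self.pool_size = pool_size
        self.redundancy_weight = float(redundancy_weight)

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        labels: "pd.Series | dict[str, str]",
        stage: str = "zscore",
        **kwargs,
    ) -> "FeatureSelectingSVM":
        """Build from a features-in-rows DataFrame and a sample -> label map.

        Labels may be ``"positive"``/``"negative"`` strings or booleans.
        """
        matrix = ExpressionMatrix.from_frame(values, stage=stage)
        if isinstance(labels, pd.Series):
            labels = labels.to_dict()
        norm = {}
        for s, v in labels.items():
            if isinstance(v, (bool, np.bool_)):
                norm[str(s)] = "positive" if v else "negative"
            else:
                norm[str(s)] = str(v)
        ds = LabeledDataset.from_label_map(matrix, norm)
        return cls(ds, **kwargs)

    def fit(self, seed: int = 0) -> "FSSVMResults":
        """Run the full selection procedure; deterministic given the seed."""
        curve = accuracy_curve(
            self.dataset,
            r_max=self.r_max,
            k=self.n_folds,
            seed=seed,
            c_param=self.c_param,
            pool_size=self.pool_size,
            redundancy_weight=self.redundancy_weight,
        )
        r_star = select_r_star(curve)
        ranking = mrmr_rank(
            self.dataset,
            top_k=self.r_max,
            pool_size=None if self.pool_size is None else max(self.pool_size, self.r_max),
            redundancy_weight=self.redundancy_weight,
        )
        model = train_linear_svm(self.dataset, ranking.top(r_star), c_param=self.c_param)
        return FSSVMResults(
            estimator=self,
            r_star=r_star,
            ranking=ranking,
            model=model,
            curve=curve,
            seed=seed,
        )


@dataclass
class FSSVMResults:
    """Fitted feature-selecting SVM: selected probes, weights, diagnostics."""

    estimator: FeatureSelectingSVM
    r_star: int
    ranking: RankedFeatures
    model: LinearModel
    curve: AccuracyCurve
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.model.features) != self.r_star:
            raise ValueError("final model size must equal r*")
        high_water = self.curve.mean.max()
        i = int(np.flatnonzero(self.curve.r_values == self.r_star)[0])
        if self.curve.mean[i] + self.curve.sd[i] < high_water - 1e-12:
            raise ValueError("r* violates the one-standard-deviation rule")

    @property
    def cv_accuracy(self) -> tuple[float, float]:
        """(mean, sd) of held-out fold accuracy at the selected model size."""
        i = int(np.flatnonzero(self.curve.r_values == self.r_star)[0])
        return float(self.curve.mean[i]), float(self.curve.sd[i])

    def predict(self, x) -> np.ndarray:
        """Classify new samples given a feature->values map or DataFrame
        (features in rows) on the same normalization stage as training."""
        return self.model.predict(x)

    def decision_values(self, x) -> np.ndarray:
        return self.model.decision_values(x)

    def summary(self) -> str:
        mean, sd = self.cv_accuracy
        lines = [
            "Feature-selecting linear SVM",
            "=" * 64,
            f"samples: {self.estimator.dataset.n_samples}"
            f"   features: {self.estimator.dataset.matrix.n_features}"
            f"   folds: {self.curve.folds}   r_max: {self.estimator.r_max}",
            f"prior positive: {self.estimator.dataset.prior['positive']:.4f}",
            f"selected model size r* = {self.r_star} (one-SD rule)",
            f"CV accuracy at r*: {mean:.4f} +/- {sd:.4f}",
            "",
            f"{'rank':>4}  {'probe':<20}{'MI (bits)':>10}{'mRMR':>9}{'weight':>10}",
            "-" * 64,
        ]
        for j, fid in enumerate(self.model.features):
            lines.append(
                f"{j + 1:>4}  {fid:<20}{self.ranking.relevance[j]:>10.4f}"
                f"{self.ranking.mrmr_score[j]:>9.4f}{self.model.weights[j]:>10.4f}"
            )
        lines.append("-" * 64)
        lines.append(f"threshold (w0): {self.model.threshold:+.4f}")
        return "\n".join(lines)


#: Back-compat alias: a fitted feature-selecting SVM.
FittedFSSVM = FSSVMResults


def fit_fs_svm(
    d: LabeledDataset,
    r_max: int = DEFAULT_R_MAX,
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
    c_param: float = DEFAULT_C,
    pool_size: int | None = DEFAULT_POOL,
) -> FSSVMResults:
    """Functional entry point; equivalent to ``FeatureSelectingSVM(...).fit``."""
    return FeatureSelectingSVM(
        d, r_max=r_max, n_folds=k, c_param=c_param, pool_size=pool_size
    ).fit(seed=seed)
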