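"""Descriptor selection, pooled-covariance LDA and AGNES clustering.

These are the supervised/unsupervised learning stages of the pipeline,
exposed as scikit-learn estimators so they compose with sklearn pipelines
and model selection:

* :class:`FRatioSelector` — univariate one-way F-ratio feature selection
  (keep features with F > f_min and p < p_max);
* :class:`PooledCovarianceLDA` — classifier using one covariance matrix
  pooled over all groups and the Mahalanobis distance from each sample to
  each group's multivariate mean;
* :class:`AgnesClustering` — agglomerative nesting with the agglomerative
  coefficient AC in [0, 1] (0 = no structure, 1 = very clear structure).

Module-level functions wrap the estimators for use on an
:class:`~spcpipe.align.AlignedMatrix`: samples are the per-animal SpC*
vectors (gene-grouped), features are proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import confusion_matrix
from sklearn.utils.validation import check_is_fitted, validate_data

from ._errors import InsufficientDataError, ValidationError
from .align import AlignedMatrix

__all__ = [
    "FRatioSelector",
    "PooledCovarianceLDA",
    "AgnesClustering",
    "LDAResult",
    "ClusterTree",
    "f_ratio_select",
    "lda_fit",
    "agnes_cluster",
    "F_MIN",
    "P_MAX",
]

F_MIN = 3.4
P_MAX = 0.05


def _group_f_ratios(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-feature one-way F ratio and p-value.

    F is the model mean square over the error mean square; features with no
    variance at all get F = 0, p = 1.
    """
    classes = np.unique(y)
    k = len(classes)
    n = X.shape[0]
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        mean_c = Xc.mean(axis=0)
        ss_between += Xc.shape[0] * (mean_c - grand) ** 2
        ss_within += ((Xc - mean_c) ** 2).sum(axis=0)
    df_b, df_w = k - 1, n - k
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    f = np.where(ss_within == 0, np.where(ss_between == 0, 0.0, np.inf), f)
    p = sps.f.sf(f, df_b, df_w)
    p = np.where(np.isinf(f), 0.0, np.where(ss_within + ss_between == 0, 1.0, p))
    return f, p


class FRatioSelector(SelectorMixin, BaseEstimator):
    """Select features whose between/within-group F ratio and p-value pass
    the (f_min, p_max) cutoffs.

    Fitted attributes: ``f_ratio_``, ``p_value_``, ``support_``.
    """

    def __init__(self, f_min: float = F_MIN, p_max: float = P_MAX):
        self.f_min = f_min
        self.p_max = p_max

    def fit(self, X, y):
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValidationError("F-ratio selection needs at least 2 groups")
        if counts.min() < 2:
            raise ValidationError("each group needs at least 2 samples")
        self.f_ratio_, self.p_value_ = _group_f_ratios(X, y)
        self.support_ = (self.f_ratio_ > self.f_min) & (self.p_value_ < self.p_max)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


class PooledCovarianceLDA(ClassifierMixin, BaseEstimator):
    """Nearest-group-mean classifier under a common covariance matrix.

    The within-group covariance is pooled over all groups; each sample is
    assigned to the group whose multivariate mean is closest in (squared)
    Mahalanobis distance.  A singular pooled covariance is ridge-regularized
    with epsilon = ``ridge_factor`` * trace / dim (warning emitted).
    """

    def __init__(self, ridge_factor: float = 1e-6):
        self.ridge_factor = ridge_factor

    def fit(self, X, y):
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValidationError("LDA needs at least 2 groups")
        n, d = X.shape
        self.means_ = np.vstack(
            [X[y_idx == i].mean(axis=0) for i in range(len(self.classes_))]
        )
        pooled = np.zeros((d, d))
        dof = 0
        for i in range(len(self.classes_)):
            Xc = X[y_idx == i]
            if Xc.shape[0] < 2:
                raise ValidationError("each group needs at least 2 samples")
            centered = Xc - Xc.mean(axis=0)
            pooled += centered.T @ centered
            dof += Xc.shape[0] - 1
        pooled /= dof
        self.covariance_ = (pooled + pooled.T) / 2
        eps = 0.0
        try:
            np.linalg.cholesky(self.covariance_ + 0 * np.eye(d))
            cond = np.linalg.cond(self.covariance_)
            if not np.isfinite(cond) or cond > 1e12:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            eps = self.ridge_factor * np.trace(self.covariance_) / d
            if eps == 0:
                eps = self.ridge_factor
            warnings.warn(
                f"singular pooled covariance; ridge-regularized with eps={eps:.3g}"
            )
        self.regularization_ = eps
        self.precision_ = np.linalg.inv(self.covariance_ + eps * np.eye(d))
        return self

    def mahalanobis(self, X) -> np.ndarray:
        """Squared Mahalanobis distance of each sample to each group mean."""
        check_is_fitted(self, "precision_")
        X = validate_data(self, X, dtype=float, reset=False)
        diffs = X[:, None, :] - self.means_[None, :, :]
        return np.einsum("sgi,ij,sgj->sg", diffs, self.precision_, diffs)

    def decision_function(self, X):
        return -self.mahalanobis(X)

    def predict(self, X):
        return self.classes_[np.argmin(self.mahalanobis(X), axis=1)]


class AgnesClustering(BaseEstimator):
    """Agglomerative nesting (AGNES) with the agglomerative coefficient.

    AC is the mean over leaves of (1 - h_first / h_max) where h_first is the
    height at which the leaf first merges and h_max the final merge height;
    when all merge heights are zero (identical samples) AC is defined as 0.
    Fitted attributes: ``linkage_matrix_``, ``agglomerative_coefficient_``,
    ``leaf_order_``.
    """

    def __init__(self, linkage: str = "average", metric: str = "euclidean"):
        self.linkage = linkage
        self.metric = metric

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float, ensure_min_samples=2)
        distances = pdist(X, metric=self.metric)
        self.linkage_matrix_ = hierarchy.linkage(distances, method=self.linkage)
        self.agglomerative_coefficient_ = _agglomerative_coefficient(
            self.linkage_matrix_
        )
        self.leaf_order_ = hierarchy.leaves_list(self.linkage_matrix_)
        return self


def _agglomerative_coefficient(linkage_matrix: np.ndarray) -> float:
    n = linkage_matrix.shape[0] + 1
    h_max = linkage_matrix[-1, 2]
    if h_max == 0:
        return 0.0
    first_height = np.full(n, np.nan)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, (left, right, height, _count) in enumerate(linkage_matrix):
        merged = members.pop(int(left)) + members.pop(int(right))
        members[n + step] = merged
        # a leaf's first merge height is recorded the first time it appears
        for leaf in merged:
            if np.isnan(first_height[leaf]):
                first_height[leaf] = height
    return float(np.mean(1.0 - first_height / h_max))


def _tree_to_newick(linkage_matrix: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(linkage_matrix)

    def recurse(node, parent_height) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({recurse(tree.left, tree.dist)},{recurse(tree.right, tree.dist)});"


@dataclass
class LDAResult:
    """Outcome of descriptor-based LDA on the animal-level SpC* vectors."""

    descriptors: tuple[str, ...]
    sample_labels: tuple[str, ...]
    conditions: tuple[str, ...]
    group_means: pd.DataFrame
    pooled_covariance: np.ndarray
    mahalanobis: pd.DataFrame
    assigned_group: pd.Series
    confusion: pd.DataFrame
    estimator: PooledCovarianceLDA

    @property
    def training_accuracy(self) -> float:
        truth = self.mahalanobis.index.map(lambda s: s[0])
        return float((self.assigned_group.values == truth.values).mean())


@dataclass
class ClusterTree:
    """AGNES merge history with the agglomerative coefficient."""

    linkage_matrix: np.ndarray
    labels: tuple[str, ...]
    agglomerative_coefficient: float

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def clades(self) -> list[frozenset]:
        """Leaf-label sets of every internal node of the tree."""
        n = len(self.labels)
        members: dict[int, frozenset] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        out = []
        for step, (left, right, _h, _c) in enumerate(self.linkage_matrix):
            merged = members[int(left)] | members[int(right)]
            members[n + step] = merged
            out.append(merged)
        return out

    def to_newick(self) -> str:
        return _tree_to_newick(self.linkage_matrix, list(self.labels))

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage_matrix, columns=["left", "right", "height", "n_members"]
        )


def _animal_samples(matrix: AlignedMatrix) -> tuple[np.ndarray, np.ndarray, list]:
    """Animal-level SpC* design matrix: rows = animals, columns = proteins."""
    X = matrix.spc_star_animal.to_numpy(dtype=float).T
    cols = list(matrix.spc_star_animal.columns)  # (condition, animal) tuples
    y = np.asarray([c for c, _a in cols])
    return X, y, cols


def f_ratio_select(
    matrix: AlignedMatrix, f_min: float = F_MIN, p_max: float = P_MAX
) -> tuple[list[str], pd.DataFrame]:
    """Per-protein F-ratio descriptor selection on animal-level SpC*.

    Returns the selected accession list and a frame of (f_ratio, p_value,
    selected) for every protein.
    """
    X, y, _ = _animal_samples(matrix)
    selector = FRatioSelector(f_min=f_min, p_max=p_max).fit(X, y)
    stats_frame = pd.DataFrame(
        {
            "f_ratio": selector.f_ratio_,
            "p_value": selector.p_value_,
            "selected": selector.support_,
        },
        index=matrix.proteins,
    ).rename_axis("accession")
    return list(matrix.proteins[selector.support_]), stats_frame


def lda_fit(
    matrix: AlignedMatrix, descriptors: Sequence[str], ridge_factor: float = 1e-6
) -> LDAResult:
    """Pooled-covariance LDA of the animal samples on the given descriptors."""
    descriptors = list(descriptors)
    if not descriptors:
        raise ValidationError("need at least one descriptor")
    missing = [d for d in descriptors if d not in matrix.proteins]
    if missing:
        raise ValidationError(f"descriptors not in matrix: {missing[:5]}")
    X, y, cols = _animal_samples(matrix)
    idx = [matrix.proteins.get_loc(d) for d in descriptors]
    Xd = X[:, idx]
    est = PooledCovarianceLDA(ridge_factor=ridge_factor).fit(Xd, y)
    maha = pd.DataFrame(
        est.mahalanobis(Xd),
        index=pd.MultiIndex.from_tuples(cols, names=["condition", "animal"]),
        columns=est.classes_,
    )
    assigned = pd.Series(est.predict(Xd), index=maha.index, name="assigned_group")
    conf = pd.DataFrame(
        confusion_matrix(y, assigned.values, labels=list(est.classes_)),
        index=est.classes_,
        columns=est.classes_,
    )
    means = pd.DataFrame(est.means_, index=est.classes_, columns=descriptors)
    return LDAResult(
        tuple(descriptors),
        tuple(f"{c}/{a}" for c, a in cols),
        tuple(matrix.conditions),
        means,
        est.covariance_,
        maha,
        assigned,
        conf,
        est,
    )


def agnes_cluster(
    matrix: AlignedMatrix,
    descriptors: Sequence[str] | None = None,
    linkage: str = "average",
    metric: str = "euclidean",
) -> ClusterTree:
    """AGNES clustering of the animal samples on descriptor SpC* profiles."""
    X, _, cols = _animal_samples(matrix)
    if X.shape[0] < 2:
        raise InsufficientDataError("clustering needs at least 2 samples")
    if descriptors is not None:
        idx = [matrix.proteins.get_loc(d) for d in descriptors]
        X = X[:, idx]
    est = AgnesClustering(linkage=linkage, metric=metric).fit(X)
    labels = tuple(f"{c}/{a}" for c, a in cols)
    return ClusterTree(est.linkage_matrix_, labels, est.agglomerative_coefficient_)
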