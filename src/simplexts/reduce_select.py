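"""Dimensionality reduction: sparse-species merging and feature ranking.

Merging pools species whose zero fraction on the training set exceeds a
threshold into one "other_species" part — rare exposures are assumed not
to drive a common outcome. Ranking orders transformed features by a
univariate two-group ANOVA F statistic (the primary selector) or by the
comparison selectors (lasso coefficients, mutual information, PCA). The
number of features kept is chosen by the mean or median validation
accuracy over inner cross-validation folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import mutual_info_classif
from sklearn.linear_model import Lasso
from sklearn.preprocessing import StandardScaler

from .data_model import StudyDataset
from .transforms import FeatureMatrix

__all__ = [
    "SparsityProfile",
    "FeatureRanking",
    "fit_sparsity_profile",
    "merge_sparse_species",
    "anova_f_rank",
    "lasso_rank",
    "mutual_info_rank",
    "pca_reduce",
    "select_optimal_n",
]

OTHER_SPECIES = "other_species"


@dataclass
class SparsityProfile:
    """Per-species fraction of zero abundances over the training rows."""

    fractions: np.ndarray
    species_names: list[str]

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < 0) or np.any(self.fractions > 1):
            raise ValueError("sparsity fractions must lie in [0, 1]")


@dataclass
class FeatureRanking:
    """Feature order by descending score, with the scoring method's tag."""

    order: np.ndarray
    scores: np.ndarray
    method: str

    def top(self, n: int) -> np.ndarray:
        return self.order[:n]


def fit_sparsity_profile(train: StudyDataset) -> SparsityProfile:
    """Zero fraction per species, pooled over all non-missing training rows."""
    rows = [s.values[~s.missing] for s in train.series if (~s.missing).any()]
    if not rows:
        raise ValueError("training set has no observed rows")
    pooled = np.vstack(rows)
    return SparsityProfile(
        fractions=(pooled == 0).mean(axis=0),
        species_names=list(train.species_names),
    )


def merge_sparse_species(
    ds: StudyDataset, profile: SparsityProfile, threshold: float
) -> StudyDataset:
    """Sum species sparser than ``threshold`` into one "other_species" part.

    The profile must come from training data only; the identical merge is
    then applied to validation and test. Row sums are unchanged. The merged
    part is appended last; when no species crosses the threshold the dataset
    is returned unchanged.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if list(profile.species_names) != list(ds.species_names):
        raise ValueError("sparsity profile fitted on different species")
    merge = profile.fractions > threshold
    if not merge.any():
        return ds.copy()
    if merge.all():
        raise ValueError("threshold merges every species; no features would remain")
    keep = ~merge
    names = [n for n, k in zip(ds.species_names, keep) if k] + [OTHER_SPECIES]
    series = []
    for s in ds.series:
        vals = np.full((s.n_timepoints, keep.sum() + 1), np.nan)
        present = ~s.missing
        vals[present, :-1] = s.values[present][:, keep]
        vals[present, -1] = s.values[present][:, merge].sum(axis=1)
        series.append(
            type(s)(
                participant_id=s.participant_id,
                values=vals,
                missing=s.missing.copy(),
                label=int(s.label),
                imputed=s.imputed.copy(),
                per_timepoint_labels=None
                if s.per_timepoint_labels is None
                else s.per_timepoint_labels.copy(),
            )
        )
    return StudyDataset(series=series, species_names=names, timepoint_names=list(ds.timepoint_names))


def _two_group_f(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way two-group ANOVA F per column; perfect separators get +inf."""
    y = np.asarray(labels)
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError("labels must contain exactly two classes")
    n = len(y)
    grand = values.mean(axis=0)
    ss_between = np.zeros(values.shape[1])
    ss_within = np.zeros(values.shape[1])
    for g in groups:
        block = values[y == g]
        if block.shape[0] < 2:
            raise ValueError("need at least 2 samples per class")
        mean_g = block.mean(axis=0)
        ss_between += block.shape[0] * (mean_g - grand) ** 2
        ss_within += ((block - mean_g) ** 2).sum(axis=0)
    df1, df2 = 1, n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    f[ss_within == 0] = np.where(ss_between[ss_within == 0] > 0, np.inf, 0.0)
    return f


def _rank(scores: np.ndarray, method: str) -> FeatureRanking:
    # stable sort on negated scores -> descending, ties by feature index
    neg = -scores
    neg[np.isnan(neg)] = np.inf
    order = np.argsort(neg, kind="stable")
    return FeatureRanking(order=order, scores=scores[order], method=method)


def anova_f_rank(features: FeatureMatrix, labels: np.ndarray) -> FeatureRanking:
    """Rank features by the two-group ANOVA F statistic, descending.

    F is between-group variability over within-group variability; a feature
    constant across samples scores 0, a perfect separator (zero within-group
    variance, nonzero between) scores +inf and ranks first.
    """
    return _rank(_two_group_f(features.values, labels), "anova")


def lasso_rank(
    features: FeatureMatrix,
    labels: np.ndarray,
    alpha: float = 10.0,
    max_iter: int = 10_000,
    seed: int = 10,
) -> FeatureRanking:
    """Rank by |coefficient| of an L1-penalized linear fit on standardized features.

    Features with zero coefficient fall to the end in index order.
    """
    X = StandardScaler().fit_transform(features.values)
    model = Lasso(alpha=alpha, max_iter=max_iter, random_state=seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("always", category=ConvergenceWarning)
        try:
            model.fit(X, np.asarray(labels, dtype=float))
        except ConvergenceWarning:  # pragma: no cover - sklearn warns, not raises
            warnings.warn("lasso did not converge; ranking may be partial")
    return _rank(np.abs(model.coef_), "lasso")


def mutual_info_rank(
    features: FeatureMatrix, labels: np.ndarray, seed: int = 0
) -> FeatureRanking:
    """Rank by estimated mutual information with the binary label.

    Uses the nearest-neighbor MI estimator; the seed controls its jitter.
    """
    mi = mutual_info_classif(features.values, np.asarray(labels), random_state=seed)
    return _rank(mi, "mutual_info")


def pca_reduce(features: FeatureMatrix, k: int, fit_rows: np.ndarray | None = None):
    """Project onto the top-k principal components fitted on training rows.

    Returns ``(scores: FeatureMatrix, pca: sklearn PCA)``; apply ``pca`` to
    transform held-out rows. ``fit_rows`` is a boolean mask of training rows
    (all rows when omitted).
    """
    X = features.values
    fit_X = X if fit_rows is None else X[np.asarray(fit_rows, dtype=bool)]
    if k > min(fit_X.shape):
        raise ValueError(f"k={k} exceeds the rank bound {min(fit_X.shape)}")
    pca = PCA(n_components=k, random_state=0)
    pca.fit(fit_X)
    scores = FeatureMatrix(
        values=pca.transform(X),
        feature_names=[f"pc{i + 1}" for i in range(k)],
        transform_tag=features.transform_tag,
    )
    return scores, pca


def select_optimal_n(validation_acc: np.ndarray, metric: str = "mean") -> int:
    """Number of features maximizing the mean/median validation accuracy.

    ``validation_acc`` is an (n_max x folds) matrix whose row ``n-1`` holds
    the per-fold accuracies with the top ``n`` features. Ties go to the
    smallest ``n``.
    """
    acc = np.asarray(validation_acc, dtype=float)
    if acc.size == 0:
        raise ValueError("empty validation accuracy matrix")
    if metric == "mean":
        summary = acc.mean(axis=1)
    elif metric == "median":
        summary = np.median(acc, axis=1)
    else:
        raise ValueError(f"metric must be 'mean' or 'median', got {metric!r}")
    return int(np.argmax(summary)) + 1
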