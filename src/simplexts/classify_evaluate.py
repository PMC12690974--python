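"""Classifiers, confusion metrics, and the tests behind the result tables.

The headline metric is balanced accuracy ``T_P/(2P) + T_N/(2N)`` — the
mean of sensitivity and specificity — which is 0.5 for constant or random
decisions on any class balance and equals the two-point trapezoid AUROC
of a hard classifier. Per-experiment significance uses a one-sided
one-sample t test against 0.5; method comparisons use two-sided Welch
tests. Multiple-imputation runs are pooled with Rubin's rules (total
variance = within + (1 + 1/m) * between) and tested with a one-sided
Wald statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.svm import SVC

__all__ = [
    "ConfusionCounts",
    "MetricSummary",
    "PooledMetric",
    "balanced_accuracy",
    "sensitivity",
    "specificity",
    "confusion_from_predictions",
    "train_classifier",
    "one_sample_t",
    "welch_t",
    "rubin_pool",
    "wald_test",
    "CLASSIFIER_KINDS",
]

CLASSIFIER_KINDS = ("random_forest", "svc", "adaboost")


@dataclass(frozen=True)
class ConfusionCounts:
    P: int
    N: int
    T_P: int
    T_N: int

    def __post_init__(self) -> None:
        if min(self.P, self.N, self.T_P, self.T_N) < 0:
            raise ValueError("counts must be nonnegative")
        if self.T_P > self.P or self.T_N > self.N:
            raise ValueError("true positives/negatives cannot exceed class sizes")


def sensitivity(c: ConfusionCounts) -> float:
    if c.P == 0:
        raise ValueError("no positives")
    return c.T_P / c.P


def specificity(c: ConfusionCounts) -> float:
    if c.N == 0:
        raise ValueError("no negatives")
    return c.T_N / c.N


def balanced_accuracy(c: ConfusionCounts) -> float:
    """``T_P/(2P) + T_N/(2N)``; requires both classes present."""
    if c.P == 0 or c.N == 0:
        raise ValueError("balanced accuracy needs both classes in the test set")
    return c.T_P / (2 * c.P) + c.T_N / (2 * c.N)


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == 1
    neg = y_true == -1
    return ConfusionCounts(
        P=int(pos.sum()),
        N=int(neg.sum()),
        T_P=int((pos & (y_pred == 1)).sum()),
        T_N=int((neg & (y_pred == -1)).sum()),
    )


def train_classifier(kind: str, features: np.ndarray, labels: np.ndarray, balance: bool = False, seed: int = 0):
    """Fit one of the three classifier families on a feature matrix.

    ``balance`` reweights classes inversely to their frequencies. The
    random forest uses its standard defaults: 100 trees, Gini impurity,
    unrestricted depth, sqrt(m) features per split, bootstrap resampling.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if kind == "random_forest":
        model = RandomForestClassifier(
            n_estimators=100,
            criterion="gini",
            max_depth=None,
            max_features="sqrt",
            bootstrap=True,
            class_weight="balanced" if balance else None,
            random_state=seed,
        )
        model.fit(X, y)
    elif kind == "svc":
        model = SVC(class_weight="balanced" if balance else None, random_state=seed)
        model.fit(X, y)
    elif kind == "adaboost":
        model = AdaBoostClassifier(random_state=seed)
        if balance:
            w = {lbl: len(y) / (2 * (y == lbl).sum()) for lbl in (-1, 1)}
            model.fit(X, y, sample_weight=np.array([w[v] for v in y]))
        else:
            model.fit(X, y)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")
    return model


def one_sample_t(accs: np.ndarray, mu0: float = 0.5) -> float:
    """One-sided p-value that the mean accuracy exceeds ``mu0``.

    Degenerate zero-variance samples use the limit convention: p = 1 when
    the mean does not exceed mu0 and p = 0 when it does.
    """
    accs = np.asarray(accs, dtype=float)
    if accs.size < 2:
        raise ValueError("need at least 2 values")
    if np.std(accs, ddof=1) == 0:
        return 0.0 if accs.mean() > mu0 else 1.0
    return float(stats.ttest_1samp(accs, mu0, alternative="greater").pvalue)


def welch_t(accs_a: np.ndarray, accs_b: np.ndarray) -> float:
    """Two-sided Welch t test for equal means (Welch-Satterthwaite df)."""
    a = np.asarray(accs_a, dtype=float)
    b = np.asarray(accs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per sample")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


@dataclass
class MetricSummary:
    """Per-test-fold balanced accuracies with the reporting statistics."""

    fold_accuracies: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    optimal_n: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, dtype=float)
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        self.specificities = np.asarray(self.specificities, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def variance(self) -> float:
        return float(self.fold_accuracies.var(ddof=1))

    @property
    def ci_half_width(self) -> float:
        """±1.96 sqrt(variance): a 95% interval under normality."""
        return 1.96 * float(np.sqrt(self.variance))

    @property
    def sensitivity(self) -> float:
        return float(self.sensitivities.mean())

    @property
    def specificity(self) -> float:
        return float(self.specificities.mean())

    @property
    def p_one_sample(self) -> float:
        return one_sample_t(self.fold_accuracies)

    def as_dict(self) -> dict:
        return {
            "acc": self.mean,
            "ci": [self.mean - self.ci_half_width, self.mean + self.ci_half_width],
            "p_one_sample": self.p_one_sample,
            "sens": self.sensitivity,
            "spec": self.specificity,
            "n": self.optimal_n,
            "fold_accuracies": self.fold_accuracies.tolist(),
        }


@dataclass
class PooledMetric:
    """Rubin-pooled balanced accuracy over m imputation rounds."""

    m: int
    round_means: np.ndarray
    within_variance: float
    between_variance: float

    def __post_init__(self) -> None:
        self.round_means = np.asarray(self.round_means, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.round_means.mean())

    @property
    def total_variance(self) -> float:
        return self.within_variance + (1 + 1 / self.m) * self.between_variance


def rubin_pool(round_means: np.ndarray, round_variances: np.ndarray) -> PooledMetric:
    """Pool per-round means and variances across imputation rounds.

    W-bar is the mean within-round variance, B the sample variance of the
    round means, and the total variance W-bar + (1 + 1/m) B.
    """
    means = np.asarray(round_means, dtype=float)
    variances = np.asarray(round_variances, dtype=float)
    if means.size == 0:
        raise ValueError("no rounds to pool")
    if means.size != variances.size:
        raise ValueError("need one variance per round")
    m = means.size
    between = float(means.var(ddof=1)) if m > 1 else 0.0
    return PooledMetric(
        m=m,
        round_means=means,
        within_variance=float(variances.mean()),
        between_variance=between,
    )


def wald_test(pm: PooledMetric, mu0: float = 0.5) -> float:
    """One-sided Wald p-value that the pooled mean exceeds ``mu0``."""
    t_var = pm.total_variance
    if t_var == 0:
        if pm.mean == mu0:
            return 0.5
        return 0.0 if pm.mean > mu0 else 1.0
    z = (pm.mean - mu0) / np.sqrt(t_var)
    return float(stats.norm.sf(z))
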