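"""Log-ratio representations of compositional time series.

Compositions live on the probability simplex, where only relative
information is meaningful. The transforms here move them into real space:

* **compositional** — the raw flattened fractions (the no-transform control);
* **CLR** — centered log ratio, log of each part over the geometric mean of
  its time point; maps a composition to a zero-sum real vector and has the
  softmax as inverse;
* **ALR** — all pairwise log ratios ``log(X_i / X_j)``, ``j > i``, of the
  flattened series, growing the dimension from ``D = d*T`` to ``D(D-1)/2``;
* **PLR** — pivot log ratios (balances): log ratios of geometric means of
  the two child clusters at each node of a Ward hierarchy over the flattened
  features, keeping the dimension at ``D``.

Because logarithms need strictly positive parts, zeros are first replaced
multiplicatively: the replacement value ``delta`` is half the minimum
positive abundance of the *training* set, and the positive parts of a row
are rescaled so the row still sums to 1.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import ward
from scipy.spatial.distance import pdist

from .data_model import CompositionSeries, StudyDataset

__all__ = [
    "ZeroPolicy",
    "FeatureMatrix",
    "BalanceTree",
    "fit_zero_policy",
    "apply_zero_policy",
    "clr",
    "clr_inverse",
    "flatten_series",
    "alr_features",
    "alr_feature_names",
    "fit_balance_tree",
    "plr_features",
    "plr_feature_names",
    "aitchison_distance",
    "shannon_index",
]


@dataclass(frozen=True)
class ZeroPolicy:
    """Zero-replacement value fitted on training data only."""

    delta: float

    def __post_init__(self) -> None:
        if not (self.delta > 0):
            raise ValueError("delta must be positive")


def fit_zero_policy(train: StudyDataset) -> ZeroPolicy:
    """delta = (minimum positive abundance over all non-missing training rows) / 2.

    Validation and test data never influence delta.
    """
    m = np.inf
    for s in train.series:
        vals = s.values[~s.missing]
        pos = vals[vals > 0]
        if pos.size:
            m = min(m, float(pos.min()))
    if not np.isfinite(m):
        raise ValueError("training data contain no positive abundance")
    return ZeroPolicy(delta=m / 2.0)


def apply_zero_policy(x: np.ndarray, policy: ZeroPolicy) -> np.ndarray:
    """Multiplicative zero replacement preserving the unit sum.

    Zeros become ``delta``; positive parts are scaled by ``1 - z*delta``
    where ``z`` is the number of zeros, so ratios among positive parts are
    preserved and the result stays on the simplex.
    """
    x = np.asarray(x, dtype=float)
    zero = x == 0
    z = int(zero.sum())
    if z == 0:
        return x.copy()
    shrink = 1.0 - z * policy.delta
    if shrink <= 0:
        raise ValueError(
            f"{z} zeros with delta={policy.delta:.3g} would exceed the unit sum"
        )
    out = x * shrink
    out[zero] = policy.delta
    return out


def apply_zero_policy_series(s: CompositionSeries, policy: ZeroPolicy) -> CompositionSeries:
    out = s.copy()
    for t in range(s.n_timepoints):
        if not out.missing[t]:
            out.values[t] = apply_zero_policy(out.values[t], policy)
    return out


def clr(x: np.ndarray) -> np.ndarray:
    """Centered log ratio: ``log(x_i / g(x))`` with ``g`` the geometric mean."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("clr requires strictly positive parts")
    logx = np.log(x)
    return logx - logx.mean(axis=-1, keepdims=True)


def clr_inverse(c: np.ndarray) -> np.ndarray:
    """Softmax; inverse of :func:`clr` up to the simplex closure."""
    c = np.asarray(c, dtype=float)
    if np.any(~np.isfinite(c)):
        raise ValueError("clr_inverse requires finite input")
    e = np.exp(c - c.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def flatten_series(s: CompositionSeries, timepoints: Sequence[int] | None = None) -> np.ndarray:
    """Concatenate the series' time points and divide by T.

    The result is a single composition of length ``D = d*T``. Missing time
    points must have been imputed first.
    """
    tps = range(s.n_timepoints) if timepoints is None else list(timepoints)
    rows = []
    for t in tps:
        if s.missing[t]:
            raise ValueError(
                f"series {s.participant_id!r} is missing time point {t}; impute first"
            )
        rows.append(s.values[t])
    T = len(rows)
    return np.concatenate(rows) / T


def alr_feature_names(names: Sequence[str]) -> list[str]:
    D = len(names)
    return [f"{names[i]}/{names[j]}" for i in range(D) for j in range(i + 1, D)]


def alr_features(X: np.ndarray, include_dummy: bool = False, dummy_value: float | None = None) -> np.ndarray:
    """All pairwise log ratios ``log(X_i/X_j)`` for ``j > i``, lexicographic in (i, j).

    With ``include_dummy`` the log ratios of each part against a constant
    dummy part are appended, adding the plain log abundances to the space.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0):
        raise ValueError("alr_features requires strictly positive parts (apply the zero policy first)")
    D = X.shape[-1]
    logX = np.log(X)
    i, j = np.triu_indices(D, k=1)
    feats = logX[..., i] - logX[..., j]
    if include_dummy:
        if dummy_value is None or dummy_value <= 0:
            raise ValueError("include_dummy requires a positive dummy_value")
        feats = np.concatenate([feats, logX - np.log(dummy_value)], axis=-1)
    return feats


@dataclass
class BalanceTree:
    """Ward hierarchy over the ``D`` flattened features, defining PLR balances.

    ``nodes`` lists the internal nodes in root-to-leaf breadth-first order;
    each entry is a pair (left_leaf_indices, right_leaf_indices). A tree over
    D leaves has exactly D - 1 internal nodes.
    """

    n_leaves: int
    nodes: list[tuple[np.ndarray, np.ndarray]]
    leaf_names: list[str] = field(default_factory=list)
    fitted_on: str = ""

    def __post_init__(self) -> None:
        if len(self.nodes) != self.n_leaves - 1:
            raise ValueError("a binary tree over D leaves has D-1 internal nodes")

    def to_newick(self) -> str:
        """Serialize as a Newick string with leaf names."""
        names = self.leaf_names or [f"f{i}" for i in range(self.n_leaves)]

        def build(leaves: np.ndarray, node_idx: int | None) -> str:
            if len(leaves) == 1:
                return names[int(leaves[0])]
            # find the node splitting exactly this leaf set
            for k, (left, right) in enumerate(self.nodes):
                if set(left) | set(right) == set(int(v) for v in leaves):
                    return f"({build(left, k)},{build(right, k)})"
            raise ValueError("inconsistent tree")

        all_leaves = np.arange(self.n_leaves)
        return build(all_leaves, None) + ";"


def fit_balance_tree(
    train_features: np.ndarray,
    leaf_names: Sequence[str] | None = None,
    fitted_on: str = "",
) -> BalanceTree:
    """Ward agglomeration of the columns of a CLR-transformed training matrix.

    Columns (flattened features) are clustered by minimum within-cluster
    variance in the Euclidean geometry the CLR provides; rows are training
    samples only. The result is deterministic for a fixed input.
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need an n x D matrix with n >= 2 and D >= 2")
    D = X.shape[1]
    Z = ward(pdist(X.T))

    # resolve each linkage node to its leaf set and child split
    leafsets: list[np.ndarray] = [np.array([i]) for i in range(D)]
    children: list[tuple[int, int]] = [(-1, -1)] * D
    for a, b, _, _ in Z:
        a, b = int(a), int(b)
        leafsets.append(np.concatenate([leafsets[a], leafsets[b]]))
        children.append((a, b))

    # breadth-first from the root over internal nodes only
    nodes: list[tuple[np.ndarray, np.ndarray]] = []
    queue = deque([len(leafsets) - 1])
    while queue:
        k = queue.popleft()
        a, b = children[k]
        if a < 0:
            continue
        nodes.append((np.sort(leafsets[a]), np.sort(leafsets[b])))
        for child in (a, b):
            if children[child][0] >= 0:
                queue.append(child)
    return BalanceTree(
        n_leaves=D,
        nodes=nodes,
        leaf_names=list(leaf_names) if leaf_names is not None else [],
        fitted_on=fitted_on,
    )


def plr_feature_names(tree: BalanceTree) -> list[str]:
    names = tree.leaf_names or [f"f{i}" for i in range(tree.n_leaves)]

    def side(leaves: np.ndarray) -> str:
        if len(leaves) <= 2:
            return "*".join(names[int(i)] for i in leaves)
        return f"g({len(leaves)} leaves)"

    out = ["log_g(X)"]
    for k, (left, right) in enumerate(tree.nodes):
        out.append(f"b{k}:{side(left)}/{side(right)}")
    return out


def plr_features(
    X: np.ndarray, tree: BalanceTree, ilr_normalize: bool = False
) -> np.ndarray:
    """Pivot log-ratio coordinates of a flattened composition.

    Feature 1 is ``log g(X)`` over all parts; features 2..D are
    ``log(g(left)/g(right))`` for the internal nodes in root-to-leaf
    breadth-first order. With ``ilr_normalize`` each balance is scaled by
    ``sqrt(r*s/(r+s))`` (the isometric-log-ratio coefficient), off by
    default.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0):
        raise ValueError("plr_features requires strictly positive parts")
    if X.shape[-1] != tree.n_leaves:
        raise ValueError(
            f"composition has {X.shape[-1]} parts but the tree has {tree.n_leaves} leaves"
        )
    logX = np.log(X)
    feats = np.empty(X.shape[:-1] + (tree.n_leaves,))
    feats[..., 0] = logX.mean(axis=-1)
    for k, (left, right) in enumerate(tree.nodes):
        bal = logX[..., left].mean(axis=-1) - logX[..., right].mean(axis=-1)
        if ilr_normalize:
            r, s = len(left), len(right)
            bal = bal * np.sqrt(r * s / (r + s))
        feats[..., k + 1] = bal
    return feats


def aitchison_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance between the CLR images of two compositions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("compositions must have equal length")
    return float(np.linalg.norm(clr(x) - clr(y)))


def shannon_index(x: np.ndarray) -> float:
    """Shannon entropy ``-sum x_i ln x_i`` (0 ln 0 := 0) of one composition."""
    x = np.asarray(x, dtype=float)
    pos = x[x > 0]
    return float(-(pos * np.log(pos)).sum())


@dataclass
class FeatureMatrix:
    """A named n x m feature block with its transform provenance."""

    values: np.ndarray
    feature_names: list[str]
    transform_tag: str

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match the number of columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            transform_tag=self.transform_tag,
        )

    def hstack(self, other: "FeatureMatrix") -> "FeatureMatrix":
        return FeatureMatrix(
            values=np.hstack([self.values, other.values]),
            feature_names=self.feature_names + other.feature_names,
            transform_tag=self.transform_tag,
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, columns=self.feature_names).to_csv(path, index=False)
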