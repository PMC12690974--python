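"""Synthetic longitudinal compositional studies with known ground truth.

The generative family is logistic-normal: each participant follows a
latent AR(1) trajectory in CLR space around a base mean, and the observed
composition is the softmax of the latent state. Class effects are planted
as log-ratio shifts — for a planted pair (i, j, t, delta), positive-label
participants get +delta/2 on species i and -delta/2 on species j at time
point t, so the between-class difference of ``log(x_i/x_j)`` at t is
delta CLR units. Structural zeros, class imbalance and (optionally
label-dependent) per-time-point missingness emulate the shape of real
cohort studies; being closed under the CLR machinery makes every effect
size interpretable in the geometry the downstream method uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import CompositionSeries, StudyDataset
from .transforms import clr_inverse

__all__ = ["GeneratorSpec", "GroundTruth", "generate", "make_linear_imputable",
           "dataset1_like", "dataset2_like"]


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic dataset.

    ``n_per_class`` maps label (-1/+1) to participant count; ``base`` is
    the mean latent CLR vector (zeros when omitted); ``planted_pairs`` are
    (species_i, species_j, timepoint, delta-in-CLR-units) class effects;
    ``rho`` the AR(1) coefficient of the latent trajectory; ``sigma`` the
    innovation scale in CLR units; ``sparsity_target`` the per-species
    fraction of structural zeros; ``missing_rates`` per-time-point drop
    probabilities, either one sequence or a {label: sequence} mapping for
    label-dependent missingness.
    """

    n_per_class: Mapping[int, int]
    d: int
    T: int
    seed: int = 0
    base: np.ndarray | None = None
    planted_pairs: list[tuple[int, int, int, float]] = field(default_factory=list)
    rho: float = 0.0
    sigma: float = 0.5
    sparsity_target: float = 0.0
    missing_rates: Sequence[float] | Mapping[int, Sequence[float]] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0 <= self.sparsity_target < 1):
            raise ValueError("sparsity_target must lie in [0, 1)")
        for i, j, t, delta in self.planted_pairs:
            if not (0 <= i < self.d and 0 <= j < self.d and i != j):
                raise ValueError(f"invalid planted species pair ({i}, {j})")
            if not (0 <= t < self.T):
                raise ValueError(f"planted time point {t} out of range")
            if not np.isfinite(delta):
                raise ValueError("planted effect must be finite")
        if set(self.n_per_class) - {-1, 1}:
            raise ValueError("labels must be -1/+1")

    def rates_for(self, label: int) -> np.ndarray:
        if self.missing_rates is None:
            return np.zeros(self.T)
        if isinstance(self.missing_rates, Mapping):
            rates = np.asarray(self.missing_rates[label], dtype=float)
        else:
            rates = np.asarray(self.missing_rates, dtype=float)
        if rates.shape != (self.T,):
            raise ValueError("missing_rates must have one entry per time point")
        if np.any(rates < 0) or np.any(rates >= 1):
            raise ValueError("missing rates must lie in [0, 1)")
        return rates


@dataclass
class GroundTruth:
    planted_pairs: list[tuple[int, int, int, float]]
    latent_clr: dict[str, np.ndarray]
    missingness_mechanism: str  # "mcar" or "label_dependent"


def generate(spec: GeneratorSpec) -> tuple[StudyDataset, GroundTruth]:
    """Draw one study from the logistic-normal model of ``spec``."""
    rng = np.random.default_rng(spec.seed)
    base = np.zeros(spec.d) if spec.base is None else np.asarray(spec.base, dtype=float)
    if base.shape != (spec.d,):
        raise ValueError("base must have length d")

    # latent trajectories and compositions
    all_series: list[CompositionSeries] = []
    latent: dict[str, np.ndarray] = {}
    raw_rows = []  # collect for sparsity quantiles
    for label in sorted(spec.n_per_class):
        for k in range(spec.n_per_class[label]):
            pid = f"{'neg' if label == -1 else 'pos'}{k:03d}"
            z = np.empty((spec.T, spec.d))
            prev = np.zeros(spec.d)
            for t in range(spec.T):
                innov = rng.normal(0.0, spec.sigma, size=spec.d)
                prev = spec.rho * prev + innov
                z[t] = base + prev
            if label == 1:
                for i, j, t, delta in spec.planted_pairs:
                    z[t, i] += delta / 2.0
                    z[t, j] -= delta / 2.0
            latent[pid] = z
            x = clr_inverse(z)
            raw_rows.append(x)
            all_series.append((pid, label, x))

    # structural zeros: per species, zero values below its sparsity_target quantile
    if spec.sparsity_target > 0:
        pooled = np.vstack([x for x in raw_rows])
        thresholds = np.quantile(pooled, spec.sparsity_target, axis=0)
    else:
        thresholds = None

    series: list[CompositionSeries] = []
    for pid, label, x in all_series:
        if thresholds is not None:
            x = np.where(x < thresholds, 0.0, x)
            sums = x.sum(axis=1, keepdims=True)
            if np.any(sums == 0):
                raise ValueError("sparsity_target zeroed out an entire row")
            x = x / sums
        rates = spec.rates_for(label)
        miss = rng.random(spec.T) < rates
        if miss.all():  # keep at least one observed time point
            miss[rng.integers(spec.T)] = False
        vals = x.copy()
        vals[miss] = np.nan
        series.append(
            CompositionSeries(
                participant_id=pid, values=vals, missing=miss, label=label
            )
        )

    ds = StudyDataset(
        series=series,
        species_names=[f"sp{i}" for i in range(spec.d)],
        timepoint_names=[f"tp{t}" for t in range(spec.T)],
    )
    mechanism = (
        "label_dependent" if isinstance(spec.missing_rates, Mapping) else "mcar"
    )
    return ds, GroundTruth(
        planted_pairs=list(spec.planted_pairs),
        latent_clr=latent,
        missingness_mechanism=mechanism,
    )


def make_linear_imputable(
    n: int,
    d: int,
    input_timepoints: Sequence[int],
    output_timepoint: int,
    A0: np.ndarray,
    b0: np.ndarray,
    sigma: float = 0.0,
    seed: int = 0,
    input_scale: float = 1.0,
) -> tuple[StudyDataset, GroundTruth]:
    """Dataset whose missing-time-point map is exactly affine in CLR space.

    The CLR vectors of the input time points are drawn i.i.d. normal and
    centered (only the zero-sum CLR component survives the simplex
    observation); the output time point is ``A0 @ C_n + b0`` plus optional
    CLR noise of scale ``sigma``. Because centering is itself linear, the
    observed input-to-output map stays exactly affine, which makes this the
    exact-recovery oracle for the linear imputer.
    """
    inputs = list(input_timepoints)
    T = max([*inputs, output_timepoint]) + 1
    A0 = np.asarray(A0, dtype=float)
    b0 = np.asarray(b0, dtype=float)
    if A0.shape != (d, d * len(inputs)) or b0.shape != (d,):
        raise ValueError(
            f"A0 must be {d} x {d * len(inputs)} and b0 length {d} for these time points"
        )
    rng = np.random.default_rng(seed)
    series = []
    latent = {}
    for k in range(n):
        pid = f"lin{k:03d}"
        z = np.zeros((T, d))
        for t in inputs:
            draw = rng.normal(0.0, input_scale, size=d)
            z[t] = draw - draw.mean()
        c_n = np.concatenate([z[t] for t in inputs])
        z[output_timepoint] = A0 @ c_n + b0
        if sigma > 0:
            z[output_timepoint] += rng.normal(0.0, sigma, size=d)
        latent[pid] = z
        x = clr_inverse(z)
        vals = np.full((T, d), np.nan)
        miss = np.ones(T, dtype=bool)
        for t in [*inputs, output_timepoint]:
            vals[t] = x[t]
            miss[t] = False
        series.append(
            CompositionSeries(
                participant_id=pid,
                values=vals,
                missing=miss,
                label=-1 if k % 2 else 1,
            )
        )
    ds = StudyDataset(
        series=series,
        species_names=[f"sp{i}" for i in range(d)],
        timepoint_names=[f"tp{t}" for t in range(T)],
    )
    return ds, GroundTruth(planted_pairs=[], latent_clr=latent, missingness_mechanism="mcar")


def dataset1_like(seed: int = 0, d: int = 20, delta: float = 2.0) -> tuple[StudyDataset, GroundTruth]:
    """Small imbalanced T=3 cohort: 82 negative / 15 positive complete series,
    plus 108 negative and 16 positive series missing the last time point."""
    spec = GeneratorSpec(
        n_per_class={-1: 82 + 108, 1: 15 + 16},
        d=d,
        T=3,
        seed=seed,
        planted_pairs=[(0, 1, 1, delta)] if delta else [],
        rho=0.5,
        sigma=0.5,
        sparsity_target=0.2,
    )
    ds, gt = generate(spec)
    # deterministically drop the last time point for the chosen counts
    for s in ds.series:
        idx = int(s.participant_id[3:])
        missing_last = (s.label == -1 and idx >= 82) or (s.label == 1 and idx >= 15)
        if missing_last:
            s.values[2] = np.nan
            s.missing[2] = True
    return ds, gt


def dataset2_like(seed: int = 0, d: int = 20, delta: float = 2.0) -> tuple[StudyDataset, GroundTruth]:
    """Near-balanced T=6 cohort (40/42) with availability decaying over time."""
    spec = GeneratorSpec(
        n_per_class={-1: 40, 1: 42},
        d=d,
        T=6,
        seed=seed,
        planted_pairs=[(0, 1, 2, delta), (2, 3, 3, delta)] if delta else [],
        rho=0.5,
        sigma=0.5,
        sparsity_target=0.3,
        missing_rates=[0.05, 0.1, 0.15, 0.2, 0.3, 0.4],
    )
    return generate(spec)
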