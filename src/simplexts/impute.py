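"""Imputation of missing time points in CLR space.

Every imputer maps the CLR concatenation of a participant's available
time points (``C_n``) to the CLR vector of a missing one (``C_m``),
trained on participants complete on those time points; the prediction is
mapped back to the simplex with the softmax. Five model families are
provided:

* ``linear`` — least-squares affine map ``A C_n + b`` (the baseline);
* ``svr`` — per-output-dimension support vector regression with an RBF
  kernel and epsilon-insensitive margin 0.1, after standard scaling;
* ``gpr`` — Gaussian process regression with an RBF kernel (posterior
  mean prediction, 5 optimizer restarts);
* ``cvae`` — conditional variational autoencoder (latent size 1);
* ``cgan`` — conditional GAN; both neural imputers draw their latent
  noise from N(0, 1) at imputation time, so repeated rounds differ.

Stochastic imputers are run ``m = 5`` times (seeds 0..4) as multiple
imputation; the rounds feed Rubin variance pooling downstream.
Imputation never alters observed values and never touches test folds.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from ._nn import CGANImputer, CVAEImputer
from .data_model import CompositionSeries, StudyDataset
from .transforms import (
    ZeroPolicy,
    aitchison_distance,
    apply_zero_policy,
    clr,
    clr_inverse,
    fit_zero_policy,
)

__all__ = [
    "ImputationTask",
    "ImputationModel",
    "ImputationRound",
    "fit_imputer",
    "impute_missing",
    "multiple_impute",
    "augment_with_flags",
    "balance_by_imputation",
    "evaluate_imputation",
    "METHODS",
]

METHODS = ("linear", "svr", "gpr", "cvae", "cgan")
DETERMINISTIC_METHODS = ("linear", "svr")


@dataclass(frozen=True)
class ImputationTask:
    """Which time points condition the model and which one it fills in."""

    input_timepoints: tuple[int, ...]
    output_timepoint: int

    def __post_init__(self) -> None:
        if not self.input_timepoints:
            raise ValueError("task needs at least one input time point")
        if self.output_timepoint in self.input_timepoints:
            raise ValueError("output time point cannot also be an input")


@dataclass
class ImputationModel:
    method: str
    task: ImputationTask
    seed: int
    _predict: object = field(repr=False)

    def predict_clr(self, c_n: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return np.asarray(self._predict(np.asarray(c_n, dtype=float), rng), dtype=float)


@dataclass
class ImputationRound:
    """One completed copy of a dataset; observed values are bit-identical."""

    round_index: int
    seed: int
    dataset: StudyDataset


def _task_pairs(
    series: Sequence[CompositionSeries], task: ImputationTask, policy: ZeroPolicy
):
    """CLR training pairs from series complete on the task's time points."""
    X, Y = [], []
    for s in series:
        needed = (*task.input_timepoints, task.output_timepoint)
        if any(s.missing[t] for t in needed):
            continue
        c_in = np.concatenate(
            [clr(apply_zero_policy(s.values[t], policy)) for t in task.input_timepoints]
        )
        c_out = clr(apply_zero_policy(s.values[task.output_timepoint], policy))
        X.append(c_in)
        Y.append(c_out)
    return np.array(X), np.array(Y)


def fit_imputer(
    method: str,
    train: Sequence[CompositionSeries] | StudyDataset,
    task: ImputationTask,
    seed: int = 0,
    zero_policy: ZeroPolicy | None = None,
) -> ImputationModel:
    """Fit one imputation model for one missingness pattern.

    ``train`` supplies the series; only those complete on the task's time
    points contribute training pairs (at least 2 are required).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    series = train.series if isinstance(train, StudyDataset) else list(train)
    if zero_policy is None:
        ds = train if isinstance(train, StudyDataset) else None
        if ds is None:
            raise ValueError("zero_policy is required when passing a bare series list")
        zero_policy = fit_zero_policy(ds)
    X, Y = _task_pairs(series, task, zero_policy)
    if len(X) < 2:
        raise ValueError(
            f"only {len(X)} training series complete on time points "
            f"{task.input_timepoints} -> {task.output_timepoint}; need at least 2"
        )

    if method == "linear":
        A1 = np.hstack([X, np.ones((len(X), 1))])
        coef, *_ = np.linalg.lstsq(A1, Y, rcond=None)
        A, b = coef[:-1].T, coef[-1]
        predict = lambda c, rng: A @ c + b
    elif method == "svr":
        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
        models = [SVR(kernel="rbf", epsilon=0.1).fit(Xs, Y[:, j]) for j in range(Y.shape[1])]
        predict = lambda c, rng: np.array(
            [m.predict(scaler.transform(c[None, :]))[0] for m in models]
        )
    elif method == "gpr":
        gpr = GaussianProcessRegressor(
            kernel=RBF(), n_restarts_optimizer=5, random_state=seed
        ).fit(X, Y)
        predict = lambda c, rng: gpr.predict(c[None, :])[0]
    elif method == "cvae":
        net = CVAEImputer(cond_dim=X.shape[1], out_dim=Y.shape[1], seed=seed)
        net.fit(X, Y)
        predict = net.predict
    else:  # cgan
        net = CGANImputer(cond_dim=X.shape[1], out_dim=Y.shape[1], seed=seed)
        net.fit(X, Y)
        predict = net.predict

    return ImputationModel(method=method, task=task, seed=seed, _predict=predict)


def impute_missing(
    model: ImputationModel, available_clr: np.ndarray, noise_seed: int = 0
) -> np.ndarray:
    """Predict one missing composition from the CLR concatenation of available points."""
    rng = np.random.default_rng(noise_seed)
    pred = model.predict_clr(available_clr, rng)
    if np.any(~np.isfinite(pred)):
        raise ValueError("imputation produced a non-finite prediction")
    return clr_inverse(pred)


def _complete_series(
    s: CompositionSeries,
    train_series: Sequence[CompositionSeries],
    method: str,
    policy: ZeroPolicy,
    seed: int,
    timepoints: Sequence[int],
    model_cache: dict,
) -> CompositionSeries:
    """Fill every missing time point of ``s`` (within ``timepoints``), one target at a time."""
    out = s.copy()
    available = tuple(t for t in timepoints if not s.missing[t])
    targets = [t for t in timepoints if s.missing[t]]
    for t in targets:
        task = ImputationTask(input_timepoints=available, output_timepoint=t)
        key = (task, seed)
        if key not in model_cache:
            model_cache[key] = fit_imputer(method, train_series, task, seed=seed, zero_policy=policy)
        c_n = np.concatenate(
            [clr(apply_zero_policy(s.values[tp], policy)) for tp in available]
        )
        # stable per-(series, time point) noise stream; crc32 is process-independent
        rng = np.random.default_rng(
            [seed, zlib.crc32(s.participant_id.encode()) & 0x7FFFFFFF, t]
        )
        pred = model_cache[key].predict_clr(c_n, rng)
        if np.any(~np.isfinite(pred)):
            raise ValueError("imputation produced a non-finite prediction")
        out.values[t] = clr_inverse(pred)
        out.missing[t] = False
        out.imputed[t] = True
    return out


def multiple_impute(
    ds: StudyDataset,
    method: str,
    m: int = 5,
    seeds: Sequence[int] | None = None,
    timepoints: Sequence[int] | None = None,
    zero_policy: ZeroPolicy | None = None,
) -> list[ImputationRound]:
    """Run ``m`` imputation rounds over every incomplete series of a dataset.

    Stochastic imputers differ between rounds through their seeds; the
    deterministic linear map yields identical rounds. Series with no
    available time point at all are excluded with a warning. Observed
    values are copied bitwise into every round.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    seeds = list(range(m)) if seeds is None else list(seeds)
    if len(seeds) != m:
        raise ValueError("need one seed per round")
    tps = list(range(ds.n_timepoints)) if timepoints is None else list(timepoints)
    policy = zero_policy if zero_policy is not None else fit_zero_policy(ds)

    usable, dropped = [], []
    for s in ds.series:
        if all(s.missing[t] for t in tps):
            dropped.append(s.participant_id)
        else:
            usable.append(s)
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} series with every time point missing: {dropped[:5]}..."
        )

    rounds = []
    for r, seed in enumerate(seeds):
        cache: dict = {}
        completed = []
        for s in usable:
            if any(s.missing[t] for t in tps):
                completed.append(
                    _complete_series(s, usable, method, policy, seed, tps, cache)
                )
            else:
                completed.append(s.copy())
        rounds.append(
            ImputationRound(
                round_index=r,
                seed=seed,
                dataset=StudyDataset(
                    series=completed,
                    species_names=list(ds.species_names),
                    timepoint_names=list(ds.timepoint_names),
                ),
            )
        )
    return rounds


def augment_with_flags(features, series: Sequence[CompositionSeries], timepoints=None):
    """Append one binary column per time point marking imputed entries."""
    from .transforms import FeatureMatrix

    if features.values.shape[0] != len(series):
        raise ValueError("features and series are misaligned")
    tps = range(series[0].n_timepoints) if timepoints is None else list(timepoints)
    flags = np.array([[float(s.imputed[t]) for t in tps] for s in series])
    extra = FeatureMatrix(
        values=flags,
        feature_names=[f"imputed_tp{t}" for t in tps],
        transform_tag=features.transform_tag,
    )
    return features.hstack(extra)


def balance_by_imputation(
    ds: StudyDataset,
    method: str,
    minority_label: int | None = None,
    seed: int = 0,
    timepoints: Sequence[int] | None = None,
    zero_policy: ZeroPolicy | None = None,
) -> StudyDataset:
    """Complete only the incomplete minority-class series, leaving controls complete-case.

    Returns the complete series of both classes plus the newly completed
    minority series (imputed flags set). When no incomplete minority series
    exists, warns and returns the complete-case dataset unchanged.
    """
    tps = list(range(ds.n_timepoints)) if timepoints is None else list(timepoints)
    if minority_label is None:
        labels = ds.labels
        minority_label = min(
            (-1, 1), key=lambda lbl: int((labels == lbl).sum())
        )
    complete = [s for s in ds.series if not any(s.missing[t] for t in tps)]
    incomplete_minority = [
        s
        for s in ds.series
        if s.label == minority_label
        and any(s.missing[t] for t in tps)
        and not all(s.missing[t] for t in tps)
    ]
    if not incomplete_minority:
        warnings.warn("no incomplete minority series; balancing is a no-op")
        return StudyDataset(
            series=[s.copy() for s in complete],
            species_names=list(ds.species_names),
            timepoint_names=list(ds.timepoint_names),
        )
    policy = zero_policy if zero_policy is not None else fit_zero_policy(ds)
    cache: dict = {}
    completed = [
        _complete_series(s, complete, method, policy, seed, tps, cache)
        for s in incomplete_minority
    ]
    return StudyDataset(
        series=[s.copy() for s in complete] + completed,
        species_names=list(ds.species_names),
        timepoint_names=list(ds.timepoint_names),
    )


def evaluate_imputation(
    ds_complete: StudyDataset,
    method: str,
    mask_plan: Sequence[tuple[str, int]],
    seeds: Sequence[int] = (0,),
    timepoints: Sequence[int] | None = None,
) -> float:
    """Mask present time points, impute them back, and score the error.

    Returns the mean Aitchison distance between imputed and true
    compositions over all masked (participant, time point) pairs and all
    seeds. The imputers are trained on the unmasked participants only.
    """
    if not mask_plan:
        raise ValueError("empty mask plan")
    tps = list(range(ds_complete.n_timepoints)) if timepoints is None else list(timepoints)
    masked_ids = {pid for pid, _ in mask_plan}
    train = [s for s in ds_complete.series if s.participant_id not in masked_ids]
    policy = fit_zero_policy(
        StudyDataset(
            series=[s.copy() for s in train],
            species_names=list(ds_complete.species_names),
            timepoint_names=list(ds_complete.timepoint_names),
        )
    )
    dists = []
    for seed in seeds:
        cache: dict = {}
        for pid, t in mask_plan:
            s = ds_complete.get(pid)
            if s.missing[t]:
                raise ValueError(f"({pid}, {t}) is already missing; cannot mask")
            masked = s.copy()
            masked.values[t] = np.nan
            masked.missing[t] = True
            filled = _complete_series(masked, train, method, policy, seed, tps, cache)
            truth = apply_zero_policy(s.values[t], policy)
            dists.append(aitchison_distance(filled.values[t], truth))
    return float(np.mean(dists))
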