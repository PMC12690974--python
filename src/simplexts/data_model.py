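"""In-memory model of longitudinal compositional studies.

A study is a collection of participants, each contributing a short time
series of compositions (relative abundances over ``d`` species at ``T``
named time points) together with a binary outcome label in {-1, +1}.
Some time points may be missing; missingness is first-class here because
downstream imputation and the missingness summaries depend on it.

The on-disk dialect is a long-format CSV/TSV with one row per
(participant, time point): columns ``participant_id``, ``timepoint``,
``label`` and then one column per species. A missing time point is an
absent row, never a NaN-filled one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompositionSeries",
    "StudyDataset",
    "FoldPlan",
    "MissingnessSummary",
    "read_study_table",
    "write_study_table",
    "summarize_missingness",
    "make_nested_folds",
    "DEFAULT_SCHEMA",
]

_SUM_TOL_INGEST = 1e-6
_SUM_TOL_STRICT = 1e-9

DEFAULT_SCHEMA: Mapping[str, str] = {
    "participant": "participant_id",
    "timepoint": "timepoint",
    "label": "label",
    "imputed": "imputed_flag",
}


@dataclass
class CompositionSeries:
    """One participant's time series of compositions.

    ``values`` is a T x d matrix; rows flagged in ``missing`` carry the
    sentinel value NaN and no information. ``imputed`` marks rows that
    were filled in by an imputation model (such rows are no longer
    ``missing``). ``label`` applies to the whole series;
    ``per_timepoint_labels`` optionally records outcomes known at each
    visit (used by the label-history baseline).
    """

    participant_id: str
    values: np.ndarray
    missing: np.ndarray
    label: int
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]
    per_timepoint_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.imputed is None:
            self.imputed = np.zeros(self.values.shape[0], dtype=bool)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x d matrix")
        if self.missing.shape != (self.values.shape[0],):
            raise ValueError("missing mask length must equal T")
        if self.label not in (-1, 1):
            raise ValueError(f"label must be -1 or +1, got {self.label}")
        if np.any(self.missing & self.imputed):
            raise ValueError("a time point cannot be both missing and imputed")
        self.validate()

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    @property
    def is_complete(self) -> bool:
        return not bool(self.missing.any())

    def validate(self) -> None:
        present = ~self.missing
        vals = self.values[present]
        if vals.size:
            if np.any(~np.isfinite(vals)) or np.any(vals < 0) or np.any(vals >= 1 + _SUM_TOL_STRICT):
                raise ValueError(
                    f"series {self.participant_id!r}: abundances must lie in [0, 1)"
                )
            sums = vals.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > _SUM_TOL_STRICT):
                raise ValueError(
                    f"series {self.participant_id!r}: non-missing rows must sum to 1 "
                    f"(max deviation {np.max(np.abs(sums - 1.0)):.3g})"
                )
        self.values[self.missing] = np.nan

    def copy(self) -> "CompositionSeries":
        return CompositionSeries(
            participant_id=self.participant_id,
            values=self.values.copy(),
            missing=self.missing.copy(),
            label=int(self.label),
            imputed=self.imputed.copy(),
            per_timepoint_labels=None
            if self.per_timepoint_labels is None
            else np.asarray(self.per_timepoint_labels).copy(),
        )


@dataclass
class StudyDataset:
    """All series of one study; every series shares T and d."""

    series: list[CompositionSeries]
    species_names: list[str]
    timepoint_names: list[str]

    def __post_init__(self) -> None:
        T, d = len(self.timepoint_names), len(self.species_names)
        ids = set()
        for s in self.series:
            if s.values.shape != (T, d):
                raise ValueError(
                    f"series {s.participant_id!r} has shape {s.values.shape}, expected {(T, d)}"
                )
            if s.participant_id in ids:
                raise ValueError(f"duplicate participant_id {s.participant_id!r}")
            ids.add(s.participant_id)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoint_names)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def participant_ids(self) -> list[str]:
        return [s.participant_id for s in self.series]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.series], dtype=int)

    def get(self, participant_id: str) -> CompositionSeries:
        for s in self.series:
            if s.participant_id == participant_id:
                return s
        raise KeyError(participant_id)

    def subset(self, participant_ids: Sequence[str]) -> "StudyDataset":
        wanted = set(participant_ids)
        return StudyDataset(
            series=[s for s in self.series if s.participant_id in wanted],
            species_names=list(self.species_names),
            timepoint_names=list(self.timepoint_names),
        )

    def copy(self) -> "StudyDataset":
        return StudyDataset(
            series=[s.copy() for s in self.series],
            species_names=list(self.species_names),
            timepoint_names=list(self.timepoint_names),
        )


@dataclass
class FoldPlan:
    """Nested stratified split: 5 outer test folds, 5 inner folds each."""

    outer_test: dict[str, int]
    inner: list[dict[str, int]]
    seed: int
    n_outer: int
    n_inner: int

    def outer_fold_ids(self, fold: int) -> list[str]:
        return [pid for pid, f in self.outer_test.items() if f == fold]

    def split(self, fold: int, inner_fold: int | None = None):
        """Return (train_ids, validation_ids, test_ids) for one outer fold.

        With ``inner_fold=None`` validation is empty and train is the full
        non-test remainder (the fit-on-train-plus-validation configuration
        used for the final test evaluation).
        """
        test = self.outer_fold_ids(fold)
        rest = [pid for pid, f in self.outer_test.items() if f != fold]
        if inner_fold is None:
            return rest, [], test
        assignment = self.inner[fold]
        val = [pid for pid in rest if assignment[pid] == inner_fold]
        train = [pid for pid in rest if assignment[pid] != inner_fold]
        return train, val, test


@dataclass
class MissingnessSummary:
    """Participant counts per (label, required-time-point subset)."""

    table: pd.DataFrame  # index = label values, columns = subset tuples

    def count(self, label: int, subset: tuple[int, ...]) -> int:
        return int(self.table.loc[label, [subset]].iloc[0])


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def _sorted_timepoints(raw: Sequence) -> list[str]:
    uniq = list(dict.fromkeys(str(t) for t in raw))
    try:
        return sorted(uniq, key=float)
    except ValueError:
        return sorted(uniq)


def read_study_table(
    path: str | Path,
    schema: Mapping[str, str] = DEFAULT_SCHEMA,
    timepoint_names: Sequence[str] | None = None,
) -> StudyDataset:
    """Read a long-format study table.

    Rows absent for a (participant, time point) pair encode a missing time
    point. Abundance rows are renormalized when their sum is within 1e-6
    of 1 and rejected otherwise; negative abundances and duplicate
    (participant, time point) rows are rejected.
    """
    df = _read_table(path)
    pid_col = schema["participant"]
    tp_col = schema["timepoint"]
    label_col = schema["label"]
    imputed_col = schema.get("imputed", "imputed_flag")
    meta_cols = {pid_col, tp_col, label_col, imputed_col, "timepoint_label"}
    species = [c for c in df.columns if c not in meta_cols]
    if not species:
        raise ValueError("no species columns found")

    dup = df.duplicated(subset=[pid_col, tp_col])
    if dup.any():
        bad = df.loc[dup, [pid_col, tp_col]].iloc[0]
        raise ValueError(f"duplicate (participant, time point) row: {tuple(bad)}")

    vals = df[species].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative abundance encountered")
    sums = vals.sum(axis=1)
    off = np.abs(sums - 1.0) > _SUM_TOL_INGEST
    if off.any():
        i = int(np.argmax(off))
        raise ValueError(
            f"abundance row sums to {sums[i]:.6g}, more than 1e-6 away from 1 "
            f"(participant {df[pid_col].iloc[i]!r}, timepoint {df[tp_col].iloc[i]!r})"
        )
    vals = vals / sums[:, None]
    df = df.copy()
    df[species] = vals

    if timepoint_names is None:
        timepoint_names = _sorted_timepoints(df[tp_col])
    timepoint_names = [str(t) for t in timepoint_names]
    tp_index = {t: i for i, t in enumerate(timepoint_names)}
    T, d = len(timepoint_names), len(species)

    series: list[CompositionSeries] = []
    for pid, group in df.groupby(pid_col, sort=False):
        values = np.full((T, d), np.nan)
        missing = np.ones(T, dtype=bool)
        imputed = np.zeros(T, dtype=bool)
        tp_labels = np.zeros(T, dtype=int) if "timepoint_label" in df.columns else None
        labels = set(int(v) for v in group[label_col])
        if labels - {-1, 1}:
            raise ValueError(f"labels must be -1 or +1, got {sorted(labels)}")
        if len(labels) != 1:
            raise ValueError(f"participant {pid!r} has inconsistent labels")
        for _, row in group.iterrows():
            t = tp_index.get(str(row[tp_col]))
            if t is None:
                raise ValueError(f"unknown timepoint {row[tp_col]!r}")
            values[t] = row[species].to_numpy(dtype=float)
            missing[t] = False
            if imputed_col in df.columns:
                imputed[t] = bool(row[imputed_col])
            if tp_labels is not None:
                tp_labels[t] = int(row["timepoint_label"])
        series.append(
            CompositionSeries(
                participant_id=str(pid),
                values=values,
                missing=missing & ~imputed,
                label=labels.pop(),
                imputed=imputed,
                per_timepoint_labels=tp_labels,
            )
        )
    return StudyDataset(series=series, species_names=species, timepoint_names=timepoint_names)


def write_study_table(
    ds: StudyDataset, path: str | Path, schema: Mapping[str, str] = DEFAULT_SCHEMA
) -> None:
    """Write a dataset in the long CSV/TSV dialect read by :func:`read_study_table`."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = []
    for s in ds.series:
        for t, tp in enumerate(ds.timepoint_names):
            if s.missing[t]:
                continue
            row = {
                schema["participant"]: s.participant_id,
                schema["timepoint"]: tp,
                schema["label"]: s.label,
                schema.get("imputed", "imputed_flag"): int(s.imputed[t]),
            }
            if s.per_timepoint_labels is not None:
                row["timepoint_label"] = int(s.per_timepoint_labels[t])
            row.update(dict(zip(ds.species_names, s.values[t])))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def summarize_missingness(
    ds: StudyDataset, timepoint_subsets: Sequence[Sequence[int]]
) -> MissingnessSummary:
    """Count, per label, the participants having ALL queried time points present."""
    T = ds.n_timepoints
    cols = []
    for subset in timepoint_subsets:
        subset = tuple(sorted(int(t) for t in subset))
        if not subset:
            raise ValueError("empty time-point subset")
        if any(t < 0 or t >= T for t in subset):
            raise ValueError(f"subset {subset} out of range for T={T}")
        cols.append(subset)
    labels = sorted({s.label for s in ds.series})
    table = pd.DataFrame(0, index=labels, columns=pd.Index(cols, tupleize_cols=False))
    for s in ds.series:
        available = ~s.missing
        for subset in cols:
            if all(available[t] for t in subset):
                table.loc[s.label, [subset]] += 1
    return MissingnessSummary(table=table)


def _deal_round_robin(ids: list[str], n_folds: int, rng: np.random.Generator) -> dict[str, int]:
    order = list(rng.permutation(len(ids)))
    return {ids[j]: i % n_folds for i, j in enumerate(order)}


def make_nested_folds(
    ds: StudyDataset, n_outer: int = 5, n_inner: int = 5, seed: int = 0
) -> FoldPlan:
    """Nested stratified fold plan over participants.

    Within each class, participants are shuffled under the seed and dealt
    round-robin to the outer folds, which bounds every fold's class count
    within one of exact proportionality. Inner folds re-stratify the
    non-test remainder of each outer fold the same way. For the default
    5 x 5 design the train/validation/test proportions are 0.64/0.16/0.20.
    """
    labels = ds.labels
    by_class: dict[int, list[str]] = {}
    for s in ds.series:
        by_class.setdefault(s.label, []).append(s.participant_id)
    for lbl, members in by_class.items():
        if len(members) < n_outer:
            raise ValueError(
                f"class {lbl} has {len(members)} members, fewer than n_outer={n_outer}"
            )

    rng = np.random.default_rng(seed)
    outer: dict[str, int] = {}
    for lbl in sorted(by_class):
        outer.update(_deal_round_robin(by_class[lbl], n_outer, rng))
    # keep insertion order aligned with the dataset for reproducible reports
    outer = {pid: outer[pid] for pid in ds.participant_ids}

    inner: list[dict[str, int]] = []
    for fold in range(n_outer):
        fold_rng = np.random.default_rng([seed, fold])
        assignment: dict[str, int] = {}
        for lbl in sorted(by_class):
            rest = [pid for pid in by_class[lbl] if outer[pid] != fold]
            assignment.update(_deal_round_robin(rest, n_inner, fold_rng))
        inner.append(assignment)
    return FoldPlan(outer_test=outer, inner=inner, seed=seed, n_outer=n_outer, n_inner=n_inner)
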