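import numpy as np
import pytest

from simplexts.data_model import CompositionSeries, StudyDataset
from simplexts.synthetic import GeneratorSpec, generate


def make_series(pid, rows, label, missing=None, tp_labels=None):
    rows = np.asarray(rows, dtype=float)
    if missing is None:
        missing = np.zeros(rows.shape[0], dtype=bool)
    missing = np.asarray(missing, dtype=bool)
    vals = rows.copy()
    vals[missing] = np.nan
    return CompositionSeries(
        participant_id=pid,
        values=vals,
        missing=missing,
        label=label,
        per_timepoint_labels=tp_labels,
    )


@pytest.fixture
def tiny_dataset():
    """2 participants x 3 time points x 4 species, fully observed."""
    rows_a = [[0.4, 0.3, 0.2, 0.1]] * 3
    rows_b = [[0.25, 0.25, 0.25, 0.25], [0.1, 0.2, 0.3, 0.4], [0.4, 0.1, 0.4, 0.1]]
    return StudyDataset(
        series=[make_series("a", rows_a, -1), make_series("b", rows_b, 1)],
        species_names=["s1", "s2", "s3", "s4"],
        timepoint_names=["1", "2", "3"],
    )


@pytest.fixture
def imbalanced_dataset():
    """97 complete participants, 82 negative / 15 positive, T=3, d=6."""
    rng = np.random.default_rng(42)

    def comp():
        v = rng.dirichlet(np.ones(6), size=3)
        return v

    series = [make_series(f"n{i}", comp(), -1) for i in range(82)]
    series += [make_series(f"p{i}", comp(), 1) for i in range(15)]
    return StudyDataset(
        series=series,
        species_names=[f"s{k}" for k in range(6)],
        timepoint_names=["1", "2", "3"],
    )


@pytest.fixture
def planted_dataset():
    """Balanced synthetic study with one planted log-ratio effect."""
    spec = GeneratorSpec(
        n_per_class={-1: 30, 1: 30},
        d=10,
        T=3,
        seed=7,
        planted_pairs=[(0, 1, 1, 2.0)],
        rho=0.3,
        sigma=0.5,
    )
    ds, gt = generate(spec)
    return ds, gt
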