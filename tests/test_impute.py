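import numpy as np
import pytest

from simplexts._nn import CGANImputer, CVAEImputer
from simplexts.data_model import StudyDataset
from simplexts.impute import (
    ImputationTask,
    augment_with_flags,
    balance_by_imputation,
    evaluate_imputation,
    fit_imputer,
    impute_missing,
    multiple_impute,
)
from simplexts.synthetic import make_linear_imputable
from simplexts.transforms import (
    FeatureMatrix,
    aitchison_distance,
    apply_zero_policy,
    clr,
    fit_zero_policy,
)

from conftest import make_series

D = 5
TASK = ImputationTask((0, 1), 2)


@pytest.fixture(scope="module")
def linear_study():
    rng = np.random.default_rng(0)
    A0 = rng.normal(0, 0.3, size=(D, 2 * D))
    b0 = rng.normal(0, 0.5, size=D)
    ds, _ = make_linear_imputable(
        n=60, d=D, input_timepoints=[0, 1], output_timepoint=2, A0=A0, b0=b0, seed=1
    )
    train = ds.subset([s.participant_id for s in ds.series[:50]])
    held_out = ds.series[50:]
    return ds, train, held_out


def clr_inputs(series, policy, tps=(0, 1)):
    return np.concatenate([clr(apply_zero_policy(series.values[t], policy)) for t in tps])


def training_pairs(train, policy):
    X = np.array([clr_inputs(s, policy) for s in train.series])
    Y = np.array([clr(apply_zero_policy(s.values[2], policy)) for s in train.series])
    return X, Y


class TestLinearImputer:
    def test_exact_recovery_of_noiseless_affine_map(self, linear_study):
        ds, train, held_out = linear_study
        policy = fit_zero_policy(train)
        model = fit_imputer("linear", train, TASK, seed=0)
        for s in held_out:
            imputed = impute_missing(model, clr_inputs(s, policy))
            truth = apply_zero_policy(s.values[2], policy)
            assert aitchison_distance(imputed, truth) < 1e-6

    def test_constant_target_learns_the_mean(self):
        rng = np.random.default_rng(2)
        const = rng.dirichlet(np.ones(D))
        series = []
        for k in range(20):
            vals = np.vstack([rng.dirichlet(np.ones(D)), rng.dirichlet(np.ones(D)), const])
            series.append(make_series(f"s{k}", vals, -1 if k % 2 else 1))
        ds = StudyDataset(
            series=series,
            species_names=[f"sp{i}" for i in range(D)],
            timepoint_names=["0", "1", "2"],
        )
        policy = fit_zero_policy(ds)
        model = fit_imputer("linear", ds, TASK, seed=0)
        probe = np.array([clr_inputs(s, policy) for s in series[:3]])
        preds = [impute_missing(model, c) for c in probe]
        for p in preds:
            np.testing.assert_allclose(p, const, atol=1e-6)

    def test_noisy_prediction_rmse_approaches_noise_scale(self):
        rng = np.random.default_rng(3)
        sigma = 0.1
        A0 = rng.normal(0, 0.3, size=(D, 2 * D))
        b0 = rng.normal(0, 0.5, size=D)
        ds, gt = make_linear_imputable(
            n=500, d=D, input_timepoints=[0, 1], output_timepoint=2,
            A0=A0, b0=b0, sigma=sigma, seed=4,
        )
        train = ds.subset([s.participant_id for s in ds.series[:400]])
        policy = fit_zero_policy(train)
        model = fit_imputer("linear", train, TASK, seed=0)
        errs = []
        for s in ds.series[400:]:
            pred = model.predict_clr(clr_inputs(s, policy), np.random.default_rng(0))
            target = clr(apply_zero_policy(s.values[2], policy))
            errs.append(pred - target)
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        # observing through the simplex centers the noise: variance sigma^2 (1 - 1/d)
        expected = sigma * np.sqrt(1 - 1 / D)
        assert rmse == pytest.approx(expected, rel=0.2)


class TestStochasticImputers:
    @pytest.mark.parametrize("method", ["cvae", "cgan"])
    def test_refitting_with_same_seed_is_deterministic(self, linear_study, method):
        _, train, held_out = linear_study
        policy = fit_zero_policy(train)
        m1 = fit_imputer(method, train, TASK, seed=3)
        m2 = fit_imputer(method, train, TASK, seed=3)
        c = clr_inputs(held_out[0], policy)
        np.testing.assert_array_equal(
            impute_missing(m1, c, noise_seed=5), impute_missing(m2, c, noise_seed=5)
        )

    @pytest.mark.parametrize("method", ["cvae", "cgan"])
    def test_different_noise_seeds_give_different_compositions(self, linear_study, method):
        _, train, held_out = linear_study
        policy = fit_zero_policy(train)
        model = fit_imputer(method, train, TASK, seed=0)
        c = clr_inputs(held_out[0], policy)
        x1 = impute_missing(model, c, noise_seed=1)
        x2 = impute_missing(model, c, noise_seed=2)
        assert x1.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(x1 > 0)
        assert not np.allclose(x1, x2)

    @pytest.mark.parametrize("method", ["svr", "gpr"])
    def test_kernel_imputers_return_valid_compositions(self, linear_study, method):
        _, train, held_out = linear_study
        policy = fit_zero_policy(train)
        model = fit_imputer(method, train, TASK, seed=0)
        x = impute_missing(model, clr_inputs(held_out[0], policy))
        assert x.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(x > 0)

    def test_training_loss_decreases_in_first_epochs(self, linear_study):
        _, train, _ = linear_study
        policy = fit_zero_policy(train)
        X, Y = training_pairs(train, policy)
        vae = CVAEImputer(2 * D, D, seed=0)
        vae.fit(X, Y, max_epochs=5, early_stopping=False)
        assert vae.loss_history[-1] < vae.loss_history[0]
        assert all(np.diff(vae.loss_history) < 0)
        gan = CGANImputer(2 * D, D, seed=0)
        gan.fit(X, Y, max_epochs=5, early_stopping=False)
        assert gan.loss_history[-1] < gan.loss_history[0]

    def test_too_few_training_series_rejected(self, linear_study):
        _, train, _ = linear_study
        one = train.subset([train.series[0].participant_id])
        with pytest.raises(ValueError, match="at least 2"):
            fit_imputer("linear", one, TASK, seed=0)


class TestMultipleImputation:
    def _incomplete_dataset(self):
        rng = np.random.default_rng(5)
        series = []
        for k in range(25):
            vals = rng.dirichlet(np.ones(D), size=3)
            missing = [False, False, k >= 20]
            series.append(make_series(f"s{k}", vals, -1 if k % 2 else 1, missing=missing))
        return StudyDataset(
            series=series,
            species_names=[f"sp{i}" for i in range(D)],
            timepoint_names=["0", "1", "2"],
        )

    def test_linear_rounds_are_identical(self):
        ds = self._incomplete_dataset()
        rounds = multiple_impute(ds, "linear", m=3, seeds=[0, 1, 2])
        assert len(rounds) == 3
        for s0, s1 in zip(rounds[0].dataset.series, rounds[2].dataset.series):
            np.testing.assert_array_equal(s0.values, s1.values)

    def test_observed_values_bitwise_identical_across_rounds(self):
        ds = self._incomplete_dataset()
        rounds = multiple_impute(ds, "cvae", m=2, seeds=[0, 1])
        for r in rounds:
            for orig, comp in zip(ds.series, r.dataset.series):
                obs = ~orig.missing
                assert np.array_equal(orig.values[obs], comp.values[obs])
                assert not comp.missing.any()
                assert np.array_equal(comp.imputed, orig.missing)

    def test_stochastic_rounds_differ_on_imputed_entries(self):
        ds = self._incomplete_dataset()
        rounds = multiple_impute(ds, "cvae", m=2, seeds=[0, 1])
        imputed_vals = [
            np.vstack([s.values[s.imputed] for s in r.dataset.series if s.imputed.any()])
            for r in rounds
        ]
        assert not np.allclose(imputed_vals[0], imputed_vals[1])

    def test_fully_missing_series_excluded_with_warning(self):
        ds = self._incomplete_dataset()
        rng = np.random.default_rng(6)
        blank = make_series(
            "blank", rng.dirichlet(np.ones(D), size=3), 1, missing=[True] * 3
        )
        ds.series.append(blank)
        with pytest.warns(UserWarning, match="every time point missing"):
            rounds = multiple_impute(ds, "linear", m=1, seeds=[0])
        assert "blank" not in [s.participant_id for s in rounds[0].dataset.series]


class TestFlagAugmentation:
    def _features(self, series):
        return FeatureMatrix(
            values=np.zeros((len(series), 2)),
            feature_names=["f0", "f1"],
            transform_tag="clr",
        )

    def test_complete_series_get_zero_flags(self):
        rng = np.random.default_rng(7)
        series = [make_series(f"s{k}", rng.dirichlet(np.ones(3), size=3), 1) for k in range(4)]
        out = augment_with_flags(self._features(series), series)
        assert out.feature_names[-3:] == ["imputed_tp0", "imputed_tp1", "imputed_tp2"]
        np.testing.assert_array_equal(out.values[:, 2:], np.zeros((4, 3)))

    def test_imputed_timepoint_sets_its_flag(self):
        rng = np.random.default_rng(8)
        s = make_series("s", rng.dirichlet(np.ones(3), size=3), 1)
        s.imputed[1] = True
        out = augment_with_flags(self._features([s]), [s])
        np.testing.assert_array_equal(out.values[0, 2:], [0.0, 1.0, 0.0])

    def test_feature_count_grows_by_t(self):
        rng = np.random.default_rng(9)
        series = [make_series("s", rng.dirichlet(np.ones(3), size=3), 1)]
        out = augment_with_flags(self._features(series), series)
        assert out.n_features == 2 + 3

    def test_misalignment_rejected(self):
        rng = np.random.default_rng(10)
        series = [make_series("s", rng.dirichlet(np.ones(3), size=3), 1)]
        with pytest.raises(ValueError, match="misaligned"):
            augment_with_flags(self._features(series + series), series)


class TestBalancing:
    def _imbalanced_with_incomplete_positives(self):
        rng = np.random.default_rng(11)
        series = [
            make_series(f"n{k}", rng.dirichlet(np.ones(D), size=3), -1) for k in range(82)
        ]
        series += [
            make_series(f"p{k}", rng.dirichlet(np.ones(D), size=3), 1) for k in range(15)
        ]
        series += [
            make_series(
                f"pm{k}", rng.dirichlet(np.ones(D), size=3), 1,
                missing=[False, False, True],
            )
            for k in range(16)
        ]
        return StudyDataset(
            series=series,
            species_names=[f"sp{i}" for i in range(D)],
            timepoint_names=["0", "1", "2"],
        )

    def test_minority_series_completed_and_added(self):
        ds = self._imbalanced_with_incomplete_positives()
        out = balance_by_imputation(ds, "linear", seed=0)
        labels = np.array([s.label for s in out.series])
        assert int((labels == 1).sum()) == 15 + 16
        assert int((labels == -1).sum()) == 82
        for s in out.series:
            assert not s.missing.any()
            if s.participant_id.startswith("pm"):
                assert s.imputed[2]

    def test_balanced_dataset_is_a_noop_with_warning(self):
        rng = np.random.default_rng(12)
        series = [
            make_series(f"s{k}", rng.dirichlet(np.ones(D), size=3), -1 if k % 2 else 1)
            for k in range(10)
        ]
        ds = StudyDataset(
            series=series,
            species_names=[f"sp{i}" for i in range(D)],
            timepoint_names=["0", "1", "2"],
        )
        with pytest.warns(UserWarning, match="no-op"):
            out = balance_by_imputation(ds, "linear", seed=0)
        assert len(out.series) == 10


class TestImputationScoring:
    def test_linear_on_noiseless_affine_data_scores_near_zero(self, linear_study):
        ds, _, held_out = linear_study
        mask_plan = [(s.participant_id, 2) for s in held_out[:5]]
        score = evaluate_imputation(ds, "linear", mask_plan, seeds=[0])
        assert score < 1e-6

    def test_empty_mask_plan_rejected(self, linear_study):
        ds, _, _ = linear_study
        with pytest.raises(ValueError, match="empty"):
            evaluate_imputation(ds, "linear", [], seeds=[0])
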