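"""End-to-end experiments: merge -> impute -> transform -> select -> classify.

One experiment evaluates a configuration (transform, merging, balancing,
selector, classifier, imputation mode) under nested stratified
cross-validation. Leakage discipline is strict: the zero policy, sparsity
profile, balance tree, scalers, rankings and imputers are fitted on seen
data only — the inner-training fold while choosing the number of
features, the outer train+validation remainder for the final test
evaluation. Test folds contain only participants complete on the chosen
time points, are identical across imputation methods for one seed, and
never receive artificial values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .classify_evaluate import (
    MetricSummary,
    PooledMetric,
    confusion_from_predictions,
    rubin_pool,
    train_classifier,
)
from .data_model import StudyDataset, make_nested_folds
from .impute import augment_with_flags, balance_by_imputation, multiple_impute
from .reduce_select import (
    anova_f_rank,
    fit_sparsity_profile,
    lasso_rank,
    merge_sparse_species,
    mutual_info_rank,
    pca_reduce,
    select_optimal_n,
)
from .transforms import (
    FeatureMatrix,
    alr_feature_names,
    alr_features,
    apply_zero_policy,
    clr,
    fit_balance_tree,
    fit_zero_policy,
    flatten_series,
    plr_feature_names,
    plr_features,
    shannon_index,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "FeatureAppearance",
    "run_experiment",
    "count_feature_appearances",
    "run_baselines",
]

TRANSFORMS = ("compositional", "clr", "alr", "plr")
SELECTORS = ("anova", "lasso", "mi", "pca")
IMPUTATION_MODES = ("none", "augment_all", "augment_1tp_missing", "balance_minority")


@dataclass
class ExperimentConfig:
    """Full factor setting for one experiment run."""

    transform: str = "plr"
    merging: bool = False
    merge_threshold: float = 0.5
    balance: bool = False
    selection_metric: str = "mean"
    selector: str = "anova"
    classifier: str = "random_forest"
    imputation_method: str | None = None
    imputation_mode: str = "none"
    timepoints: list[int] | None = None
    seed: int = 0
    n_outer: int = 5
    n_inner: int = 5
    classifier_seeds: list[int] = field(default_factory=lambda: [0, 1, 2, 3, 4])
    imputation_seeds: list[int] = field(default_factory=lambda: [0, 1, 2, 3, 4])
    n_max: int = 20
    alr_dummy: bool = False
    ilr_normalize: bool = False

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"transform must be one of {TRANSFORMS}")
        if self.selector not in SELECTORS:
            raise ValueError(f"selector must be one of {SELECTORS}")
        if self.imputation_mode not in IMPUTATION_MODES:
            raise ValueError(f"imputation_mode must be one of {IMPUTATION_MODES}")
        if self.imputation_mode != "none" and self.imputation_method is None:
            raise ValueError("imputation_mode set but no imputation_method given")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @property
    def stochastic_imputation(self) -> bool:
        return (
            self.imputation_mode != "none"
            and self.imputation_method in ("gpr", "cvae", "cgan")
        )


@dataclass
class FeatureAppearance:
    """How often each feature was selected across qualifying fold-runs."""

    counts: dict[str, int]
    denominator: int


@dataclass
class ExperimentResult:
    summary: MetricSummary
    pooled: PooledMetric | None
    fold_records: list[dict]
    fit_participants_per_fold: list[set]
    test_ids_per_fold: list[list[str]] = field(default_factory=list)
    newick_trees: list[str] = field(default_factory=list)  # per fold, PLR only


def _complete_on(ds: StudyDataset, tps: Sequence[int]) -> tuple[list, list]:
    complete, incomplete = [], []
    for s in ds.series:
        (complete if not any(s.missing[t] for t in tps) else incomplete).append(s)
    return complete, incomplete


def _flatten_with_policy(series, tps, policy) -> np.ndarray:
    rows = []
    for s in series:
        parts = [apply_zero_policy(s.values[t], policy) for t in tps]
        rows.append(np.concatenate(parts) / len(parts))
    return np.array(rows)


def _leaf_names(species, tps):
    return [f"tp{t}:{sp}" for t in tps for sp in species]


class _FittedStages:
    """Everything fitted on the training series of one fold."""

    def __init__(self, train_ds: StudyDataset, cfg: ExperimentConfig, tps, impute_seed: int):
        self.cfg = cfg
        self.tps = list(tps)
        # 1. merging (training sparsity profile only)
        if cfg.merging:
            self.profile = fit_sparsity_profile(train_ds)
            train_ds = merge_sparse_species(train_ds, self.profile, cfg.merge_threshold)
        else:
            self.profile = None
        self.species = list(train_ds.species_names)
        # 2. imputation-based training augmentation
        complete, incomplete = _complete_on(train_ds, self.tps)
        base = StudyDataset(
            series=[s.copy() for s in complete],
            species_names=self.species,
            timepoint_names=list(train_ds.timepoint_names),
        )
        self.zero_policy = fit_zero_policy(base)
        mode = cfg.imputation_mode
        if mode == "none" or not incomplete:
            self.train_series = base.series
        elif mode == "balance_minority":
            balanced = balance_by_imputation(
                StudyDataset(
                    series=[s.copy() for s in complete + incomplete],
                    species_names=self.species,
                    timepoint_names=list(train_ds.timepoint_names),
                ),
                cfg.imputation_method,
                seed=impute_seed,
                timepoints=self.tps,
                zero_policy=self.zero_policy,
            )
            self.train_series = balanced.series
        else:
            n_missing_allowed = 1 if mode == "augment_1tp_missing" else len(self.tps) - 1
            pool = [
                s
                for s in incomplete
                if 1 <= sum(bool(s.missing[t]) for t in self.tps) <= n_missing_allowed
            ]
            if pool:
                rounds = multiple_impute(
                    StudyDataset(
                        series=[s.copy() for s in complete + pool],
                        species_names=self.species,
                        timepoint_names=list(train_ds.timepoint_names),
                    ),
                    cfg.imputation_method,
                    m=1,
                    seeds=[impute_seed],
                    timepoints=self.tps,
                    zero_policy=self.zero_policy,
                )
                self.train_series = rounds[0].dataset.series
            else:
                self.train_series = base.series
        # 3. transform (tree fitted on training only)
        X = _flatten_with_policy(self.train_series, self.tps, self.zero_policy)
        self.tree = None
        if cfg.transform == "plr":
            self.tree = fit_balance_tree(
                clr(X), leaf_names=_leaf_names(self.species, self.tps)
            )
        self.train_features = self._featurize(self.train_series)
        # 4. ranking fitted on training features
        self.ranking = self._rank(self.train_features, np.array([s.label for s in self.train_series]))

    def _merge(self, series):
        if self.profile is None:
            return series
        ds = StudyDataset(
            series=[s.copy() for s in series],
            species_names=self.profile.species_names,
            timepoint_names=[f"tp{t}" for t in range(series[0].n_timepoints)],
        )
        return merge_sparse_species(ds, self.profile, self.cfg.merge_threshold).series

    def _featurize(self, series) -> FeatureMatrix:
        cfg, tps = self.cfg, self.tps
        X = _flatten_with_policy(series, tps, self.zero_policy)
        leaf = _leaf_names(self.species, tps)
        if cfg.transform == "compositional":
            fm = FeatureMatrix(values=X, feature_names=leaf, transform_tag="compositional")
        elif cfg.transform == "clr":
            fm = FeatureMatrix(values=clr(X), feature_names=leaf, transform_tag="clr")
        elif cfg.transform == "alr":
            dummy = self.zero_policy.delta if cfg.alr_dummy else None
            vals = alr_features(X, include_dummy=cfg.alr_dummy, dummy_value=dummy)
            names = alr_feature_names(leaf)
            if cfg.alr_dummy:
                names = names + [f"{n}/dummy" for n in leaf]
            fm = FeatureMatrix(values=vals, feature_names=names, transform_tag="alr")
        else:
            vals = plr_features(X, self.tree, ilr_normalize=cfg.ilr_normalize)
            fm = FeatureMatrix(
                values=vals,
                feature_names=plr_feature_names(self.tree),
                transform_tag="plr",
            )
        if cfg.imputation_mode != "none":
            fm = augment_with_flags(fm, series, timepoints=tps)
        return fm

    def _rank(self, fm: FeatureMatrix, labels: np.ndarray):
        cfg = self.cfg
        if cfg.selector == "anova":
            return anova_f_rank(fm, labels)
        if cfg.selector == "lasso":
            return lasso_rank(fm, labels)
        if cfg.selector == "mi":
            return mutual_info_rank(fm, labels, seed=cfg.seed)
        return None  # pca handled separately

    def features_for(self, series, n: int):
        """Top-n training and eval feature blocks (PCA projects instead of ranking)."""
        key = tuple(s.participant_id for s in series)
        cache = getattr(self, "_eval_cache", None)
        if cache is None or cache[0] != key:
            eval_fm = self._featurize(self._merge(series))
            self._eval_cache = (key, eval_fm)
        else:
            eval_fm = cache[1]
        if self.cfg.selector == "pca":
            k = min(n, min(self.train_features.values.shape))
            scores, pca = pca_reduce(self.train_features, k)
            eval_scores = pca.transform(eval_fm.values)
            names = scores.feature_names
            return scores.values, eval_scores, names
        idx = self.ranking.top(n)
        names = [self.train_features.feature_names[i] for i in idx]
        return self.train_features.values[:, idx], eval_fm.values[:, idx], names


def _safe_balanced_accuracy(y_true, y_pred) -> tuple[float, float, float]:
    c = confusion_from_predictions(y_true, y_pred)
    sens = c.T_P / c.P if c.P else np.nan
    spec = c.T_N / c.N if c.N else np.nan
    acc = np.nanmean([sens, spec])
    return float(acc), sens, spec


def run_experiment(ds: StudyDataset, cfg: ExperimentConfig) -> ExperimentResult:
    """Run one configuration under nested stratified cross-validation.

    Returns per-(fold, run) balanced accuracies, the per-fold optimal
    feature counts, the selected feature names, and — for stochastic
    multiple imputation — the Rubin-pooled metric over rounds.
    """
    tps = cfg.timepoints if cfg.timepoints is not None else list(range(ds.n_timepoints))
    complete, _ = _complete_on(ds, tps)
    complete_ds = StudyDataset(
        series=complete,
        species_names=list(ds.species_names),
        timepoint_names=list(ds.timepoint_names),
    )
    if len(set(s.label for s in complete)) < 2:
        raise ValueError("need both classes among series complete on the chosen time points")
    plan = make_nested_folds(complete_ds, cfg.n_outer, cfg.n_inner, cfg.seed)
    incomplete_ids = {s.participant_id for s in ds.series} - {s.participant_id for s in complete}

    rounds = cfg.imputation_seeds if cfg.stochastic_imputation else [cfg.imputation_seeds[0]]
    n_rounds = len(rounds) if cfg.stochastic_imputation else 1
    # paired runs: classifier seed r goes with imputation seed r
    runs = list(zip(range(n_rounds), rounds)) if cfg.stochastic_imputation else [
        (r, rounds[0]) for r in range(len(cfg.classifier_seeds))
    ]

    fold_records: list[dict] = []
    fit_participants: list[set] = []
    optimal_ns: list[int] = []
    test_ids_per_fold: list[list[str]] = []
    newick_trees: list[str] = []

    for fold in range(cfg.n_outer):
        test_ids = plan.outer_fold_ids(fold)
        test_ids_per_fold.append(list(test_ids))
        # --- choose the number of features on inner folds
        acc = np.zeros((cfg.n_max, cfg.n_inner))
        for g in range(cfg.n_inner):
            train_ids, val_ids, _ = plan.split(fold, g)
            train_sub = _subset_with_pool(ds, train_ids, incomplete_ids, tps)
            stages = _FittedStages(train_sub, cfg, tps, impute_seed=cfg.imputation_seeds[0])
            val_series = [complete_ds.get(pid) for pid in val_ids]
            y_val = np.array([s.label for s in val_series])
            y_train = np.array([s.label for s in stages.train_series])
            n_cap = min(cfg.n_max, stages.train_features.n_features)
            for n in range(1, cfg.n_max + 1):
                Xtr, Xva, _ = stages.features_for(val_series, min(n, n_cap))
                model = train_classifier(
                    cfg.classifier, Xtr, y_train, balance=cfg.balance,
                    seed=cfg.classifier_seeds[0],
                )
                a, _, _ = _safe_balanced_accuracy(y_val, model.predict(Xva))
                acc[n - 1, g] = a
        n_opt = select_optimal_n(acc, cfg.selection_metric)
        optimal_ns.append(n_opt)

        # --- final evaluation on the test fold, trained on train+validation
        rest_ids, _, _ = plan.split(fold)
        test_series = [complete_ds.get(pid) for pid in test_ids]
        y_test = np.array([s.label for s in test_series])
        for run_idx, imp_seed in runs:
            rest_sub = _subset_with_pool(ds, rest_ids, incomplete_ids, tps)
            stages = _FittedStages(rest_sub, cfg, tps, impute_seed=imp_seed)
            fit_participants.append({s.participant_id for s in rest_sub.series})
            if stages.tree is not None and len(newick_trees) == fold:
                newick_trees.append(stages.tree.to_newick())
            y_rest = np.array([s.label for s in stages.train_series])
            n_use = min(n_opt, stages.train_features.n_features)
            Xtr, Xte, names = stages.features_for(test_series, n_use)
            clf_seed = (
                cfg.classifier_seeds[run_idx % len(cfg.classifier_seeds)]
                if cfg.stochastic_imputation
                else cfg.classifier_seeds[run_idx]
            )
            model = train_classifier(
                cfg.classifier, Xtr, y_rest, balance=cfg.balance, seed=clf_seed
            )
            a, sens, spec = _safe_balanced_accuracy(y_test, model.predict(Xte))
            fold_records.append(
                {
                    "fold": fold,
                    "round": run_idx,
                    "imputation_seed": imp_seed,
                    "classifier_seed": clf_seed,
                    "acc": a,
                    "sens": sens,
                    "spec": spec,
                    "n": n_use,
                    "features": names,
                }
            )

    accs = np.array([r["acc"] for r in fold_records])
    summary = MetricSummary(
        fold_accuracies=accs,
        sensitivities=np.array([r["sens"] for r in fold_records]),
        specificities=np.array([r["spec"] for r in fold_records]),
        optimal_n=optimal_ns,
    )
    pooled = None
    if cfg.stochastic_imputation and n_rounds > 1:
        round_means, round_vars = [], []
        for run_idx, _ in runs:
            vals = np.array([r["acc"] for r in fold_records if r["round"] == run_idx])
            round_means.append(vals.mean())
            round_vars.append(vals.var(ddof=1))
        pooled = rubin_pool(np.array(round_means), np.array(round_vars))
    return ExperimentResult(
        summary=summary,
        pooled=pooled,
        fold_records=fold_records,
        fit_participants_per_fold=fit_participants,
        test_ids_per_fold=test_ids_per_fold,
        newick_trees=newick_trees,
    )


def _subset_with_pool(ds, train_ids, incomplete_ids, tps) -> StudyDataset:
    """Training subset: the given complete participants plus all incomplete ones.

    Incomplete participants are never in any test fold, so adding them to
    every training set leaks nothing.
    """
    wanted = set(train_ids) | set(incomplete_ids)
    return StudyDataset(
        series=[s.copy() for s in ds.series if s.participant_id in wanted],
        species_names=list(ds.species_names),
        timepoint_names=list(ds.timepoint_names),
    )


def count_feature_appearances(
    fold_records: Sequence[dict], min_accuracy: float = 0.5
) -> FeatureAppearance:
    """Count, per feature name, the qualifying fold-runs where it was selected.

    A fold-run qualifies when its balanced accuracy exceeds
    ``min_accuracy``; the denominator is the number of qualifying runs.
    """
    counts: dict[str, int] = {}
    denom = 0
    for rec in fold_records:
        if rec["acc"] <= min_accuracy:
            continue
        denom += 1
        for name in rec["features"]:
            counts[name] = counts.get(name, 0) + 1
    counts = dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return FeatureAppearance(counts=counts, denominator=denom)


BASELINES = ("missingness", "missingness_plus_labels", "shannon")


def run_baselines(
    ds: StudyDataset,
    which: str,
    timepoints: Sequence[int] | None = None,
    classifier: str = "random_forest",
    classifier_seeds: Sequence[int] = (0, 1, 2, 3, 4),
    seed: int = 0,
    n_outer: int = 5,
) -> MetricSummary:
    """Reference feature sets: missingness flags, flags + earlier labels, Shannon diversity.

    The missingness baselines include incomplete participants (their
    missingness pattern IS the feature); the Shannon baseline uses
    participants complete on the chosen time points.
    """
    if which not in BASELINES:
        raise ValueError(f"which must be one of {BASELINES}")
    tps = list(range(ds.n_timepoints)) if timepoints is None else list(timepoints)
    if which == "shannon":
        series = [s for s in ds.series if not any(s.missing[t] for t in tps)]
        feats = np.array(
            [[shannon_index(s.values[t]) for t in tps] for s in series]
        )
    else:
        series = list(ds.series)
        feats = np.array([[float(s.missing[t]) for t in tps] for s in series])
        if which == "missingness_plus_labels":
            if any(s.per_timepoint_labels is None for s in series):
                raise ValueError("missingness_plus_labels needs per-time-point labels")
            labels_feats = np.array(
                [[float(s.per_timepoint_labels[t]) for t in tps] for s in series]
            )
            feats = np.hstack([feats, labels_feats])
    sub = StudyDataset(
        series=[s.copy() for s in series],
        species_names=list(ds.species_names),
        timepoint_names=list(ds.timepoint_names),
    )
    plan = make_nested_folds(sub, n_outer, 2, seed)
    id_index = {s.participant_id: i for i, s in enumerate(series)}
    labels = np.array([s.label for s in series])
    accs, senss, specs = [], [], []
    for fold in range(n_outer):
        rest_ids, _, test_ids = plan.split(fold)
        tr = [id_index[p] for p in rest_ids]
        te = [id_index[p] for p in test_ids]
        for cs in classifier_seeds:
            model = train_classifier(classifier, feats[tr], labels[tr], seed=cs)
            a, sens, spec = _safe_balanced_accuracy(labels[te], model.predict(feats[te]))
            accs.append(a)
            senss.append(sens)
            specs.append(spec)
    return MetricSummary(
        fold_accuracies=np.array(accs),
        sensitivities=np.array(senss),
        specificities=np.array(specs),
        optimal_n=[feats.shape[1]] * n_outer,
    )
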