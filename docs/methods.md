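# Methods

## Problem setting

`simplexts` classifies participants of a longitudinal study from short time
series of compositional measurements — typically relative abundances of
`d` microbial species at `T` named visits, each row lying on the
probability simplex (non-negative, summing to 1). Outcomes are binary
labels in {−1, +1} attached to the whole series. Two features of such
cohorts drive the design: some visits are missed, so many participants are
incomplete; and case/control ratios are often far from balanced.

## Data model and cross-validation

A study is a list of per-participant series with an explicit boolean
missingness mask; on disk a missing time point is an *absent row* of the
long-format CSV, never a NaN-filled one. The unit of splitting is always
the participant, so time points of one person can never straddle a
train/test boundary.

Folds are nested and stratified: within each class, participants are
shuffled under the seed and dealt round-robin to 5 outer test folds, which
bounds every fold's class count within one of exact proportionality. The
non-test remainder of each outer fold is re-stratified the same way into 5
inner folds, giving train/validation/test proportions of 0.64/0.16/0.20.
With class sizes (82, 15) this puts exactly 3 positives in every outer
test fold and 2–3 in every inner validation fold.

## Zero handling and log-ratio transforms

Log ratios need strictly positive parts. The replacement value `delta` is
half the minimum positive abundance of the *training* data (one global
value per training set); zeros become `delta` and the positive parts of a
row are rescaled by `1 − z·delta` (`z` = number of zeros), which keeps the
row on the simplex and preserves all ratios among positive parts.
Validation and test sets never influence `delta`; their own zeros are
replaced with the training value. All logarithms are natural — the
conventional choice in compositional data analysis, and immaterial to
tree classifiers.

Four representations are supported, all over the flattened series
`X = [x_{·,1}, …, x_{·,T}]/T` of dimension `D = d·T`:

* **compositional** — the raw fractions (control condition);
* **CLR** — `log(x_i/g)` with `g` the geometric mean of the time point;
  zero-sum, inverse is the softmax;
* **ALR** — all pairwise log ratios `log(X_i/X_j)`, `j > i`
  (`D(D−1)/2` features); an optional dummy part with constant value
  `delta` adds the plain log abundances (off by default);
* **PLR** — pivot balances from a Ward hierarchy over the `D` flattened
  features. The tree is fitted by Ward linkage on the *columns* of the
  CLR-transformed training matrix: Ward requires Euclidean geometry and
  the CLR supplies it, and clustering flattened features lets balances mix
  species *and* time points. Feature 1 is `log g(X)`; features 2..D are
  `log(g(left)/g(right))` for the internal nodes in root-to-leaf
  breadth-first order. The log of the geometric mean (rather than the raw
  geometric mean) keeps all features on one scale; both are monotone
  transformations of each other, so tree classifiers are indifferent. The
  isometric-log-ratio normalizing coefficient `sqrt(rs/(r+s))` is a config
  flag, off by default — the balances are plain log ratios of geometric
  means.

Aitchison distance (`‖clr(x) − clr(y)‖₂`) scores imputation quality;
Shannon entropy (`−Σ x ln x`) provides the diversity baseline.

## Dimensionality reduction and selection

Species whose zero fraction on the training rows exceeds a threshold are
summed into a single "other_species" part before any transform — a rare
exposure is assumed not to drive a common outcome. The primary selector
ranks transformed features by a univariate two-group ANOVA F statistic
(perfect separators get an infinite sentinel and rank first); lasso
coefficients, nearest-neighbor mutual information and PCA are the
comparison selectors. Note the default lasso penalty (L1 weight 10 on
standardized features) is large enough to zero every coefficient on ±1
labels, in which case the ranking degenerates to index order — consistent
with lasso underperforming ANOVA in this setting.

The number of features kept (1..20 by default) maximizes the mean or
median balanced accuracy over the inner validation folds, ties going to
the smaller count; the median tends to pick smaller, more robust counts.

## Imputation

All imputers work in CLR space: the model maps the concatenated CLR
vectors of a participant's available time points to the CLR vector of a
missing one, and the prediction returns to the simplex through the
softmax, so every imputed composition is strictly positive and sums to 1
by construction. One model is fitted per missingness pattern
(input-set → output time point); a series missing two time points is
imputed one target at a time from all its available inputs. Training
pairs come from participants complete on the pattern's time points.

Model families: a least-squares affine map (the deterministic baseline);
per-output-dimension RBF support vector regression (margin 0.1, after
standard scaling); Gaussian-process regression with an RBF kernel
(posterior-mean prediction, 5 optimizer restarts); and two conditional
generative networks. Both networks are deliberately tiny — one hidden
layer per component, hidden width equal to the output dimension, latent
size 1, batch size 1, hyperbolic-tangent hidden activations (sigmoid on
the discriminator output), Adam at its standard settings (1e-3,
(0.9, 0.999)), at most 1000 epochs — and are implemented directly in
numpy with manual backpropagation. Early stopping has patience 0 on a
held-out 20% of the training pairs: the CVAE monitors reconstruction +
KL at the posterior mean; for the cGAN the notion of "validation error"
is genuinely ambiguous under adversarial training, and the choice here is
the generator's adversarial loss on held-out pairs (the recorded training
curve is the discriminator objective, which is the component that behaves
monotonically early in training). The CVAE conditions on the
concatenation of *all* available time points jointly rather than on each
single one pairwise — a deliberate design choice that uses every
observation the participant has.

At imputation time the latent noise is drawn from N(0, 1), so repeated
rounds give different values; 5 rounds with seeds 0–4 are the default.
Per-round balanced accuracies are pooled with Rubin's rules: total
variance `W̄ + (1 + 1/m)·B`, tested with a one-sided Wald statistic
against 0.5. Observed values are copied bit-for-bit into every round, and
test folds never contain artificial values.

Three imputation modes feed the classifier: augment the training set with
all imputable incomplete series; with only those missing exactly one time
point; or complete only the incomplete minority-class series (balancing),
leaving controls complete-case.

## Classification and evaluation

Random forest (100 trees, Gini, unrestricted depth, `sqrt(m)` features
per split, bootstrap) is the primary classifier; SVC and AdaBoost are
comparators. Optional class weighting is inverse to class frequency.
Significance against chance uses a one-sided one-sample t test on the
per-fold accuracies (zero-variance samples take the limit convention
p ∈ {0, 1}); method comparisons use the two-sided Welch test. The
reported interval is mean ± 1.96·sqrt(sample variance) over the
(fold × run) accuracies. The p ≥ 0.05 reporting filter is applied only
at output time; raw records are always kept.

The experiment orchestration runs merge → impute → transform → select →
classify per outer fold. Merging precedes imputation so the imputers
operate on the reduced dimension. During feature-count selection all
fitting uses the inner-training fold only; for the final test evaluation
everything is refitted on the full train+validation remainder. When
imputation is stochastic, runs pair imputation seed r with classifier
seed r (5 paired runs rather than a 5×5 cross), keeping run counts
comparable across deterministic and stochastic methods; inner
feature-count selection uses the first imputation round only.

## Synthetic data

The generator draws logistic-normal studies: a latent AR(1) trajectory in
CLR space (`z_t = ρ z_{t−1} + N(0, σ²I)` around a base mean, default
σ = 0.5, ρ = 0 unless stated) mapped to the simplex by the softmax.
Class effects are planted as log-ratio shifts — ±Δ/2 on a species pair at
one time point — so Δ is the between-class difference of `log(x_i/x_j)`
in CLR units, directly interpretable in the geometry the method uses.
Structural zeros are imposed per species by zeroing values below the
species' target quantile; missingness is Bernoulli per time point,
optionally label-dependent (to emulate informative missingness).
Presets mirror the two cohort shapes the package targets: an imbalanced
T=3 study (82/15 complete plus 108/16 missing-last) and a near-balanced
T=6 study with availability decaying over time, both at reduced dimension
(d ≈ 20) so the full machinery runs in seconds.

What the generator does **not** emulate: phylogenetic correlation between
species, read-count (sequencing depth) noise, over-dispersion beyond the
logistic-normal, or non-stationary dynamics. Passing tests therefore
demonstrate that the machinery recovers effects that exist in its own
geometry and stays at chance when none do — not that real microbiome
cohorts carry such effects.

## Problem sizes and numerical choices

Verification runs use scaled-down but non-trivial sizes chosen so the
full suite completes comfortably on one core: the strong-signal pipeline
check uses n = 150, d = 20, T = 3, Δ = 2; the permutation-null and
missingness-baseline checks use n = 60–90 at d = 6–10 over 10 generator
seeds; the ANOVA recovery rate uses 40 seeds at n = 100. Row sums are
validated to 1e−9 in memory and renormalized at ingest when within 1e−6
of 1; CLR round-trips are exact to 1e−10; Ward ties are resolved by
scipy's deterministic linkage ordering, and all stochastic components
(fold dealing, generators, network initialization, latent noise) are
driven by explicit integer seeds, making every experiment bit-reproducible.

## Known limitations

* The linear/SVR imputers are deterministic, so their "multiple
  imputation" collapses to identical rounds; Rubin pooling then reduces
  to the within-variance term.
* The cGAN stopping rule is a pragmatic choice, not a solved problem;
  badly initialized adversarial pairs can stop very early.
* With the default lasso penalty the lasso ranking is degenerate (see
  above); it is retained as a faithful comparator, not a recommendation.
* PCA scores are dense combinations of all features, so feature-
  appearance reporting is not meaningful for the PCA selector.
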