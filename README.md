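# simplexts

Binary classification of **longitudinal compositional data** — e.g. gut
microbiome relative abundances sampled over repeated visits — when some
visits are missing. The package imputes missing time points in log-ratio
space, transforms compositions into real space via log ratios, selects
features, classifies, and evaluates with balanced accuracy under nested
stratified cross-validation, pooling multiple imputation rounds with
Rubin's rules.

It is aimed at researchers analyzing cohort studies of the form
*n participants × T time points × d species*, rows on the probability
simplex, with a binary outcome per participant and an appreciable
fraction of missed visits.

## The method

Each participant contributes compositions `x_{t} ∈ Δ^{d-1}` at time
points `t = 1..T` and a label `y ∈ {−1, +1}`. The pipeline runs, per
cross-validation fold:

1. **Merge** species whose training zero fraction exceeds a threshold
   into one `other_species` part.
2. **Impute** missing time points: every imputer maps the CLR
   concatenation `C_n` of the available time points to the CLR vector
   `C_m` of a missing one, then returns to the simplex via softmax.
   Families: affine least squares (`A C_n + b`), RBF support vector
   regression, Gaussian-process regression, a conditional VAE and a
   conditional GAN (both: one hidden tanh layer, latent noise ε ~ N(0,1)).
   Stochastic imputers run m = 5 rounds.
3. **Transform** the flattened series `X = [x_1, …, x_T]/T` (dimension
   D = d·T): raw *compositional*, *CLR* `log(x_i/g(x))`, *ALR* — all
   pairwise `log(X_i/X_j)` (D(D−1)/2 features) — or *PLR* pivot balances
   `log(g(left)/g(right))` at each node of a Ward hierarchy over the
   CLR-transformed training features (D features).
4. **Select** the top-n features by two-group ANOVA F (or lasso, mutual
   information, PCA), with n chosen by mean/median validation accuracy.
5. **Classify** with a random forest (or SVC, AdaBoost) and report
   balanced accuracy

   `acc = T_P/(2P) + T_N/(2N) = (sensitivity + specificity)/2`,

   which is 0.5 for constant decisions on any class balance. One-sample
   (one-sided, vs 0.5) and Welch tests give p-values; multiple-imputation
   runs are pooled with total variance `W̄ + (1 + 1/m)B` and a Wald test.

All fitting — zero replacement, sparsity profile, Ward tree, scalers,
rankings, imputers — uses training (or train+validation) data only, and
test folds never contain imputed values.

A synthetic-data module generates logistic-normal studies with planted
log-ratio class effects, AR(1) temporal correlation, structural zeros,
class imbalance and (optionally label-dependent) missingness, so the
whole pipeline is testable with known ground truth.

## Worked example

```python
import numpy as np
from simplexts import ExperimentConfig, run_experiment
from simplexts.synthetic import GeneratorSpec, generate

# 150 participants, 20 species, 3 visits; class +1 carries a 2-CLR-unit
# shift of log(x_0/x_1) at visit 1
spec = GeneratorSpec(
    n_per_class={-1: 75, 1: 75}, d=20, T=3, seed=0,
    planted_pairs=[(0, 1, 1, 2.0)], sigma=0.5,
)
ds, truth = generate(spec)

result = run_experiment(ds, ExperimentConfig(transform="plr", seed=0))
s = result.summary
print(f"balanced accuracy {s.mean:.3f} ± {s.ci_half_width:.3f}")
print(f"sensitivity {s.sensitivity:.2f}  specificity {s.specificity:.2f}")
print("features per fold:", s.optimal_n)
```

Output:

```
balanced accuracy 0.921 ± 0.096
sensitivity 0.90  specificity 0.95
features per fold: [2, 9, 2, 5, 2]
```

The mean test-fold balanced accuracy (0.921) shows the pivot-log-ratio
pipeline recovering the planted species-pair effect; the ± value is the
1.96·sd half-width over the 25 (fold × seed) runs, and the per-fold
feature counts are the n chosen by inner cross-validation. On
label-permuted data the same pipeline stays near 0.5.

The same workflow is available from the shell:

```bash
simplexts simulate --preset dataset1_like --seed 0 --out work/
simplexts run --data work/study.csv --seed 0 --out work/results/
simplexts report --in work/results/
```

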