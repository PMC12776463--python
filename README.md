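# cfrlearn

Counterfactual representation learning for estimating individualized drug
effects on two linked endpoints: incident conversion from mild cognitive
impairment (MCI) to Alzheimer's disease (AD), and months from MCI to
conversion. The package is aimed at observational pharmaco-epidemiology:
given a baseline cohort with a binary treatment indicator, it estimates,
per patient, what the model predicts would happen under treatment *and*
under control, and turns the difference into population summaries,
feature attributions, and rule-based subgroups.

## Model

For patient *i* with baseline covariates *x_i*, treatment *t_i* ∈ {0,1},
conversion indicator *y_inc* and months-to-conversion *y_time* (observed
only for converters, the set Ω_time), an encoder Φ produces a latent
embedding *z_i* = Φ(*x_i*) (MLP with batch norm, ReLU, dropout). Four
heads predict the potential outcomes Ŷ_inc(1), Ŷ_inc(0) (logistic link)
and Ŷ_time(1), Ŷ_time(0) (softplus link) from the shared embedding. To
mitigate confounding, the latent distributions of the two arms are
aligned by an integral probability metric (IPM) penalty — linear MMD,
RBF MMD, or entropic 1-Wasserstein — inside the training loss

  L_total = λ_inc·L_inc/r_inc + λ_time·L_time/r_time + α·IPM(z|t=1, z|t=0)

with factual losses only (each head learns from its own arm), running-mean
rescalers r, Adam (lr 2e-3, weight decay 1e-4, batch 128), and gradient
clipping at global norm 1. λ and α are selected on a validation grid.

Individualized treatment effects are
τ̂_inc = Ŷ_inc(1) − Ŷ_inc(0) (negative = benefit) and
τ̂_time = Ŷ_time(1) − Ŷ_time(0) (positive = delayed conversion);
ATE is their mean, with percentile-bootstrap intervals. Directional
feature effects DE_j intervene on one binary covariate at a time on the
treated prediction; uplift trees partition patients by a heterogeneity
gain Var(τ̂_S) − Σ weighted child variances + λ·|μ_L − μ_R|.

Everything is validated against a synthetic cohort generator with known
ground-truth potential outcomes, confounded assignment and heterogeneous
effects (real cohorts of this kind are access-restricted).

## Worked example

```python
import numpy as np
import cfrlearn as cf

sc = cf.generate_cohort(cf.standard_spec(n=4000, seed=7))
tc = cf.TrainConfig(epochs=120, early_stopping_patience=10**6, seed=1, alpha=1.0)
models = cf.train_ensemble(sc.cohort, None, tc, cf.IPMConfig(kind="mmd_rbf"), n_models=5)

tau = cf.ensemble_ite(models, sc.cohort.X, "incidence")
print(f"ATE_inc  {tau.mean():+.3f}   (generator truth {sc.truth.true_ite_inc.mean():+.3f})")
from scipy.stats import spearmanr
print(f"Spearman(tau, true ITE)  {spearmanr(tau, sc.truth.true_ite_inc).statistic:.3f}")
print(f"mean predicted delay  {cf.ensemble_ite(models, sc.cohort.X, 'time').mean():+.2f} months")
```

prints (about seven minutes on one CPU):

```
ATE_inc  -0.136   (generator truth -0.144)
Spearman(tau, true ITE)  0.541
mean predicted delay  +3.81 months
```

i.e. the five-seed ensemble recovers the true average risk reduction of
the simulated drug to within 0.01, ranks patients by benefit in agreement
with the generator's individual effects, and recovers the planted
+4-month conversion delay to within 0.2 months of its true value. From
there,

```python
tree = cf.build_tree(sc.cohort.X, tau, sc.cohort.covariate_kinds,
                     cf.TreeConfig(max_depth=3, min_node_size=100, seed=0),
                     feature_names=sc.cohort.covariate_names)
print(cf.uplift.format_rules(tree))
```

yields human-readable subgroup rules with leaf-level mean ITE, bootstrap
CI and support.

A command-line pipeline wraps the same steps
(`cfrlearn simulate | build-cohort | fit | predict | effects | tree |
diagnose | run`), driven by a YAML config; see `cfrlearn --help`.

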