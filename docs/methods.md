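# Methods

## Problem and model

The package estimates individualized effects of a drug on two linked
endpoints in patients with mild cognitive impairment (MCI): whether they
convert to Alzheimer's disease (AD), and after how many months. Under the
potential-outcomes framework each patient has four unobserved quantities —
incidence under treatment and control, Y_inc(1), Y_inc(0), and conversion
months Y_time(1), Y_time(0) — of which only the pair matching the assigned
treatment t is observed, and months only for converters (the set Ω_time).

An encoder Φ maps baseline covariates x ∈ R^d to a latent embedding
z = Φ(x) through an MLP with batch normalization, ReLU and dropout. Four
heads — two-layer MLPs with their own parameters — read the shared
embedding: incidence heads end in a logistic link, time heads in a softplus
link (so ranges hold structurally; softplus was chosen over a plain ReLU
output to avoid dead gradients at zero). The individualized treatment
effects are

    τ_inc = Ŷ_inc(1) − Ŷ_inc(0)   (risk difference; negative = benefit)
    τ_time = Ŷ_time(1) − Ŷ_time(0) (months; positive = delayed conversion)

and the ATE is their mean over the cohort.

## Training objective

Only the head matching the assigned arm receives a factual loss:
binary cross-entropy L_inc over all rows and squared error L_time over
Ω_time. The two are brought to comparable magnitude by running means
r_inc, r_time of the raw losses (exponential moving average, decay 0.99,
with a 50-step warm-up during which raw losses are used), then combined
with a distributional balance penalty on the latent batch:

    L_total = λ_inc L_inc / r_inc + λ_time L_time / r_time + α · IPM(z|t=1, z|t=0)

The integral probability metric is one of: linear-kernel MMD (squared mean
gap), RBF-kernel MMD (biased V-statistic, bandwidth from the median
pairwise-distance heuristic recomputed per batch), or an entropic
1-Wasserstein distance (log-domain Sinkhorn on the Euclidean cost, uniform
marginals, ε defaulting to 0.1 × the median cost; gradients use the
envelope approximation with the plan held fixed, which is exact in the
ε → 0 limit). Batches with an empty arm skip the penalty for that step and
increment a logged counter.

Optimization is Adam (learning rate 2e-3, weight decay 1e-4 applied as an
L2 term on weight matrices only, batch size 128) with gradients clipped to
a global L2 norm of 1.0. A cosine decay of the learning rate over the
epoch budget is enabled by default; it measurably stabilizes the effect
estimates and can be disabled (`lr_schedule: constant`). The monitor used
for early stopping and checkpoint selection evaluates the validation
L_total with rescalers frozen at the end of warm-up — a moving-target
normalizer would otherwise make later epochs incomparable with earlier
ones and systematically select underfit checkpoints.

λ = (λ_inc, λ_time) and α are chosen on a stratified 20% validation split
by a composite objective

    w_auc·AUC − w_cal·Brier − w_rmse·(RMSE / sd(y_time)) − w_ipm·IPM_std

(defaults 1, 0.5, 1, 0.5), where RMSE is normalized by the standard
deviation of observed conversion months on the validation split and the
IPM is computed between arms after per-dimension standardization of the
pooled validation embeddings, making both penalty terms scale-free. The
search is staged — λ scanned at α = 1, then α over {0.1, 0.5, 1, 2, 10} at
the selected λ — with ties broken toward the smaller α, then the smaller
λ_time. The full product grid is available behind a flag. Selected models
are not refit on train+validation.

Point estimates of effects benefit from a small seed ensemble
(`train_ensemble`, default 3–5 members differing only in seed): averaging
member ITEs damps initialization and minibatch noise, which is the
dominant error source for τ_time at cohort sizes of a few thousand.

## Effect summaries

Bootstrap confidence intervals for the ATE are percentile intervals over
patient resamples of the fixed fitted model's ITEs ("prediction
bootstrap"; the seed protocol — one `(n_boot, n)` index draw from
`default_rng(seed)`, row means, linear-interpolation quantiles — is part
of the contract). A full-refit bootstrap is out of scope at desk scale.

Directional effects intervene on one binary covariate at a time,
DE_j = mean[Ŷ_inc(1)|x_j:=1 − Ŷ_inc(1)|x_j:=0], holding everything else
fixed: a counterfactual, not correlational, attribution on the treated
potential outcome. Pairwise interactions are the corresponding double
difference (departure from additivity), symmetric by construction, with
an empty diagonal. Continuous covariates (age) are excluded unless the
caller binarizes them, since the intervention is defined on presence
versus absence.

Subgroup summaries report, per group: mean τ, within-group SD (the
variability axis; no other convention is defined), benefit probability
P(τ_inc < −δ) and harm probability P(τ_inc > +δ) with δ = 0 by default.

## Uplift trees

Per-patient τ_inc values are partitioned by greedy recursion. A split of
node S on covariate j at threshold c scores

    Gain = Var(τ_S) − (|L|/n)Var(τ_L) − (|R|/n)Var(τ_R) + λ·|μ_L − μ_R|

with population variances, so at λ = 0 the gain is exactly the
between-group term of the law of total variance and is never negative.
Binary covariates split at 0.5 (absent left / present right); continuous
covariates are tried at node-local deciles — node-local rather than
root-level quantiles keep candidate diversity deep in the tree. Growth
stops at the depth cap (default 4), below twice the minimum node size
(default 50), or when no candidate gain exceeds 1e-12 (the floor absorbs
floating-point residue on constant nodes). Ties break toward the lower
feature index, then the lower threshold. Leaves carry the mean ITE, a
seeded 500-resample percentile bootstrap interval, and their support.

## Cohort construction

`build_treatment_cohort` turns a longitudinal event log into an analysis
cohort with a fixed, first-failing-rule exclusion order: MCI present →
age ≥ 50 at first MCI → no AD/dementia before first MCI → follow-up
(last event − first MCI) ≥ 1 year → ≥ 3 visits on/after first MCI → arm
rules. Treated patients start the drug after first MCI and before any AD
diagnosis with ≥ 3 prescriptions; controls have no exposure in the washout
window after MCI onset. The washout defaults to 3 years and is
configurable (5 years is an equally defensible reading of the design);
both are supported. Baseline comorbidity flags are diagnosis codes dated
on/before the first MCI (inclusive). Months are floor(days / 30.44).
"Continuous follow-up" is operationalized as the span from first MCI to
the last recorded event, since EHR-style logs carry no enrollment spans,
and the visit count is taken over the whole follow-up window.

## Synthetic cohorts

Real cohorts of this kind live in restricted clinical data warehouses, so
validation uses a generator with known ground truth. Covariates are
independent Bernoulli comorbidities plus Gaussian age; continuous
covariates enter every linear predictor standardized by their specified
mean/sd. Treatment is Bernoulli(logistic(x'γ)); incidence potential
outcomes are logistic with a treatment main effect and per-covariate
effect modifiers; conversion months are linear with a treatment delay and
truncated Gaussian noise (max(0, ·) — the simplest family consistent with
nonnegative months). Both potential outcomes per endpoint share one
uniform draw per patient (common random numbers), so per-patient true
effects are well defined. Months are generated for everyone but masked
unobserved for non-converters, mirroring Ω_time. Degenerate single-arm
draws raise an error rather than silently resampling.

The reference conditions (`standard_spec`, chosen once): n = 4000 at
seed 7 for recovery studies; comorbidity prevalences typical of MCI
cohorts (diabetes 0.30, hypertension 0.50, obesity 0.25, stroke 0.10,
depression 0.20, TBI 0.05, plus a null marker at 0.30 with no role in any
model); age 72 ± 8; confounding through diabetes, hypertension, depression
and age shared between propensity and outcome (a `confounding_scale` knob
scales the shared coefficients); a protective treatment main effect of
−0.9 on the conversion log-odds with modifiers +0.4 (diabetes) and −0.5
(depression); and a homogeneous +4-month conversion delay with 6-month
noise. `easy_spec` strengthens the covariate signal and removes
confounding to probe factual discrimination. The generator emulates
confounded assignment, heterogeneous effects and shifted conversion times
with independent covariates and static baselines; it does not emulate
coded-vocabulary noise, longitudinal covariate drift, or informative
censoring beyond the converters-only mask — so passing recovery tests
demonstrates correctness of the estimation machinery, not robustness to
those real-data pathologies.

## Evaluation protocol and problem sizes

The reference evaluation (mirrored by `scripts/acceptance.py` and the
end-to-end tests) uses: a five-member seed ensemble, 120 epochs with full
cosine decay and no early stopping, α = 1 with RBF-MMD, on the n = 4000
standard cohort for effect recovery; ten paired α = 2 vs α = 0 runs
(40 epochs, n = 1200, confounding scale 1.5) for balance efficacy; ten
40-epoch runs (n = 1500) for directional-effect signs; and ten-fold
cross-validation (30 epochs, n = 1500) on the easy cohort for factual
AUC. These sizes are the package's reference conditions; larger budgets
sharpen the same conclusions.

## Numerical conventions and edge cases

* SMD uses pooled sample variances (ddof = 1); two constant equal arms
  give 0, constant unequal arms give inf (not standardizable).
* Multivariate balance in latent space is summarized as the mean of
  per-dimension two-sample KS statistics; no canonical multivariate KS
  reduction exists, so the reduction is named in the output.
* AUC counts ties as one half and is NaN (undefined), never 0.5, on a
  single-class split; C-index and Spearman require ≥ 2 observed times.
* Cross-validation folds are stratified jointly on (treatment, incidence).
* Evaluation mode disables dropout and switches batch norm to running
  statistics, making counterfactual predictions deterministic; batch-norm
  biases start at zero, which parks ReLU pre-activations exactly on their
  kink at initialization — relevant only to finite-difference testing.
* One global seed derives all stage seeds as CRC-32("stage:seed") mod
  2^31, so inserting a pipeline stage never shifts another stage's
  randomness.

## Known limitations

Non-converters contribute nothing to the time endpoint (no
censoring-aware likelihood), so τ_time extrapolates the time heads to
patients without observed conversion; its cohort mean is the noisiest
reported quantity, which is why the ensemble default exists. The
composite objective's functional form is a pragmatic scalarization, not a
derived criterion. Uplift trees are single greedy trees — no honesty,
pruning, or forests. The event-log vocabulary is a toy (plain code
strings), deliberately outside real ICD/RxNorm mapping.
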