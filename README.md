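# intlognet

Network-penalized integrative logistic regression for biomarker
identification across multiple case/control cohorts.

## The problem

Biomarkers selected from a single expression study rarely replicate in
another: sample sizes are small relative to the number of genes, and
platform/laboratory batch effects shift each cohort's baseline. `intlognet`
fits **one** sparse logistic regression model *jointly* across M cohorts
that measure the same p features, keeping what should be shared (the gene
effects) shared, while absorbing what is cohort-specific (the baseline)
into per-sample intercepts that are shrunk toward cohort-wise constancy.

## The model

For sample i of cohort m with expression row X_i and outcome Y_i ∈ {0, 1},

    logit P(Y_i = 1 | X_i) = β₀,i + X_i β,

with one coefficient vector β shared by all cohorts and a per-sample
intercept β₀,i. The fit minimizes

    (1/N) Σ_i [ −Y_i (β₀,i + X_i β) + log(1 + exp(β₀,i + X_i β)) ]
        + λ P_α(β) + μ β₀ᵀ L̃ β₀ ,

where L̃ is the Laplacian of the *sample-relation network* (an edge between
every pair of samples from the same cohort), so μ β₀ᵀL̃β₀ penalizes
within-cohort intercept differences while leaving cohort-level differences
free. The variable penalty P_α is one of

| kind          | P_α(β)                                       |
|---------------|----------------------------------------------|
| `lasso`       | ‖β‖₁                                         |
| `enet`        | ½(1−α)‖β‖₂² + α‖β‖₁                          |
| `network`     | ½(1−α) βᵀLβ + α‖β‖₁                          |
| `abs_network` | ½(1−α) \|β\|ᵀL\|β\| + α‖β‖₁                  |

with L the normalized Laplacian of a feature network (e.g. a
protein–protein interaction graph). The `abs_network` form lets connected
genes carry strong coefficients of *opposite* sign and still be selected
together.

The optimizer is a proximal Newton method: each outer step forms the IRLS
working response and solves the penalized weighted least-squares
subproblem by alternating an exact blockwise linear solve for β₀ with
cyclic coordinate descent (soft-thresholding updates) for β, guarded by
step halving so the objective never increases. Prediction for a new sample
from cohort m uses the cohort's averaged intercept:
p̂ = logistic(β̄₀^m + X β̂).

## Worked example

```python
import numpy as np
import intlognet as il

# four heterogeneous cohorts from the TF-module generator (p = 550)
config = il.SimulationConfig(n_TF=50, seed=7)
train, test, beta_true, net = il.simulate(config)

cfg = il.PenaltyConfig(kind="abs_network", alpha=0.5, lam=0.1, mu=1.0)
fit = il.fit_integrated(train, cfg, net=net)

X_test = np.vstack([X for X, _ in test])
y_test = np.concatenate([y for _, y in test])
origin = np.repeat([1, 2, 3, 4], 100)
p_hat = il.predict_proba(fit, X_test, dataset_of_origin=origin)

pred = il.prediction_metrics(y_test, p_hat)
sel = il.selection_metrics(fit.beta, beta_true)
```

Output:

```
dataset intercepts: [-0.66 -0.2   0.37  0.59]
pooled test AUC:    0.938
accuracy at 0.5:    0.830
selected features:  26 (precision 0.96, recall 0.57)
subnetworks:        5 components, largest = 8 genes (TF2, TF2_RG1, ...)
```

The four fitted cohort intercepts recover the ordering of the true
baselines (−3, −1, 1, 3; penalization attenuates their scale along with
β), the shared coefficients rank the 400 pooled test samples at AUC 0.94,
and 25 of the 26 selected features are true signal genes falling into five
connected modules of the regulatory network.

A command-line interface mirrors the library
(`intlognet simulate / fit / cv / predict / evaluate / experiment /
subnets`); run `intlognet --help`.

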