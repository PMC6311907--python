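# Methods

## Model

`intlognet` fits a logistic regression jointly over M case/control cohorts
that measure the same p features. Writing N = Σ_m N^m for the stacked
sample count, the estimate minimizes

    f(β₀, β) = (1/N) Σ_i [ −Y_i η_i + log(1 + exp(η_i)) ]
               + λ P_α(β) + μ β₀ᵀ L̃ β₀,      η_i = β₀,i + X_i β.

Two graphs enter the penalty:

- **Sample-relation Laplacian L̃** — the combinatorial Laplacian of the
  graph joining every pair of samples in the same cohort. Its quadratic
  form equals Σ_m Σ_{i<j∈m} (β₀,i − β₀,j)², so the penalty vanishes
  exactly when intercepts are constant within every cohort and never
  touches between-cohort differences (cohort-constant vectors span its
  null space). The combinatorial form is the default because this
  exact-vanishing property is the point of the device; a degree-normalized
  variant (each block scaled by 1/(N^m − 1)) is available via
  `SampleRelationLaplacian(..., normalized=True)` for users who want the
  penalty weight independent of cohort size.
- **Feature Laplacian L** — the symmetric normalized Laplacian
  I − D^{−1/2} A D^{−1/2} of an undirected feature network. Rows/columns
  of isolated features are zero, so degree-0 features feel only the L1
  term. Binary adjacency is the default; weighted edge lists propagate
  into degrees and L.

Penalty kinds: `lasso` (α forced to 1), `enet`, `network`
(½(1−α)βᵀLβ + α‖β‖₁) and `abs_network` (½(1−α)|β|ᵀL|β| + α‖β‖₁). The last
is nonconvex but coordinate-wise exactly solvable; it tolerates connected
features with opposite effect signs.

## Optimization

Proximal Newton. Each outer iteration linearizes the log-likelihood at
the current iterate (working response Z_i = η_i + (Y_i − p_i)/W_ii,
weights W_ii = p_i(1 − p_i), probabilities clipped to [ε, 1−ε] with
ε = 10⁻⁵) and solves

    min (1/2N) Σ_i W_ii (Z_i − β₀,i − X_i β)² + λ P_α(β) + μ β₀ᵀL̃β₀

by alternating:

1. **Exact β₀ solve.** Stationarity gives ((1/N)W + 2μL̃) β₀ =
   (1/N) W (Z − Xβ). Each cohort block is diagonal-minus-rank-one
   (c(nI − J) structure of the complete-graph Laplacian), solved in O(n)
   with the Woodbury identity. The Woodbury denominator 1 − c·Σ 1/D_i is
   rearranged as Σ_i (w_i/N)/(n D_i), a sum of positive terms, so the
   solve has no cancellation and stays accurate as μ → ∞ (verified to
   spread < 10⁻⁴ within blocks at μ = 10⁸).
2. **Coordinate descent in β.** Cyclic sweeps in fixed ascending feature
   order (reproducibility), each coordinate updated by soft-thresholding
   β_k = S(u_k, v_k) with the penalty-specific numerators: the network
   coupling λ(1−α) Σ_j A_kj β_j /√(d_k d_j) enters u_k for `network` and
   (with |β_j|) lowers the threshold v_k for `abs_network`. For
   `abs_network` the effective threshold can turn negative; S is applied
   literally, which is the exact branch-wise minimizer (|β_k| then equals
   |u_k| + |v_k|). When |u_k| = v_k exactly, β_k = 0. Features with zero
   weighted curvature and no ridge term are skipped with a warning. After
   each full sweep the nonzero support is iterated to convergence
   (active-set refinement) before the next β₀ solve. The kernel is
   numba-compiled with a maintained residual.

The alternation stops when the largest coefficient/intercept change drops
below `tol_inner` (10⁻⁵) or after `max_inner_sweeps` (200) sweeps. The
outer loop stops on relative objective change below `tol_outer` (10⁻⁶) or
`max_outer` (50) iterations. A step-halving safeguard (≤ 20 halvings)
rejects any outer step that would increase f — plain proximal Newton can
overshoot on (near-)separable data — making the objective trace provably
non-increasing; for convex kinds the inner subproblem value is also
checked non-increasing as a bug trap.

Initialization: β = 0 and β₀,i = logit of the sample's cohort outcome
prevalence (clipped), which is cohort-wise constant and hence free of
penalty at the start.

Merged and single-cohort baselines use the same machinery with the
intercept forced exactly constant over the block (the μ → ∞ limit,
computed as the W-weighted mean rather than with a large μ); the μ-term
then contributes nothing. `fit` with μ = 10⁶ on one cohort agrees with a
reference L1-penalized logistic regression to < 10⁻³ per coefficient.

Selection uses |β_k| > 10⁻⁸ as the nonzero criterion.

## Estimators and model selection

- `fit_integrated` — the joint model above; per-cohort intercepts
  reported as within-cohort means of β₀.
- `fit_merged` — all cohorts pooled with one common intercept.
- `fit_single` — ordinary penalized logistic regression on one cohort.
- `predict_proba` — logistic(β̄₀^m + Xβ̂) using the intercept of the
  sample's cohort of origin; an unseen origin is an error (the model has
  no intercept for it) unless the averaged-intercept fallback is opted
  into.
- `cross_validate_lambda` — folds are stratified by outcome *within each
  cohort* (guards against class-empty folds at cohort sizes near 100 and
  keeps every fold's cohort composition intact); the score is AUC on the
  fold's pooled validation samples; the grid is traversed from large to
  small λ with warm starts; ties go to the larger (sparser) λ; the final
  model is refit on all training data at the winner. The default grid is
  10 log-spaced values in [10⁻³, 1], bracketing the null model and the
  nearly-unpenalized fit at the generator's signal strengths. μ = 1 and
  α = 0.5 are fixed by default (λ-only tuning, matching the study
  protocol); a joint grid can be swept by calling `cross_validate_lambda`
  per (α, μ) pair.

## Synthetic data

The generator emulates case/control expression studies driven by a
TF-module regulatory network:

- **Network**: n_TF transcription factors (default 200), each linked to
  its own n_RG = 10 regulated genes; p = n_TF(1 + n_RG) = 2200 by
  default. The total feature count is a package default (the study design
  this mimics uses 200 modules); it is configurable, and scaled runs
  state the p they used.
- **Expression**: TFs i.i.d. N(0, 1); each target is bivariate normal
  with its TF at correlation ρ = 0.7, i.e. conditionally
  N(0.7·x_TF, 0.51), so targets are marginally standard normal.
- **Coefficients**: only the first four modules (44 features) carry
  signal. Setting 1 is a fixed block vector: TF weights ±√5 (modules
  1–2) / ±√3 (modules 3–4), seven targets at ±5/√10 (resp. 3/√10)
  sharing the TF's sign, and three opposite-signed targets per module.
  Setting 2 keeps a fixed sign pattern (11+, 11−, 7+, 4−, 7−, 4+) with
  magnitudes drawn U[0, 3], redrawn each replicate.
- **Heterogeneity**: cohort m's per-sample intercepts are
  N(mean_m, 0.5) around means (−3, −1, 1, 3). The 0.5 is read as a
  *variance* (sd ≈ 0.707), matching the variance convention of the
  N(0.7x, 0.51) noise term in the same design; an `spread_is_variance`
  flag flips the interpretation. Test-set intercepts are fresh per-sample
  draws from the same mechanism.
- **Outcomes**: Y_i ~ Bernoulli(logistic(β₀,i + X_i β)). A cohort drawn
  all one class is redrawn with a logged warning (≤ 10 attempts). Each
  replicate is fully determined by one integer seed.

What the generator does *not* emulate: platform/probe measurement noise,
missing values, non-Gaussian expression marginals, or feature networks
with hubs/cliques beyond star modules. Passing the simulation tests
therefore demonstrates correct operating characteristics under the
generative model, not performance on real microarray cohorts.

With the setting-1 coefficients, var(X β) ≈ 160, so the linear signal
dominates the ±3 cohort baselines and class labels are nearly
deterministic functions of η; prevalences sit near 0.5 in every cohort.

## Evaluation harness

`run_experiment` replicates the study protocol: per replicate, simulate;
for each requested (scheme × penalty) method select λ by 5-fold CV, refit
on the full training data, predict the pooled 4 × 100 test samples and
score sensitivity/specificity/accuracy (threshold 0.5 on p̂) and AUC
(rank statistic, ties ½), plus precision/recall/F1 of the selected
support against the 44 true signal features. The no-integration baseline
fits each cohort separately and reports the model with the best pooled
AUC (its other metrics come from that same model). F1 is always the
harmonic mean of the reported precision and recall. Failed replicates are
re-seeded and retried (≤ 2), never dropped. Means and sds over replicates
are tabulated per method.

`extract_selected_subnetworks` induces the feature network on the
selected support and returns connected components sorted by size — the
"subnetwork biomarkers" interpretation of a network-penalized fit.

## Preprocessing recipe

For real cohorts: collapse probes to genes by mean; drop genes absent
from the interaction network; keep the 2000 most-variable genes per
cohort (unbiased variance, ties by name) and intersect across cohorts;
mean-impute and standardize each gene to mean 0/sd 1 *per cohort*.
Normalization runs after all filters — an explicit choice where the
order is not dictated — and a constant gene becomes an all-zero column
with a warning. No GEO/BioGRID downloaders are included; inputs are
plain TSV/SIF files.

## Known limitations

- Prediction requires the test sample's cohort to have been present at
  training time (per-cohort intercepts); the averaged-intercept fallback
  is a heuristic, off by default.
- The `abs_network` objective is nonconvex: coordinate descent reaches a
  coordinate-wise minimum that may depend on the (fixed) sweep order.
- λ grids are warm-started but not pathwise in the strong-rule sense; very
  large p may warrant screening rules not implemented here.
- The intercept linear solve exploits the complete-graph block structure;
  replacing the sample-relation graph with an arbitrary one would need
  the dense per-block fallback.
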