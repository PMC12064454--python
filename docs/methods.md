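# Methods

## Model

`dyadcfm` fits a two-level structural equation model for distinguishable
dyads observed over a daily diary. Shared constructs (we-disease
appraisal WDA, common dyadic coping CDC, daily relationship
satisfaction RS) are **common fate** latents: one dyad-level variable
per level measured by the two partners' reports with both unstandardized
loadings fixed to 1 and the latent variance free. Quality of life, ART
adherence and PrEP attitude are non-common-fate: partner-specific
observed outcomes (single indicators with residual fixed to 0, the
outcome disturbance carried in Ψ). The within/between decomposition is
latent — implicit in the two-level likelihood — not manual centering.

Identification note: fixing both loadings to 1 (rather than fixing the
latent variance) is the classic common fate parameterization for
distinguishable dyads; unequal *standardized* loadings between partners
then arise purely from unequal residual variances. The two schemes are
observationally equivalent and produce the same standardized solution.

Six outcome models are available (`daily_qol`, `daily_rs`, `post_qol`,
`post_adherence`, `post_prep`, `post_rs`). Daily outcomes appear at
both levels; post-diary outcomes enter the between level only, so their
mediation is 1-1-2. The binary adherent indicator (days > 28 of 30) is
treated as a continuous 0/1 outcome in the linear model and its
chi-square-based fit indices are suppressed; this preserves the
product-of-paths arithmetic for its indirect effect at the cost of an
approximate likelihood for a Bernoulli margin. Dyad-level observed
covariates can be added as exogenous regressors on all between-level
endogenous variables; the default analysis runs without covariates.

## Likelihood and estimation

A dyad with n_j complete diary days and between-only observations z_j
contributes a multivariate normal likelihood with covariance
`I_{n_j}⊗Σ_W + J_{n_j}⊗Σ_B` plus the z blocks of Σ_B. This is
evaluated via the eigenstructure of the day-exchangeable matrix:
n_j − 1 deviation components governed by Σ_W and one cluster-mean
component jointly normal with z_j under `Σ_B + Σ_W/n_j`, including the
`−(p_W/2)·ln n_j` Jacobian of moving from the orthonormal mean
component to the mean's own density. Clusters are grouped by n_j and
reduced to sufficient statistics (deviation SSCP; per-group SSCP of
[mean, z] rows), so one likelihood evaluation costs a handful of small
matrix operations regardless of the number of dyads. A dense
multivariate-normal evaluation exists as a test oracle and agrees to
better than 1e-8.

Missing data: day-level full-information ML. A dyad-day enters only if
both partners' records are present and complete on the model's items;
dyads keep whatever days survive (n_j-specific likelihood). This
captures the dominant mechanism in diary data — skipped person-days —
without item-level pattern explosion. Clusters left with zero usable
days are dropped with a logged count.

Optimization is L-BFGS-B on an unconstrained reparameterization
(log-variances, raw paths and means) with **analytic gradients**: the
moment-space score `∂ℓ/∂Σ = −½(mΣ⁻¹ − Σ⁻¹SΣ⁻¹)` chained through the
structural form (`∂ℓ/∂ψ_k = (AᵀGA)_kk`, `∂ℓ/∂θ_i = G_ii`,
`∂ℓ/∂B_{d,s} = 2[C_η(ΛᵀGΛ)(I−B)⁻¹]_{s,d}` with `A = Λ(I−B)⁻¹`).
Start values are method-of-moments: grand means; common-fate latent
variances from the cross-indicator covariance at each level (exact
identity under unit loadings); structural paths from the normal
equations among the approximate latent moments; disturbances and
residuals by subtraction, floored away from zero. This start typically
lands within a few dozen iterations of the optimum; a path-at-zero
start reaches the same optima but needs roughly three times the
iterations. Non-positive-definite proposals return −∞ (optimizer-safe);
convergence failures and boundary variance estimates are flagged on the
result, never discarded silently.

Standard errors come from the inverse of the observed information,
computed by central finite differences of the analytic gradient and
delta-method-transformed to the natural scale. Wald z statistics and
p-values are reported (the reference distribution for these tests is
not further refined to a t with specific degrees of freedom).

## Fit indices

χ² = 2(ℓ_sat − ℓ_model) against a numerically maximized saturated
two-level moment model (Cholesky-parameterized); the CFI/TLI baseline
is the independence model (free variances and means, zero covariances)
at both levels. RMSEA uses N = total within-level observations
(dyad-days); the convention is recorded in the output metadata so a
different convention can be applied post hoc. SRMR is computed per
level from standardized residuals of the saturated ML moment estimates
against the model-implied matrices — under missingness and unbalance
the saturated estimates are the coherent "sample" moments. With df = 0,
RMSEA and TLI are reported as not applicable.

## Indirect effects

The indirect effect is exactly `â·b̂`. Its CI is Monte Carlo: 20,000
draws (default; seed mandatory) of (a*, b*) from a bivariate normal
centered at the estimates with the **joint** covariance submatrix of
the observed-information inverse — a and b share an equation system, so
sampling them independently is a known source of bias — and empirical
percentiles of a*·b*. The delta-method SE `√(b²V_aa + a²V_bb + 2abV_ab)`
is reported alongside. A degenerate (zero) covariance collapses the CI
to the point estimate.

## Synthetic data generator

The generator is the joint model read forward: per dyad, between-level
latents in topological order (WDA, then CDC = a_B·WDA + ζ, then outcome
latents), per day the within-level analogues, observed scores as
mean + between part + within part. It emulates a 141-dyad × 14-day
diary among serodiscordant male couples: 7-point daily single items
(0–6), a five-item coping subscale (0–30), post-diary totals
(WHOQoL-HIV BREF 0–116 / WHOQoL BREF 0–96, PrEP attitude 0–20, CSI
0–20), 4.4% of person-days missing completely at random, and 14.9% of
patients adherent (>28 of 30 days).

Default variance components are *solved*, not asserted: from target
means/SDs/ICCs per variable and role and target standardized loadings
per level, the shared-latent variance at each level is
`φ = λ_p·λ_a·s_p·s_a` (geometric convention over the two partners'
standardized loadings and level-specific SDs), endogenous disturbances
are target variance minus the structurally explained part, and
indicator residuals follow by subtraction. Structural paths default to
the published two-level estimates (a = 4.78 within / 2.08 between, and
the per-outcome b and c paths). The resulting panel reproduces the
target ICCs (e.g. 0.83 for we-disease appraisal) and moment structure;
tests verify pooled-within/between sample moments against the analytic
Σ_W, Σ_B within Monte Carlo error.

Adherence days are generated marginally as `30 − Poisson(λ)` truncated
to [0, 30], with λ solved so P(days > 28) hits the target fraction —
the printed margin is matched without inventing a structural claim the
study did not make. Scores are continuous (latent-normal) by default;
`likert=True` rounds and clips to the instrument grids as a robustness
variant, since the estimator assumes multivariate normality.

What the generator does **not** emulate: floor/ceiling effects and
discreteness of real Likert responses (unless the rounding switch is
on), day-of-week or autoregressive dynamics (the model has none),
informative missingness (MCAR only — the weakest mechanism compatible
with FIML), and any covariate structure. Passing tests therefore
demonstrate correctness of the machinery under the model's own
assumptions, not robustness to their violation.

## Simulation scale and known limitations

Simulation-based tests run at the study's own size (141 × 14, ~1,780
dyad-days after missingness): 500 replicate refits for CI coverage
(observed 95%-CI coverage ≈ 0.96) and 200 replicates per model for
parameter recovery.

At 141 clusters the ML estimator carries visible finite-sample bias:
the within-level shared-appraisal latent is weakly identified (variance
≈ 0.08 against residuals ≈ 0.4–0.5, standardized loadings ≈ 0.4), so
ratio-type path estimates are right-skewed (the a-path mean over
replicates exceeds the generating 4.78 by roughly 5%) and between-level
variance components are biased downward by a few percent, the classic
O(1/J) behaviour. Bias vanishes as the number of dyads grows (verified
at J = 1500–3000 in the test suite); it is a property of maximum
likelihood at this design size, not of the implementation. Interval
coverage for the indirect effect is nevertheless close to nominal.

Other limitations: no robust (sandwich) or Bayesian standard errors; no
categorical-outcome link for adherence; no random slopes or cross-level
interactions; item-level missingness is handled by day deletion rather
than item-level FIML patterns.
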