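# Methods

## Model and estimation

`mmnet` fits Gaussian multilevel models in which an individual response
depends on several *classifications* — groupings that enter the random part
of the model. A classification may be single-membership (each individual in
exactly one school or county) or multiple-membership (an individual belongs
to several network subgroups with weights). For individual *i*:

    y_i = x_i'β + Σ_k Σ_j w_ij^(k) u_j^(k) + e_i,
    u^(k) ~ N(0, σ²_k I),   e ~ N(0, σ²_e I),

with random-effect sets independent across classifications. Priors are flat
on β and Gamma(a, b) on each precision, a = b = 0.001 by default (the
conventional diffuse choice in multilevel MCMC software; configurable). All
full conditionals are conjugate, so the sampler is a plain Gibbs sweep:
β from its Gaussian conditional; each u^(k) jointly from a multivariate
Gaussian with precision Z_k'Z_k/σ²_e + I/σ²_k; precisions from Gamma
updates.

Numerical choices:

- **Joint random-effect draws via a one-off eigendecomposition.** For each
  classification, Z_k'Z_k is decomposed once (symmetric eigendecomposition);
  every subsequent joint draw costs two K×K matrix–vector products instead
  of a fresh O(K³) factorization. A single-site updater is also implemented
  (`update="single"`); both target the same posterior and the test suite
  checks they agree within Monte-Carlo error.
- **All-zero weight columns** (subgroups nobody belongs to after
  restriction, e.g. never-nominated individuals in the ego-net
  classification) are dropped before sampling: their conditional equals the
  prior and keeping them only adds noise to the variance update. Reported
  random-effect vectors are re-expanded with zeros.
- **Starting values**: β at OLS; each variance at the empirical response
  variance divided equally among the components. Diffuse-prior Gibbs
  samplers for Gaussian models are insensitive to these choices after
  burn-in; halving or doubling the starting split moves no reported
  posterior mean by more than Monte-Carlo error in our checks.
- **Burn-in**: default 2,000 of a 20,000-draw chain. The recovery studies in
  the test suite and the acceptance script use 2,500 draws with 500 burn-in,
  which the effective-sample-size diagnostics show is ample for these
  posteriors at n ≈ 1000; production analyses should keep the long default.
- **Determinism**: a single `numpy` Generator seeded from `random_state`
  drives the whole chain; identical data + seed reproduce chains
  bit-identically.

DIC is computed as 2·mean(D) − D(θ̄) with the plug-in deviance at the
posterior means of *all* parameters — β, every random effect, and σ²_e —
matching the convention of the standard multilevel MCMC packages; pD =
mean(D) − D(θ̄). Other plug-ins (e.g. marginalizing the random effects)
give different pD and are out of scope.

## Network classifications and weights

From directed nominations D (zero diagonal, out-of-sample alters dropped on
parsing, creating sample isolates) the package derives:

- **Ego-nets**: the random effects entering individual i's response are
  those of i's alters, one effect per individual-as-network-member. Under
  equal weights the resulting n×n weight matrix *is* the row-standardized
  adjacency matrix, so the ego-net multiple-membership model and the
  network disturbances model use literally the same weight information —
  the property the head-to-head comparison relies on. The ego is never a
  member of its own ego-net.
- **Cliques**: maximal (Luce–Perry) cliques of the symmetrized network,
  enumerated by Bron–Kerbosch (networkx) with a canonical sort so repeated
  runs are byte-identical. When dyad (clique-2) and clique-3 classifications
  enter one model jointly, the dyad level holds cliques of size exactly 2
  and the clique-3 level everything larger; non-maximal complete subgraphs
  are never emitted.
- **Schemes**: `equal` (1/n_i, rows sum to 1 or 0), `unit` (1), `inv_sqrt`
  (1/√n_i with n_i the individual's own membership count). Schemes apply to
  network classifications; school/area are single-membership and always
  carry one weight of 1.

## Variance partition

Raw multiple-membership components are not comparable across levels: the
contribution to individual i's variance is σ²_k Σ_j w_ij², which under
equal weights is σ²_k/n_i. The average membership factor
f_k = (1/n) Σ_i Σ_j w_ij² (isolates included as zeros) converts σ²_k into
its average contribution A_k = σ²_k·f_k. Shares are reported against the
factor-adjusted total σ²_e + Σ A_k — the quantity that is ≈ 1 for a
standardized response — and the unadjusted sum σ²_e + Σ σ²_k is reported
alongside, since for multiple-membership models it exceeds 1 and the gap is
itself diagnostic.

## Network autocorrelation models

The effects model Y = ρW₁Y + Xβ + ε, the disturbances model
Y = Xβ + δ, δ = ρW₂δ + ε, and their combination are estimated by maximum
likelihood. β and σ² are profiled out analytically (OLS of the transformed
response for the effects model, GLS at fixed ρ for the disturbances model);
the profile likelihood is maximized over ρ by bounded scalar search in
(−1, 1) — admissible for a row-standardized W, whose spectral radius is at
most 1; zero rows are allowed — with the log-Jacobian log|I − ρW| computed
by sparse LU per evaluation. The combined model starts (ρ₁, ρ₂) from the
two one-parameter fits and polishes by L-BFGS-B. Standard errors come from
the inverse numerical observed information of the full (ρ, β, σ²)
likelihood. σ̂² is the ML estimator (RSS/n); a degrees-of-freedom corrected
RSS/(n−p) can be derived from the stored quantities but is not the reported
value. AIC = 2k − 2·loglik with k = p + (#ρ) + 1.

## Synthetic populations

The generator emulates the structure the models assume, not any particular
data set:

- **Groups**: near-even school sizes; each school has a home county and a
  small fraction (default 2%) of students live elsewhere, so three counties
  hold only crossers — matching the near-nesting and the one-or-two-student
  counties typical of school-based samples.
- **Covariates**: female 52%, black 17%, age truncated-normal
  N(14.76, 1.5²) on [10, 19], centred before model use.
- **Network**: each ego draws latent nominations up to 5 per sex with a
  two-point sociality mixture (low/high propensity), preferring same-school
  (log-weight 4) and same-sex (log-odds 1) alters; each nomination is then
  retained with a probability solved numerically so the expected isolate
  share hits the 39% target. Thinning emulates out-of-sample friends; the
  mixture's overdispersion lets the isolate share and a non-isolate mean
  out-degree near 1.7 coexist. The generator makes no claim to reproduce
  degree correlations, transitivity or community structure of real
  friendship networks beyond what homophily and school blocking induce —
  passing recovery tests therefore demonstrate correctness of the
  estimators under the assumed model, not robustness to real-data
  misspecification.
- **Responses**: under the multilevel model (y = Xβ + ΣZ_k u_k + e, then
  standardized; generating values and pre-standardization response are
  retained so recovery tests can rescale the truth by the realized SD) or
  under either autocorrelation model. Default generating magnitudes
  (individual ≈ 0.87, network ≈ 0.15, school/area ≈ 0.03–0.05, ρ = 0.10)
  put the recovery studies in the empirically relevant regime for
  standardized attainment outcomes.

## Problem sizes used in validation

The test suite validates: clique enumeration against exhaustive subset
search (100 graphs, n ≤ 12); the Gibbs β posterior against the closed-form
conjugate posterior with fixed variances (n = 200); variance-component
recovery over 20 replicates at n = 1000 (95% credible-interval coverage
≥ 16/20 per component); pD ≈ 1 on the known-variance iid check and DIC
model ordering over 20 replicates; the autocorrelation likelihood against a
dense reimplementation (1e-10) and ρ̂ against a 1e-4 grid search; ρ
recovery (truth 0.10, n = 1000, 20 replicates, mean error < 0.03); the
variance-partition identities; and bit-identical CLI reruns. Chains of
2,500 (500 burn-in) are used for the replicated studies, as discussed
above.

## Known limitations

- Gaussian responses only; no random slopes; random effects are independent
  across classifications by construction.
- The gamma-prior convention can matter for very small variance components
  with few groups (e.g. 10 schools); posterior means of such components are
  upwardly noisy on a single data set, which is why validation is by
  coverage over replicates.
- The combined autocorrelation model's likelihood can be flat when W₁ = W₂;
  the fit is reported with its observed-information SEs, which are then
  wide.
- Weight-scheme sensitivity (`unit`, `inv_sqrt`) applies to network
  classifications only; the equal scheme's 1/n_i is the default everywhere.
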