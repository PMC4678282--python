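# Methods

## Relatedness from pedigrees

Kinship matrices are computed per family by the standard recursion over a
founder-first topological order: founders have self-kinship 1/2 and pairwise
kinship 0; a non-founder's kinship with an earlier member is the average of
its parents' values, and its self-kinship is (1 + Φ(father, mother))/2. The
fraternity coefficient of a non-inbred pair (j, k) with parent pairs
(f_j, m_j), (f_k, m_k) is Δ = Φ(f_j,f_k)Φ(m_j,m_k) + Φ(f_j,m_k)Φ(m_j,f_k),
with terms through a missing parent equal to zero. Assumptions and edge
handling:

- **Random mating.** The recursion handles inbreeding exactly for Φ, but the
  Δ formula is exact only without inbreeding; inbred parent pairs are
  detected and flagged with a warning rather than rejected.
- **Monozygotic twins** cannot be expressed by parent links, so an optional
  twin-group tag marks them; tagged members share one genotype node in the
  recursion, giving Φ = 1/2 and Δ = 1 within a group and parent-grade
  kinship between a twin's child and the co-twin. MZ twins make Φ singular;
  the cached inverse falls back to the pseudo-inverse with a warning.
- **A single missing parent** becomes a unique unrelated founder, keeping
  the recursion total.
- The full-sample relatedness is block diagonal by family and is never
  materialized densely; blocks restricted to a subject subset are the
  corresponding submatrices (the marginal of a multivariate normal).

## Variance-components maximum likelihood

The polygenic log likelihood is accumulated family by family, with families
batched by size so a likelihood evaluation is a handful of stacked Cholesky
factorizations regardless of family count. The score (gradient) in
(σ_a², σ_d², σ_e², μ_m, μ_f) is analytic and unit-tested against finite
differences; expected (Fisher) information is available, and standard errors
of ĥ² use the observed information (numerically differentiated score) with a
delta-method transformation — labelled as such since different packages
report different flavors.

The maximizer is a bounded quasi-Newton iteration (L-BFGS-B) on the natural
parameter scale with σ² ≥ 0, so boundary solutions (σ_d² = 0 is common in
nuclear-family samples) are reached exactly rather than asymptotically;
components below 10⁻⁸ are reported as zero. Convergence uses the optimizer's
relative-likelihood criterion with a 500-iteration cap; starting values are
sex-stratified means and a (½, ¼, ¼) split of the residual variance. The
test of σ_a² = 0 is the boundary likelihood-ratio test with the standard
½χ²₀ + ½χ²₁ mixture. Sex is modeled through separate means in the
likelihood by default; any other covariates are removed beforehand by
ordinary least squares (the heritability of the residual is reported). A
one-sex sample collapses to a single mean.

## The heritability-maximization program

With the derived trait scaled to unit sample variance, maximizing the
likelihood of "all covariance is additive" reduces to minimizing
Σᵢ (Xᵢᵀw − μⁱ)ᵀ Φᵢ⁻¹ (Xᵢᵀw − μⁱ) + λ‖w‖₁ subject to the variance constraint
and the two linear constraints pinning μ_m/μ_f to the sex means of the
trait. Unrelated singletons stay in every block: with scalar kinship 1/2
they contribute no covariance information but anchor the total variance and
the means.

Numerical design of the SQP solver:

- **Split variables.** w = u − v with u, v ≥ 0 turns the ℓ1 term linear; at
  an optimum the split is complementary (u_j v_j = 0), and every iterate is
  projected onto its complementary representative, which changes no
  constraint value and never increases the objective.
- **QP subproblem.** The linearized bounds are simple bounds on the step
  (p_j ≥ −γ_j), so the subproblem — 3 linearized equalities plus bounds — is
  solved by a primal-dual active-set iteration on the KKT system, which also
  yields the multiplier estimates the outer iteration needs. If the active
  set cycles, scipy's SLSQP solves the subproblem and multipliers are
  recovered by least squares on the stationarity conditions. Subproblems are
  solved in row-equilibrated, magnitude-scaled form: the variance-constraint
  gradient grows like n^{3/2} and would otherwise swamp the mean rows.
- **Curvature.** The Lagrangian Hessian 2A − 2α₁G is generally indefinite;
  its eigenvalues are clipped at 10⁻⁶ of the spectral radius. The split
  directions e_j + e_{d+j} are exact null directions of both quadratic
  forms (they leave w unchanged), so they receive artificial curvature
  (10⁻² of the spectral radius) to stop the subproblem drifting along them.
- **Retraction.** Every constraint except the variance constraint is
  homogeneous in γ, so scaling γ onto γᵀGγ = n is an exact retraction that
  preserves the mean constraints and the bounds. Line-search trial points
  are retracted before the merit test; this removes the second-order
  constraint violation that otherwise forces tiny steps along the curved
  surface, and with it the solver converges in roughly 10–20 iterations at
  every λ instead of creeping.
- **Merit and step.** ℓ1-penalty merit (objective + ρ·violation) with Armijo
  backtracking (factor 0.5, c₁ = 10⁻⁴); ρ is kept 10% above the largest
  multiplier magnitude and never decreases. Multipliers move toward the
  subproblem duals scaled by the accepted step.
- **Convergence and canonicalization.** A scaled KKT residual (stationarity,
  feasibility, complementarity, dual feasibility) below 10⁻⁶, with a
  200-iteration cap. The returned solution is rescaled so the variance
  constraint holds exactly and sign-fixed so the largest-magnitude weight is
  positive; consequently a global sign flip of the features maps to the same
  canonical solution, while flipping one non-pivot feature flips exactly its
  weight.
- **Initialization and continuation.** Start at u = 1, v = 0 with μ's the
  sex means of the w = 1 trait and α = 1, retracted onto the constraint.
  The program is nonconvex, and penalty-shaped local basins exist for λ > 0:
  a cold fit at λ > 0 therefore first solves λ = 0 and continues from its
  solution. Along a λ grid, fits warm-start from the previous λ. Within
  these rules the solver is deterministic; ties among global optima (beyond
  the sign) are resolved by whichever the iteration reaches first.
- **Features are z-scored** before optimization (training statistics only;
  validation subjects reuse them), with weights reported on both scales.
  This makes λ comparable across datasets and is switchable.

Covariate correction replaces X with M = X − Z(ZᵀZ)⁻¹ZᵀX (intercept
included): deriving a corrected trait equals correcting the design. The
fitted weights then apply to raw features of new subjects; covariate removal
at evaluation time is the estimator's job.

## Cross-validation protocol

Multi-member families and singletons are shuffled separately and dealt
round-robin into k folds (default 3), so folds balance both counts and no
family is split. For every (λ, repeat, fold): fit on the training folds,
project the held-out subjects (training standardization), estimate the
held-out trait's h² with the polygenic model (sex via separate means, any
supplied covariates residualized). The selected λ maximizes the mean
validation h², ties broken toward the smallest λ. Defaults: λ grid 0–50 in
steps of 1, 10 random splits (scaled to 3 in the packaged end-to-end runs,
which keeps the full pipeline under a minute without changing the mean
materially). A fold without related pairs has undefined h² and is excluded
with a warning; a holdout of pure singletons raises, since σ_a² is then
unidentifiable.

## The synthetic-data generator

The generator emulates a familial study sample: 6810 subjects of whom 1915
belong to small nuclear families. Family sizes are uniform on 3–6 (two
founder parents plus 1–4 children; only the headcounts and "small nuclear
families" are constrained, so the size law is a modeling choice), the last
family trimmed to hit the familial headcount, singletons filling the rest.
Sex is Bernoulli(1/2) apart from the parent pair; age is uniform on 18–65
and race a balanced binary code — arbitrary but fixed, stored in provenance.

The trait y₁ is drawn per family from N(μ, 2σ_a²Φ + σ_d²Δ + σ_e²I) with
components (0.8, 0.1, 0.1) and sex means (0.9, 0.3), so the implied h² is
exactly 0.8; an eigendecomposition square root handles the PSD boundary
(MZ twins with σ_e² = 0). Features implant a weight vector drawn once per
scenario with magnitudes uniform on [0.5, 1.5] and random signs — bounded
away from zero, as the construction divides by a weight: per subject, one
relevant feature (chosen uniformly, per subject) balances the others so that
**x**ᵀ**w** reproduces the trait exactly; irrelevant features are pure
standard normal with weight zero. y₂ = y₁ + 1.1·age + 0.7·race adds fixed
covariate effects (and the covariate experiment implants the weights into
y₂); a sensitivity mode removes 1–5 relevant columns.

What the generator does **not** emulate: real family-size and household
structure, ascertainment, feature distributions of real instruments
(bounded ordinal scores, floor effects), missingness, and any linkage
between features and measured genotypes. Passing tests therefore show that
the estimator and solver recover what the variance-components model
generates, not that real low-level traits satisfy that model.

## Observed behavior worth knowing

- At the study scale the solver recovers the implanted direction with
  squared weight error around 0.003–0.005 (after normalizing both vectors to
  a unit-variance trait), and the cross-validated heritability of the
  derived component sits within a few points of the implanted 0.8 with and
  without covariate correction.
- Because recovery is this tight, the irrelevant-feature weights are already
  tiny at λ = 0 and cross-validation tends to select λ near 0: the ℓ1
  threshold acts on gradient magnitudes, which scale like √n, so on the 0–50
  grid at n ≈ 6810 few weights reach exact zero. Exact zeros do appear and
  grow with λ (the shrinkage mechanism is tested), but by the time most
  irrelevant weights are zeroed, relevant ones are being dropped too —
  feature *selection* by this penalty is weak at this sample size even
  though feature *recovery* is strong.
- ĥ² from a single replicate at n ≈ 6810 has a standard error near 0.03;
  single-replicate comparisons against the implanted value should use bands
  of at least ±0.05–0.06.

## Known limitations

- Identity coefficients for inbred pedigrees (all nine condensed
  coefficients) and X-linked kinship are out of scope; Δ is approximate
  under inbreeding (warned).
- No household/shared-environment variance component, no epistasis, no
  gene–environment interaction; Γ defaults to the identity.
- The program is nonconvex; continuation and warm starts find the
  heritability-maximizing basin in all tested conditions, but global
  optimality is only verified exhaustively at d = 2.
- Scaling is comfortable at ~10⁴ subjects with small families; million-scale
  samples or very large families (dense per-family matrices) are untested.
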