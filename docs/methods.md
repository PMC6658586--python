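# Methods

## Model

For person *i* in group *g*, the vector of log response times over the *p*
items is multivariate normal,

    T_ig ~ N(μ_Tg, Σ_g),      μ_Tg = λ_g − μ_ζg·1,

where λ_gk are item time intensities (log-seconds) and μ_ζg is the group's
mean speed.  Random person effects are marginalized, leaving an additive
covariance structure

    Σ_g = diag(σ²_g) + δ_g·11ᵀ + Σ_{d=1..D} Δ_gd·u_gd u_gdᵀ.

The base layer (all-ones vector, parameter δ_g) is heterogeneous compound
symmetry: the dependence implied by a common latent speed.  Each further
layer carries the dependence of one random-effect structure — a testlet, a
presentation format, a time-pressure block — through a 0/1 membership vector
u_gd and a covariance parameter Δ_gd.  Real-valued (loading) vectors are
supported in construction and validation, mirroring item-specific time
discriminations, but have no sampling step: no closed-form conditional
exists for loadings in this framework, so fitting treats them as fixed.

Layers are applied in declared order.  Layer *d* keeps Σ positive definite
iff its parameter exceeds −1/(uᵀ A_d⁻¹ u), where A_d stacks the layers below
it (Sherman–Morrison).  These bounds — not eigenvalue checks — are the
operative PD test everywhere: the same recursion yields the inverse and
log-determinant in O(p²) per layer, and a violated layer is reported by
name.  Because the Gibbs sweep draws δ and then the Δ's in declared order,
each above its bound given the parameters already updated, the state after
every sweep is positive definite by construction.

Identification: the design-vector set per group must be mutually distinct
(including the implicit all-ones layer).  The mean structure is identified
by rescaling stored samples — equal mean item intensity across groups and
μ_ζ1 = 0 (alternatively μ_ζg = 0 in all groups, as in counterbalanced
designs where the layers differ by group) — leaving every fitted μ_Tg
invariant.

## Conjugate family

All (co)variance parameters use the four-parameter truncated shifted
inverse-gamma TSIG(α, β, υ, τ): an inverse-gamma kernel in x + υ restricted
to x > max(τ, −υ).  τ = −υ gives the untruncated shifted law; τ = υ = 0 the
plain inverse-gamma.  Numerics run through the regularized incomplete gamma
of β/(x+υ): the CDF, quantile and sampler work on the survival scale, so
inverse-CDF sampling is exact and rejection-free under arbitrarily heavy
truncation (down to truncated masses near 1e-280; a fully collapsed interval
raises a degenerate-truncation error naming the offending parameters, since
it signals a near-degenerate conditional).  The truncated mean has the
closed form β/(α−1)·P(IG(α−1, β) > edge)/P(IG(α, β) > edge) − υ; a lower
truncation never tempers the upper tail, so moments of order m exist exactly
when α > m.

Hyperparameters (α0, β0) are shared by all (co)variance priors.
`vague_prior(shape, scale)` maps the common "shape/scale" phrasing for vague
inverse-gamma priors to (α0 = shape, β0 = 1/scale), i.e. shape 1e-8 with
scale 1e8 is the near scale-invariant IG(1e-8, 1e-8).  Defaults follow the
study settings: 1e-8/1e8 for the recovery study, 1e-3/1e3 for evidence
computation, both configurable.

## Gibbs sampler

Sufficient statistics per group: SSB (between-person sum of squares of
person means) for δ; SSW_k per item for σ²_gk; SSW (total) for the
auxiliary mean variance σ̄²_g; SSB_d (between sum of squares of per-person
means over layer d's items, centered at the layer grand mean) for Δ_gd.
Each conditional posterior is TSIG with shape α0 + n_g/2 and scale
β0 + SS/2 (β0 + SSW/(2p) for σ̄²).

**Shifts are computed recursively.**  The shift of a parameter's conditional
equals the total contribution of all *other* (co)variance parameters to the
variance of its sufficient statistic:

* σ²_gk:        δ_g + Σ_{d∋k} Δ_gd, truncation 0;
* σ̄²_g:        δ_g + Σ_d Δ_gd·p_d/p, truncation 0;
* δ_g:          σ̄²_g/p + Σ_d Δ_gd·(p_d/p)², truncation −1/Σ_k σ⁻²_gk
                (σ̄²_g is the auxiliary draw);
* Δ_gd:         (mean σ² over the layer's items)/p_d + δ_g +
                Σ_{d'≠d} Δ_gd'·(u_d'ᵀu_d)²/p_d², truncation = the PD bound
                given the layers below d.

For a single extra layer this reduces to the familiar pairs (δ ← σ̄²/p,
σ² ← δ, Δ ← σ̄²_layer/p_d + δ); with several layers the overlap terms are
required for the equilibrium to center each parameter on its generating
value — dropping them biases the testlet covariances downward by roughly
Σ_d Δ_d p_d²/p².  The shift sums over *all* other layers, not only the ones
declared below: for disjoint testlets the two conventions coincide, and for
overlapping (cross-testlet) layers only the symmetric version accounts for
the full variance of the layer mean.  The conditional *prior* of each
parameter is TSIG(α0, β0) with the same shift and truncation, which is what
makes the family conjugate: prior kernel × sufficient-statistic likelihood
kernel equals the claimed posterior kernel identically (the "conjugacy
audit" in the test suite checks this pointwise on a grid).

Update order per iteration: fixed effects (μ_Tg ~ N(item means, Σ_g/n_g)
under a locally uniform prior) → σ²_g → σ̄²_g → δ_g → Δ layers in declared
order → missing-data imputation.  Cross-group equality constraints (a tied
σ²_k, tied layer parameters) are updated once per iteration from pooled
statistics: shape α0 + Σn_g/2, scale β0 + ΣSS_g/2, shift the n_g-weighted
mean of per-group shifts, truncation the tightest per-group bound.  This is
exact when the per-group shifts coincide (symmetric designs) and a
documented approximation otherwise — the exact tied conditional is a product
of shifted inverse-gamma kernels with different shifts, which leaves the
TSIG family.

Initialization is method-of-moments (σ² from item variances, δ from the
mean off-diagonal covariance clamped above its bound, Δ at 0, μ_T at item
means) and lies in the PD region by construction.  Burn-in defaults to 10%;
intervals are equal-tailed; chains are bit-identical given a seed.

Missing-at-random cells are redrawn each iteration from the conditional
normal given the person's observed coordinates (Schur complement; a fully
missing person draws from the unconditional group law), and the sufficient
statistics are recomputed from the completed data.

## Evidence

The log marginal likelihood is estimated by importance sampling with the
product of marginal posteriors as the importance density: block-wise
independent permutations of the retained chains supply the draws, and both
the marginal posteriors (denominator) and the marginal priors of the
covariance parameters (numerator) are Rao-Blackwellized — averages of the
closed-form TSIG/normal full conditionals over retained draws.  Blocks: one
fixed-effects vector per group (flat prior; its constant cancels in Bayes
factors between models sharing the mean structure), one σ² vector per
group, and each covariance parameter separately.  The likelihood term uses
observed data only, marginalizing each person's normal law to observed
coordinates; missing-data draws never enter the evidence.  Unknown prior
normalizing constants shift both competing marginal likelihoods equally and
cancel in the log Bayes factor.

A point-null restriction (Δ_d = 0) is represented by a model without that
layer, refit with its own chains; the restricted parameter is absent from
both the numerator density and the importance density.  The number of
importance draws J defaults to the retained chain length; the study
harnesses use J = 500 permuted draws against 500 thinned conditioning draws,
a problem size at which a replication evaluates in a few seconds with
run-to-run spread well inside the between-replication spread of the log BF.
The BIC uses the observed-data likelihood at the posterior means,
d = fixed effects + free covariance-matrix parameters (ties counted once),
and N* = pN.

## Synthetic data

`simulate_dataset` draws each person's vector from the marginal multivariate
normal with mean λ_g − μ_ζg − μ_θg(k) and the additive covariance above —
so negative covariance parameters are allowed anywhere inside the PD region.
A conditional mode draws explicit speed and person–testlet effects for
cross-checks and requires non-negative (co)variances; both modes agree in
their first two moments.  MCAR deletion (a special case of MAR, independent
of all values) is applied after generation; the pre-deletion matrix is kept
in the truth record so missingness can be audited.

The two replication harnesses encode the calibration studies:

* **Recovery/coverage** (`study1_replication`): one group, N = 300, p = 30,
  three testlets of 10; truth δ = .2, Δ = (0, .01, .05), σ² = 1,
  λ ~ N(0,1), prior shape 1e-8 / scale 1e8.  Defaults run 200 replications
  of 2,000 iterations — a desk-scale problem size whose Monte-Carlo and
  binomial standard errors are reported in the output table; the original
  1000 × 10,000 design is available through the arguments.
* **Bayes-factor power** (`study2_replication`): three equal groups,
  p = 18, three testlets of 6, Δ1 swept over {−.2, 0, .2, .4, .6, .8, 1}
  with Δ2 = Δ3 = 0, group sizes 100 and 150, 3,000 iterations, prior shape
  1e-3 / scale 1e3, layer parameters tied across groups.  δ, σ², λ reuse
  the recovery-study values (the power design leaves them unstated).

What passing tests on these data do and do not show: the generator is the
model — real response-time data bring lognormality violations, speededness,
non-random missingness, and item-position effects that no test here
exercises.  Within the model family the tests establish distributional
correctness of every conditional, exact linear algebra, calibrated recovery
of covariance parameters near zero, and the expected ordering and sign
behavior of the Bayes factor.

## Numerical choices and known limitations

* All TSIG computation is in log space; densities outside the support are
  −∞, and CDF/quantile round-trips hold to 1e-8 absolute.
* The person-mean likelihood keeps its (2pπ)^(−n/2) normalization
  convention; it differs from the product of person-mean normal densities by
  the constant −(n/2)·log p, which cancels everywhere it is used.
* Sums of squares are centered at data means with shape n_g/2 (not a
  degrees-of-freedom-corrected n_g − 1), matching the sufficient-statistic
  conditionals; the resulting O(1/n) effects are far below the posterior
  spread at the study sizes.
* The sufficient-statistic conditionals form a *working* posterior: each
  parameter sees only its own statistic, so the joint law is overdispersed
  relative to the full-likelihood posterior.  Posterior means remain
  unbiased (the recovery harness confirms this to three decimals), but the
  equal-tailed intervals for testlet covariances are conservative —
  empirical coverage of the nominal 95% intervals runs near 100% in the
  recovery design rather than 95%.  Tests of local dependence therefore err
  on the side of caution.
* With moderate MCAR missingness (15%), data augmentation on the working
  conditionals shows a small negative bias (~0.02–0.03) on small-testlet
  covariance parameters; observed-data evidence computation is unaffected.
* In the evidence estimator, a permuted covariance value can fall below the
  truncation point of every conditioning draw, making both the RB prior and
  RB posterior densities zero (they share truncations).  Such rows lie
  outside the estimated importance-density support and receive zero weight;
  if more than 5% of rows are affected the estimate errors out instead.
* Degenerate inputs: constant data collapse the variance chains toward
  prior-scale values without crashing (a tiny diagonal jitter guards the
  Cholesky); empty groups, duplicate design vectors, non-positive raw times
  and PD violations raise informative errors.
* Not implemented: sampling of loading layers, adaptive MCMC, multi-chain
  convergence diagnostics, prior odds elicitation, order-restricted
  hypotheses, and joint response–accuracy modeling.
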