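# Methods

## Model and scope

All analyses assume the normal-approximation random-effects model for
study-level summary effects on the log odds ratio scale,

y_i | x_i ~ N(x_i β, σ_i² + τ²),

with within-study variances σ_i² treated as fixed and known. A plain
meta-analysis is the special case x_i ≡ 1 with scalar coefficient μ.
Binomial exact likelihoods, effect measures other than the log odds ratio,
and multivariate/between-contrast heterogeneity structures are out of scope.

## Pseudo-data representation of an inverse-gamma prior

An IG(α, β) prior on τ² equals a Gamma(α, rate β) prior on the precision
ϕ = 1/τ². Written in the log precision φ = log ϕ = −2 log τ (the scale on
which a flat prior is appropriate, and the scale on which the change of
variable contributes the Jacobian e^φ), the prior density is
∝ exp(αφ − β e^φ). A block of K₀ artificial studies with common effect y₀,
mean zero and within-study variance ≈ 0 contributes the likelihood
∝ exp((K₀/2)φ − (K₀y₀²/2)e^φ). Matching exponents gives K₀ = 2α and
y₀ = √(2β/K₀).

Numerical choices:

- **K₀ rounding.** K₀ must be an integer: K₀ = round(2α), half-up ties,
  minimum 1. y₀ is recomputed from the *rounded* K₀, which preserves the
  prior scale β = K₀y₀²/2 exactly and perturbs only the shape. The prior
  actually encoded — IG(K₀/2, β), the *achieved prior* — is always reported
  next to the declared one, since the two differ whenever 2α is not an
  integer.
- **Pseudo variance.** σ₀² = 10⁻²⁰, small enough that the identity between
  the pseudo-block likelihood and the prior density holds to ~10⁻¹⁶ over any
  practically relevant (μ, τ²) range, large enough to keep all weights
  finite in double precision. It is configurable for robustness
  experiments. `augmented_loglik_identity_check` verifies the identity
  directly (constant difference over a (μ, τ²) grid) and is exposed because
  it is the package's central correctness claim.
- **Zero bias.** Pseudo effects are centred at zero and carry an all-zero
  covariate row, so at fixed τ² the weighted coefficient estimate is
  unchanged by augmentation (asserted to 10⁻¹⁰ in the tests). Augmentation
  moves μ̂ only through its effect on τ̂².

## Prior registry

Nine empirically derived predictive IG distributions for τ² in
binary-outcome meta-analyses (outcome type × comparison type) plus a generic
IG(1.14, 0.08) are stored as printed constants — no re-derivation from the
underlying hierarchical model is attempted, and the log-normal / log-t₅
families from related prior work are excluded because they have no
pseudo-data representation. Quantiles are computed through the gamma
inverse-CDF of the reciprocal (Q(p) = β / Q_Gamma(1−p; α)), which is robust
for the small shapes involved; the upper tail uses the complementary gamma
CDF to stay float-accurate where the distribution function saturates.

A caveat documented here deliberately: the exact quantiles of the fitted
IG distributions can differ by a few percent from the central summaries
quoted alongside them in the source material for the generic setting (the
fitted IG(1.14, 0.08) has median 0.0965 and upper 95% limit 1.88). The
package always reports the exact quantiles of the stored distribution.

## Frequentist estimation

- **DL**: fixed-effect WLS (weights 1/σ_i²) gives the residual Q; the
  moments estimator is τ̂² = max(0, (Q − (n−p)) / C) with
  C = tr(W) − tr[(XᵀWX)⁻¹XᵀW²X], followed by WLS at weights 1/(σ_i²+τ̂²).
- **ML / REML**: β is profiled out by WLS; the scalar (restricted) profile
  likelihood is maximized on the log(τ²+ε) scale (ε = 10⁻¹⁰) over
  [0, 10 × max marginal variance], with an 80-point grid presearch before
  bounded Brent refinement (tolerance 10⁻¹² on the log scale) — bounded,
  scale-free and reproducible. Estimates below ε are reported as exact
  zeros and flagged `truncated`. Agreement with an independent
  implementation (metafor's `rma.uni`) is ~10⁻⁵, limited by the two
  optimizers' convergence tolerances.
- **τ² intervals**: Q-profile — the generalized Q(τ²) = Σ(y_i −
  x_iβ̂(τ²))²/(σ_i²+τ²) is strictly decreasing, so each limit is a single
  bracketed root against the χ²_{n−p} quantiles (Brent, relative tolerance
  10⁻¹⁰, geometric bracket growth), truncated at 0. On augmented data the
  pseudo rows are included in n − p; this reproduces the observation that
  augmented DL/ML/REML fits share one τ² interval, since the Q function
  does not depend on the point estimator. The point estimate and the
  interval are computed independently and may disagree in ordering (a DL
  τ̂² can fall below the interval's lower limit); this is reported as-is.
- **μ intervals**: Wald with the standard normal quantile, never t;
  Knapp–Hartung is out of scope.

## Fully Bayesian comparators

The posterior under an IG prior on τ² and independent N(0, v₀) priors on
the coefficients (v₀ = 10⁶) is computed without MCMC. Conditional on τ²,
the coefficients integrate out analytically:
y | τ² ~ N(0, V + v₀ XXᵀ), V = diag(σ_i²+τ²), evaluated through the
Woodbury/determinant identities so only p×p systems are solved (closed form
for p = 1, vectorized over τ²).

- **Grid engine** (deterministic): log-spaced τ² grid over the prior's
  [10⁻⁶, 1−10⁻⁶] quantile range, 400 points by default; trapezoid
  normalization; τ² quantiles by CDF interpolation; the μ marginal is the
  grid mixture of conditional normals with quantiles by bracketed
  root-finding on the mixture CDF. If ≥ 1% of posterior mass lands in an
  edge cell the call errors and advises a wider grid rather than silently
  truncating.
- **Importance sampling**: proposal = the τ² prior itself; weights = the
  marginal likelihood; μ drawn from its conditional normal per sample;
  summaries are weighted quantiles via linear interpolation of the
  midpoint weighted empirical CDF (the step-function inverse is noticeably
  tail-biased at modest effective sample sizes). ESS = (Σw)²/Σw² is
  reported, with a recorded warning below 50. Heavier-tailed proposals are
  a possible extension; the prior proposal is adequate because the
  one-dimensional weight function is bounded.

The two engines target the identical posterior, so their agreement (tested
within Monte Carlo error on random small datasets) is a genuine
cross-validation, not a tautology. The grid posterior mode in φ also
cross-checks the augmented ML optimum for integer-2α priors.

## Network meta-analysis

Two-arm contrasts enter an intercept-free meta-regression with one column
per non-reference intervention: +1 for the contrast's non-reference arm, −1
for its within-study reference arm when that arm is not the global
reference. A single common τ² is assumed for all contrasts. Multi-arm
studies are split into independent two-arm contrasts against the study's
declared reference arm, with a logged warning that the shared-arm
correlation is ignored — a deliberate simplification. Consistency is
assumed; derived contrasts are linear combinations of basic parameters with
delta-method variances, so the closure identity (jk + kl − jl = 0) holds
exactly and re-referencing the network changes nothing observable. The
study-level reference arm must be declared in the input; it is not inferred
from arm ordering.

## Simulation harness

The generator draws θ_i ~ N(μ, τ²), y_i ~ N(θ_i, σ_i²). Defaults define the
study conditions: K ∈ {5, 10, 20} with K = 5 the headline case; τ² on the
grid {0, 0.029, 0.069, 0.206, 1.302}, which corresponds to I² = 0–95% at a
typical within-study variance of 0.069; σ_i² fixed at 0.069. The constant
0.069 is obtained by inverting I² = τ²/(τ²+σ²) on that (τ², I²) grid — every
pair is consistent with σ² ≈ 0.069 — because the original generating design
for the within-study variances is not published; a sampled alternative
(σ_i² ~ 0.069·χ²₄/4) is available behind configuration for sensitivity
analysis. Consequently the harness's quantitative outputs are validated as
*properties* (directions and orderings: DL's upward bias at τ² = 0,
above-nominal coverage at τ² = 0, Bayesian shrinkage at high τ², augmented
REML tracking the fully Bayesian mean more closely than augmented ML), not
as reproductions of any published table.

Reproducibility: one scenario seed; per-replicate substreams via
`SeedSequence([seed, rep])` so every method sees identical data; the
importance-sampling engine gets a per-replicate derived seed. Reference
replicate counts are 20 000 for frequentist-only metrics and 1000 for
scenarios including Bayesian engines; the shipped tests and examples run
300–2000 replicates, a size at which all the asserted orderings are stable
with wide margin while the whole suite completes in about a minute.

For coverage and interval length, *all* methods — including the Bayesian
engines — are summarized by point estimate plus model-based standard error
with the normal quantile: for the Bayesian methods the posterior median of
μ and the inverse-variance standard error evaluated at the posterior-median
τ². Credible intervals would be wider; the z-interval convention isolates
how each method's τ² estimate propagates into inference on μ and makes the
methods directly comparable.

## Known limitations

- Approximate Bayes only on the augmentation path: no posterior
  percentiles, and Q-profile intervals on augmented data are not posterior
  credible intervals (they are typically wider).
- Inverse-gamma priors only; log-normal/log-t priors cannot be represented
  as pseudo data.
- Normal within-study approximation throughout; small studies and rare
  events will inherit its bias.
- Multi-arm correlation ignored in the network module by construction.
- The synthetic generator draws exchangeable studies with identical (or
  exchangeable sampled) within-study variances; real meta-analyses have
  correlated study sizes, asymmetric variance distributions and possible
  small-study effects, none of which the passing property tests speak to.
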