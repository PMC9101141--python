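# Methods

## Model

For areal units i = 1..n on a connected adjacency graph and outcome types
k = 1..K,

    y_ik ~ Poisson(θ_ik · E_ik),        E_ik = r_k · p_i,
    log θ_ik = α_k + β_ik · NDI_i,      NDI_i = Σ_j w_j q_ij,

with q_ij ∈ {1,…,10} the decile scores of C sociodemographic variables after
orientation (advantage measures such as per capita income are folded by
max(x) − x so that larger always means more disadvantaged). The expected
count uses the outcome's overall per-capita rate r_k = Σ_i y_ik / Σ_i p_i, so
Σ_i E_ik = Σ_i y_ik exactly and θ_ik is the relative risk against
proportional allocation.

Priors: α_k improper flat; w ~ Dirichlet(a) on the open simplex (default
a = 1, i.e. uniform — each variable gets prior mean weight 1/C); the n × K
coefficient field β has the intrinsic multivariate CAR kernel

    p(β | Ω) ∝ |Ω|^{(n−1)/2} exp(−½ Σ_{i~j} (β_i − β_j)ᵀ Ω (β_i − β_j)),

where i~j ranges over unordered neighbor pairs and the exponent (n−1)
reflects the kernel's rank on a connected graph; and Ω ~ Wishart(R, ν) in the
**rate convention** f(Ω) ∝ |Ω|^{(ν−K−1)/2} exp(−½ tr(RΩ)) with prior mean
ν·R⁻¹ (defaults R = 0.2·I, ν = K; this is the BUGS-family convention — note
scipy parameterizes by R⁻¹). Σ = Ω⁻¹ is the between-outcome covariance of
the coefficient fields; its correlations are the *conditional correlations*
between outcome types reported by `diagnostics.conditional_correlations`.

### Identifiability and the centered+slope mode

The intrinsic kernel is flat along per-column constants, so the mean level of
each β column is identified only through the likelihood (NDI varies across
units). The default `mode="centered"` treats β_ik = b_k + δ_ik with flat
priors on the mean slopes b_k and a sum-to-zero field δ; operationally the
sampler keeps the combined β and adds dedicated level moves (below), and the
stored β is always the sum, so exp(β_ik) is directly the unit-level relative
risk per index unit. `mode="unconstrained"` drops the extra level moves for
sensitivity analysis; both modes target the same posterior.

Two softly identified ridges deserve note because they shape both the sampler
and what data can ever determine:

1. **(w, β) rescaling.** The likelihood is *exactly invariant* under
   w → w′, β_ik → β_ik · NDI_i / NDI′_i. Index weights are therefore
   identified only because the rescaled field is spatially rougher and the
   CAR prior penalizes it. Consequently the weight posterior concentrates
   with data volume only up to a lattice-dependent limit (see the
   count-scaling test), and weight information grows with the number of
   units and edges more than with counts per unit.
2. **(α, β) compensation.** β_ik → β_ik + ε/NDI_i with α_k → α_k − ε also
   leaves the likelihood unchanged and is pinned only by the kernel. On
   large lattices the pin is strong; on tiny instances it is the dominant
   posterior direction.

## Sampler

Metropolis-within-Gibbs, per iteration and chain:

- **β field** — scalar random-walk Metropolis per (unit, outcome) entry with
  an individually adapted step size, accepted on the Poisson log-likelihood
  change plus the local CAR kernel change. Units are processed by color
  class of a greedy proper coloring of the adjacency (within a class no two
  units are neighbors, so a whole class updates in one vectorized step).
  Per-entry step sizes matter: units whose counts run into the thousands
  coexist with prior-dominated units, and any shared scale mixes one of them
  badly.
- **column-shift move** (centered mode) — proposes β_·k += ε with
  α_k −= ε·c_k, where c_k = Σ_i y_ik NDI_i / Σ_i y_ik is the count-weighted
  index mean, the local slope of the (b_k, α_k) likelihood ridge. Kernel and
  flat priors are invariant; the likelihood decides.
- **η-shift move** (centered mode) — proposes β_·k += ε/NDI with α_k −= ε,
  traveling ridge (2) exactly; the likelihood cancels and only the kernel
  votes.
- **α** — exact Gibbs: with flat prior, t_k = exp(α_k) has full conditional
  Gamma(Σ_i y_ik, Σ_i E_ik exp(β_ik NDI_i)).
- **Ω** — conjugate Gibbs: Ω | β ~ Wishart(rate R + S, df ν + n − 1) with
  S = Σ_{i~j} (β_i − β_j)(β_i − β_j)ᵀ = βᵀLβ (L the graph Laplacian), drawn
  by Bartlett decomposition.
- **w** — componentwise random-walk Metropolis on the additive-log-ratio
  coordinates z_j = log(w_j/w_C); the target combines the Poisson likelihood
  (through NDI), the Dirichlet prior, and the ALR Jacobian Σ_j log w_j.
  Proposals leaving the open simplex (any w_j ≤ 1e−12) are rejected.
- **rescale move** — componentwise z proposals paired with the deterministic
  field map β′ = β · NDI/NDI′ of ridge (1). The likelihood cancels exactly;
  acceptance uses the Dirichlet/Jacobian terms, the kernel change of the
  rescaled field, and the map's own Jacobian Π_i (NDI_i/NDI′_i)^K. Without
  this move the weight chains crawl (R̂ of 5–10 at desk scale); with it the
  reference protocol reaches max R̂ ≈ 1.01–1.1.

All proposal scales adapt by Robbins–Monro (step (t+1)^−0.6) toward 0.44
acceptance during burn-in only and are frozen afterwards, so retained draws
come from a fixed kernel. Chain c of a run seeded σ uses
`numpy.random.default_rng([σ, c])`; everything downstream is bit-reproducible.
Initialization is deterministic and moment-matched: α_k = log(Σy_k/ΣE_k),
β = 0, w = 1/C, Ω = ν·R⁻¹.

Default protocol: two chains, 50,000 burn-in, 10,000 retained, thin 1 — the
standard protocol for this model family. `MCMCConfig.test_scale()` (5,000 +
5,000) is the desk protocol used by the test suite and the analysis scripts;
at n = 400, K = 3 it runs in under a minute per experiment on one CPU.

Derived quantities (NDI per draw, relative risks θ, Σ = Ω⁻¹) are recomputed
on demand from the stored draws, so they match the draws exactly by
construction.

## Diagnostics and summaries

- **Gelman–Rubin**: classical two-chain formula, W = mean within-chain
  variance, B = T·var(chain means), R̂ = √(((T−1)/T·W + B/T)/W); convergence
  threshold 1.2. Monitored scalars: all α_k, w_j, upper-triangle Ω entries,
  and a seeded random subsample of 100 β entries (monitoring all n·K would
  be wasteful).
- **Effects**: pooled-chain equal-tailed quantiles of exp(β_ik); a unit is
  *significantly elevated* when the 2.5% quantile exceeds 1. Equal-tailed
  (not HPD) intervals throughout, empirical quantiles with linear
  interpolation.
- **Conditional correlations**: each Ω draw inverted and converted to
  correlations; medians and 95% CrIs per outcome pair.
- **Weights/NDI**: componentwise medians and CrIs (medians reported raw, not
  renormalized); per-unit posterior median NDI.
- **Welch tests**: for each outcome, units split by the significance flag;
  the posterior-median NDI and each decile column are compared across groups
  with Welch's t (Welch–Satterthwaite df, raw two-sided p, no multiplicity
  correction). Groups smaller than two units are skipped with a notice.

## Synthetic-data generator

The generator produces data with exactly the structure the model assumes, so
every downstream stage is testable against a recorded truth:

- **Lattice**: regular grid, rook contiguity by default (queen optional);
  row-major unit order; connected by construction.
- **Covariates**: exponentiated equicorrelated Gaussians (lognormal
  marginals — nonnegative and right-skewed like percentage and
  segregation-ratio variables), equicorrelation 0.5 by default to mimic the
  substantial collinearity of deprivation indicators. The last column is
  flagged inverse-oriented and plays the role of per capita income. Only
  ranks survive decile scoring, so the marginal family is otherwise
  immaterial. Columns are iid over units (no spatial autocorrelation): the
  model consumes deciles, and spatial structure in covariates is not needed
  for any property under test.
- **Index**: decile scores are computed by the same code path the model
  uses, and the emitted truth satisfies NDI_i = Σ_j w_j q_ij for the emitted
  design exactly. Default truth weights (0.26, 0.18, 0.16, 0.14, 0.12, 0.04,
  0.04, 0.03, 0.03) — a realistic, strongly non-uniform importance profile
  for nine deprivation components.
- **Coefficient field**: β = b + δ with mean slope b = 0.15 per outcome and
  δ drawn from the constrained (sum-to-zero) intrinsic MVCAR — the intrinsic
  density is improper, and the constrained draw matches the identifiability
  convention of the model's centered mode. Sampling is spectral: with
  Laplacian eigenpairs (λ_m > 0, u_m), coordinates are N(0, Ω⁻¹/λ_m), giving
  field covariance L⁺ ⊗ Ω⁻¹. The default Ω is the inverse of
  Σ = 0.3² · corr with corr(1,2) = 0.9 and zeros elsewhere; on the default
  20 × 20 lattice this yields a marginal field spread of ≈ 0.27, i.e.
  unit-level relative risks exp(β) ranging up to about 2 around the mean
  slope — the operating point where spatially varying index effects are
  scientifically interesting (elevated RRs of roughly 1.8–2 in the strongest
  units). The 0.9/0.0 correlation pattern makes correlation recovery and
  ordering directly checkable.
- **Counts**: Poisson with mean exp(α_k + β_ik NDI_i)·r_k·p_i; populations
  uniform on [500, 3000]; default base rates r_k = 0.0015 give on the order
  of 10–20 events per unit. Means above 1e12 are rejected with a pointer to
  smaller effect sizes.

What the generator does **not** emulate: real geography (no shapefiles),
spatially autocorrelated covariates, overdispersion or zero inflation beyond
Poisson, and measurement error in the covariates. Passing tests therefore
demonstrate correctness of the machinery and calibration under the model's
own assumptions, not robustness to their violation.

## Numerical choices

- Decile cutpoints: empirical quantiles at 0.1,…,0.9 with the
  median-unbiased definition; a unit gets the smallest decile d with
  x_i ≤ cutpoint_d; ties share the lowest admissible decile; a constant
  column collapses to decile 1 with a warning. Decile codes are 1–10 (the
  intercept absorbs any shift). Cutpoints are computed on the analysis set,
  i.e. after unit exclusions.
- Units with zero population or missing values are dropped at load time with
  the count logged; the graph must remain connected afterwards (disconnected
  input is rejected rather than handled, and the kernel exponent assumes a
  single component).
- Orientation is declared per variable in configuration; no automatic sign
  detection, to keep preprocessing deterministic.
- Poisson means are computed with the linear predictor clipped at 700 before
  exponentiation inside Metropolis ratios (pure overflow guard; proposals
  that far out are rejected anyway).
- Wishart draws use the Bartlett construction and are symmetrized against
  roundoff; every stored Ω draw passes a Cholesky check.

## Known limitations

- Weight identification is prior-mediated in the large-count limit (ridge
  (1) above): on small lattices the weight posterior stays wide no matter
  how large the counts, and near-tied truth weights cannot be ranked
  reliably at desk scale. The reference recovery experiment (400 units,
  ~10–20 events/unit, 5k+5k draws) recovers coverage (typically 7–9 of 9
  CrIs) and the correlation structure, but the posterior medians of
  individual weights scatter by ±0.04–0.05 across dataset replicates, so an
  exact top-3 ranking of a profile whose ranks 3 and 4 differ by 0.02
  succeeds only on favorable draws. Resolving that gap reliably needs an
  analysis set roughly an order of magnitude larger.
- Conditional-correlation posteriors show mild attenuation toward zero at
  desk scale (prior shrinkage from Wishart(0.2·I, K) plus finite
  information); medians for a 0.9 truth land around 0.85–0.90.
- Single-component graphs only; no negative binomial or zero-inflated
  variants; no covariate effects outside the index; no cartographic output
  (results tables are joinable to user geometry by unit id).
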