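# Methods

`smrmap` implements a Bayesian spatio-temporal disease-mapping analysis for
small-area count data: indirect age standardization, hierarchical Poisson /
negative-binomial regression with conditional-autoregressive (CAR) spatial
random effects fitted by MCMC, model comparison by the deviance information
criterion (DIC), and smoothed standardized-mortality-ratio (SMR) summaries
for mapping. A synthetic-data generator with known ground truth makes every
stage testable without access to confidential registry data.

## Observation model

Counts are analysed per coarse age group (<55, 55–74, 75+), each group
fitted separately. For unit *i* and period *t*,

    y_it ~ Poisson(E_it · r_it)     or     y_it ~ NB(mean E_it · r_it, κ)
    log r_it = α + β_t + β_l(i) + β_u(i) + φ_i (+ θ_i)

* `E_it` — expected deaths from indirect standardization (below).
* `β_t` — period factor; the first period is the reference (β = 0), so
  `exp(β_t)` is the SMR ratio of period *t* relative to the first period.
* `β_l`, `β_u` — language-region (German reference) and urbanisation
  (rural reference) factors, fixed in time.
* `φ` — spatially structured random effect, intrinsic CAR (ICAR) prior:
  conditionally `φ_i | φ_-i ~ N(mean of neighbours, σ_φ²/n_i)` with `n_i`
  the neighbour count. The ICAR is improper; identifiability comes from a
  sum-to-zero constraint per graph component, with the intercept absorbing
  the level. Degree-0 units (islands) have φ fixed at 0 — there is no
  neighbour information to smooth with.
* `θ` — optional exchangeable N(0, σ_θ²) effect; φ + θ is the
  Besag–York–Mollié convolution.
* Negative binomial: mean μ, variance μ(1 + μ/κ), so κ → ∞ recovers the
  Poisson. This parameterization is used because its Poisson limit is clean
  enough to test numerically (κ = 1e8 agrees with Poisson to < 1e-6 per
  cell).

The four candidate models of the DIC comparison are the crossing
{Poisson, NB} × {spatial RE, spatial + unstructured RE}; a non-spatial GLM
(`random_effects="none"`) is available for preliminary analysis.

## Indirect standardization

Reference rates are computed per 5-year age band, pooled over **all** units
and periods: `rate_b = Σ deaths_b / Σ person-years_b` (bands with zero
person-years get rate 0 so expected counts stay defined). Expected counts
are `E(unit, period, group) = Σ_{b in group} PY · rate_b`. When the rates
come from the analysed data itself, `Σ E = Σ y` exactly (closure); this
anchors the overall SMR level at 1 and makes period SMR ratios readable as
temporal trends against the all-period average.

Cause-of-death coding corrections are multiplicative factors per (age band
or group, period or era) supplied by the user — the factor values are
study-specific and not shipped. Corrected counts are rounded half-to-even
per cell so the count likelihood sees integers (the source material does
not say whether corrected counts were rounded; an unrounded pipeline is
available behind `round_counts=False` for sensitivity analysis). A
pre-round at 1e-9 removes binary-float fuzz so e.g. 10 × 0.85 rounds as
8.5 → 8, not 8.500000000000001 → 9.

Annual tables are aggregated into multi-year windows (default: five 4-year
windows around census years, 1969–1972 … 2008–2011); years outside every
window are dropped.

## Priors and MCMC

Defaults (all configurable): Gaussian(0, 10²) on α and every β;
half-normal(1) on σ_φ and σ_θ; Gaussian(0, 2²) on log κ. These are weakly
informative on the log-SMR scale, where effects beyond ±2 are implausible.

Sampling is adaptive random-walk Metropolis-within-Gibbs:

* α and each β: scalar random-walk proposals; only the affected cells'
  likelihood is recomputed.
* φ: the graph is greedily coloured; units of one colour share no edge, so
  their ICAR full conditionals are mutually independent given the rest and
  a whole colour class is proposed and accept/rejected as a vector (two
  colours on a lattice). After every sweep φ is re-centred per component
  and the (size-weighted) level is transferred to α, which leaves the
  likelihood unchanged on a connected map.
* θ: all units proposed at once (conditionally independent).
* σ_φ, σ_θ, κ: random walks on the log scale. The ICAR "likelihood" for
  σ_φ uses the field's quadratic form over edges and rank
  `Σ (component size − 1)`.
* Proposal scales adapt toward 0.44 acceptance in batches of
  `adapt_interval` sweeps during burn-in and are frozen at the end of
  burn-in, preserving detailed balance for the retained draws.
* Initialization: α at the crude log-SMR, β over-dispersed across chains
  (N(0, 0.25²) jitter), φ = θ = 0, σ at prior medians. Default 4 chains.
* Each chain's RNG derives from `(seed, chain index)` via `SeedSequence`;
  identical configs give bit-identical chains.

`sample_posterior(..., fixed={...})` pins named scalars (σ_φ, σ_θ, κ, α);
this is how the tests verify that the prior-only sampler reproduces the
ICAR moments and that the NB sampler at κ = 1e8 reproduces the Poisson
chain.

Convergence is monitored with the classic potential-scale-reduction factor
(PSRF) per scalar parameter, flagged above 1.1. The classic statistic (not
the rank-normalized variant) is used so that identical chains give exactly
√((n−1)/n) ≤ 1.

## DIC and summaries

Per retained draw the deviance −2·log p(y | params) is stored.
`D̄` is its posterior mean; `D̂` is the deviance at the elementwise
posterior mean of **all** quantities, latent fields included (the
"focused"/conditional-level DIC); `pD = D̄ − D̂`; `DIC = D̄ + pD`.
Negative pD is flagged, never hidden. Model selection takes the smallest
DIC; exact ties go to fewer random-effect sets, then Poisson over NB.

Effect summaries report the posterior **median** of `exp(β)` with a central
95% credible interval (the median is robust to the skew of exp-transformed
draws and equivariant under the exp transform); an effect is "significant"
when the interval excludes 1. Reference levels are emitted as exactly 1.
Spatial variation is the posterior median and CI of σ_φ. Smoothed unit
SMRs are posterior medians of `exp(α + β_t + covariate terms + φ_i (+ θ_i))`
per (unit, period); because φ pools neighbours, small units are shrunk
toward their neighbourhood rather than reported at their unstable raw SMR.

## Synthetic data generator

The generator emulates the statistical structure of municipality-level
registry data; its defaults are the documented study scenario used by the
tests:

* **Geography**: 20×20 rook lattice (400 units standing in for a national
  municipality mosaic; arbitrary polygon/edge-list geographies are equally
  supported).
* **Population**: unit-period person-years log-uniform on [500, 50,000] —
  many small units with unstable raw SMRs and a few large ones, as in real
  municipality data; 18 five-year age bands (0–4 … 85+) with one shared,
  gently ageing profile; five 4-year periods with population constant
  within period.
* **Reference rates**: log-linear in age from ~1e-6 (children) to ~1.5e-3
  (85+) deaths per person-year, matching the magnitude of female-cancer
  crude rates per 100,000 by age.
* **Covariates**: language regions grown as contiguous blocks by seeded
  multi-source BFS from random roots (spatially autocorrelated, as
  language is in reality); the largest 25% of units by population are
  urban.
* **Truth**: period SMR ratios (1.0, 0.8, 0.6, 0.45, 0.3) — a strong
  monotone decline of the magnitude reported for female-cancer mortality
  over four decades; language ratios 1.0 (no effect); urban ratio 0.85;
  σ_φ = 0.3; θ absent; Poisson counts (NB with chosen κ on request).
* **CAR field**: drawn exactly from the ICAR with covariance σ_φ²·Q⁺
  (eigen-decomposition per component, null space removed), hence
  sum-to-zero per component by construction; validated against the dense
  pseudoinverse oracle.

What the generator does **not** emulate: the real population pyramid and
its variation across units (one shared age profile — this also keeps the
indirect-standardization estimand exactly proportional to the generating
expected counts), municipality fusions over time, inter-unit migration,
non-constant covariates, or cause-of-death coding artefacts beyond a
user-supplied multiplicative correction. Passing tests therefore
demonstrate correctness of the machinery under the stated model, not
robustness to real-data violations of it.

## Verification experiments and problem sizes

The acceptance suite runs the whole analysis at sizes chosen to give each
check statistical teeth on a single CPU:

* **Parameter recovery**: one full fit (4 chains × 5000 iterations, half
  burn-in) of the spatial Poisson model on the 75+ group of the default
  scenario (the group with the most deaths, hence the most information);
  posterior medians of the period and urban SMR ratios and of σ_φ land
  within ±0.10 of truth. Credible-interval coverage of the same parameters
  is checked over 20 replicate datasets fitted with 2 × 3000 chains.
* **Spatial confounding**: language-ratio recovery is *not* asserted. A
  spatially contiguous covariate cannot be separated from the realized CAR
  field: the field's mean over a language block is attributed to the
  language coefficient, so on any single map the estimate sits at
  exp(block mean of φ) — up to ±0.3 away from the generating ratio — with
  correspondingly wide credible intervals. This is a well-known
  identifiability limit of spatial regression, not an estimation error,
  and it is why single-map language estimates deserve cautious
  interpretation.
* **DIC selection**: under Poisson truth, the spatial Poisson model must
  have the lowest DIC in ≥ 7/10 replicate datasets. An unneeded
  unstructured RE collapses toward zero, so models 1 and 3 differ by only
  ~2 DIC units; the two Poisson fits run longer (4 × 6000) so the
  posterior-mean deviance resolves that gap, while the clearly-losing NB
  fits run at 2 × 2500. Under NB truth the experiment runs at baseline
  SMR 3 so the per-cell variance/mean ratio 1 + μ/κ ≈ 2.5 constitutes
  genuinely strong overdispersion — at the default baseline (μ ≈ 0.6 per
  cell) the ratio is only ~1.3 and no criterion can tell the families
  apart, since per-unit random effects mimic that much noise; an NB model
  must then win ≥ 7/10.
* **Shrinkage**: among cells with expected < 1 and at least one death, the
  posterior log-SMR must be closer to the neighbourhood mean (of the
  neighbours' smoothed log-SMRs) than the raw log-SMR in ≥ 95% of cells.
* **Exact identities**: standardization closure to 1e-9 relative; CAR full
  conditionals equal to the dense Gaussian conditionals on every connected
  graph with ≤ 5 nodes; forward-simulated CAR covariance within ~5 Monte
  Carlo standard errors of σ²Q⁺ over 10,000 draws; DIC decomposition
  identities; bit-identical reruns.

## Numerical choices and degenerate inputs

* Cells with expected = 0 must have y = 0 (enforced) and contribute 0 to
  the likelihood; they are excluded from the sampler's flat cell arrays.
* Zero person-year bands get reference rate 0, keeping E defined.
* σ_φ = 0 (only reachable when pinned): the field prior degenerates to
  φ ≡ 0 and field moves are skipped.
* Exact DIC ties are resolved at 1e-9 rounding before the simplicity
  tie-break.
* Unit ordering is lexicographic by `unit_id` everywhere; lattice ids are
  zero-padded so lexicographic order is row-major.
* Queen contiguity (any shared boundary point) is the polygon default
  because real municipality mosaics contain corner touches; rook (shared
  edge of positive length) is a flag away. The treatment of islands and
  the contiguity rule are this package's choices — source analyses rarely
  state them.

## Known limitations

* Conditional-level ("focused") DIC under-penalizes latent flexibility;
  alternative focuses (marginal DIC, WAIC, LOO) are out of scope.
* No space–time interaction random effects and no period-specific spatial
  fields: period enters as a fixed factor and the spatial field is
  time-constant. A temporal random-walk extension is a natural next step
  but is not assumed by the reported summaries.
* The per-component re-centring of φ transfers the level to the intercept
  exactly only on a connected map; with several components the projection
  is the standard practical approximation.
* Language-type (spatially contiguous) covariates are confounded with the
  spatial field; see above.
* Shapefile input is not supported; polygon geographies are read from
  GeoJSON.
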