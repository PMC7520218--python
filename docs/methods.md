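# Methods

## Data model and preparation

The analysis unit is a subplot × species abundance matrix with nested
sample metadata (site > plot > subplot) and a two-level management factor
(pasture / meadow). Two abundance kinds are supported:

- **Percent cover** (plants). Rarefaction and PIE are defined over discrete
  individuals, so cover is discretised to pseudo-individuals at 1%
  resolution: each cell becomes `round(value)`, with positive covers below
  0.5% mapped to 1 so presence is never lost. This treats 1% cover as one
  "individual"; any monotone discretisation at fixed resolution gives the
  same ranking of communities, but absolute S_n values depend on the
  resolution chosen.
- **Read counts** (OTU tables). Rare OTUs are removed by prevalence: taxon
  kept iff its count exceeds `min_count` (default 5, strict inequality) in
  at least `ceil(min_sample_fraction × n_samples)` samples (default 1%,
  rounded up so the threshold is never zero). The per-sample reading of
  "occurs more than 5 times in at least 1% of samples" follows the common
  phyloseq filtering idiom. Filtering touches only the taxon set, never
  retained cell values, and is idempotent.

All-zero taxa and samples are retained with a logged note; subplots with
fewer than 2 individuals are excluded from base-n determination and carry
missing PIE values, but keep their N and S.

## Diversity metrics

Per abundance vector (counts `N_i`, total `N`, richness `S`):

- `S_n = Σ_i [1 − C(N−N_i, n)/C(N, n)]`, the hypergeometric expectation of
  richness in a subsample of `n` individuals. Binomial ratios are computed
  as `exp(lnΓ(N−N_i+1) + lnΓ(N−n+1) − lnΓ(N−N_i−n+1) − lnΓ(N+1))`, exact to
  ~1e−12 against brute-force subset enumeration and stable for totals of
  at least 1e7 (deep sequencing). `n` must satisfy `1 ≤ n ≤ N`.
- `PIE = N/(N−1) · (1 − Σ (N_i/N)²)`: the without-replacement (bias
  corrected) probability of interspecific encounter. Undefined for `N < 2`
  (propagated as missing). Tiny negative values from float cancellation in
  monocultures are clamped to 0.
- `S_PIE = 1/(1−PIE)`. The degenerate `PIE = 1` yields a missing value with
  a warning. As counts grow, `S_PIE → 1/Σp²` (Hill number of order 2); for
  a perfectly even community it tends to `S`.

**Scales.** The rarefaction base `n` is the minimum subplot total of the
site across both management types. α-scale values are arithmetic means of
per-subplot metrics (per-subplot vectors retained for the ANOVA); γ-scale
values are computed on the pooled group vector, with `S_n` rarefied at
`n × n_subplots` so both scales reflect the same per-subplot effort.

**β-diversity** is multiplicative, `β = γ/ᾱ` (Whittaker), for `S`, `S_n`
and `S_PIE`. Inside `β-S_n` the pooled vector is rarefied at the *same*
`n` as the subplots — this is what cancels density and SAD-shape effects
and leaves `β-S_n` a measure of intraspecific aggregation. Note that the
reported γ-scale `S_n` (at `n × n_subplots`) and the γ rarefaction inside
`β-S_n` (at `n`) are deliberately different computations.

Exact `β = 1` for identical subplots holds only where the α- and γ-scale
computations coincide (e.g. identical monocultures): for general identical
subplots the pooled vector has k-fold counts, so `E[S_n]` (which depends on
absolute counts, not proportions) and PIE's `N/(N−1)` factor differ
slightly from the subplot values. The discrepancy vanishes as counts grow;
a property test pins it below 2e−3 at subplot totals of 7000.

## Inference

Effect sizes are log-response ratios `ln(pasture/meadow)` (meadow =
reference). Non-positive or missing group values propagate as missing with
a warning.

- **α-scale**: one-way ANOVA on subplot values; two groups, so `F = t²` of
  the pooled-variance t-test, `p` from `F(1, n−2)`. Degenerate inputs: no
  within-group variance with equal means → `F = 0, p = 1`; with unequal
  means → `F = ∞`, p at float tiny. An optional label-permutation p for the
  same F statistic is available (`alpha_n_perm`).
- **γ- and β-scales**: one value per group, so a permutation null —
  subplots are reassigned to the two management labels uniformly at random
  with group sizes preserved (optionally whole plots via
  `permutation_unit="plot"`), both pooled metrics recomputed, and the
  two-sided add-one p-value computed as
  `p = (1 + #{|LRR*| ≥ |LRR_obs|}) / (n_perm + 1)` with ties counted as
  extreme (Phipson–Smyth). Default `n_perm = 199`, giving a minimum
  reportable p of 0.005. A raw-difference statistic is available behind
  `statistic="diff"`. All metrics share one set of permutations per site;
  draws where any metric is undefined are redrawn (hard cap 100 rounds).
  The engine is vectorised across permutations (pooled count matrices via
  one boolean matrix product), which is what keeps 1,000-dataset
  calibration runs in seconds.
- **Design standardization**: when plot counts differ between groups, all
  `C(P_large, P_small)` subsets of the larger group's plots are enumerated
  (seeded uniform sample of distinct subsets above a cap, default 200);
  each subset plus the full smaller group forms one balanced replicate.
  Balancing selects whole plots — keeping all their subplots — which
  reproduces the tractable replicate counts of the field designs (3-vs-1
  plots → 3 replicates, 4-vs-2 → 6, balanced → 1). Replicate LRRs are
  combined by arithmetic mean; replicate p-values by the plain unweighted
  harmonic mean `k/Σ(1/p_i)` (used here as an averaging device, not
  Wilson's asymptotically exact HMP test; the harmonic mean is never
  larger than the arithmetic mean and lies within the replicate range).
  The base `n` is recomputed within each replicate, since the standardized
  subplot set defines that replicate's minimum.
- **Classification**: each metric's (LRR_α, LRR_γ) pair with p-values at
  α-level 0.05 → `qualitative_reversal` (both significant, opposite
  signs), `consistent_both`, `alpha_only`, `gamma_only`, `none`, or
  `undetermined` (missing effects); an exact-equality flag marks pairs on
  the 1:1 line. The quadrant summary reports category counts and the
  fraction of reversals among determined cases.

Per-site analyses are independent; no multiple-testing correction is
applied across sites or taxa, and no mixed-effects structure is modelled.

## Synthetic communities

The generator emulates the nested field design (default 5 sites × 2
management types × 3 plots × 10 subplots of 1 m²) with three orthogonal
community knobs and per-component treatment multipliers applied to the
pasture group:

- **Density** `density_lambda` (individuals per subplot; default 100):
  subplot totals are Poisson(λ), counts multinomial. Poisson totals (not
  fixed N) let density and richness effects decouple naturally.
- **Evenness** `sad_sigma` (lognormal SAD shape; default 1.0): the
  regional SAD is `p_i ∝ exp(σ·z_i)` with shared standard-normal deviates
  `z_i` per site. A treatment multiplier rescales σ *on the same
  deviates*, so both groups share one species pool and ranking and only
  the SAD shape (hence S_PIE) moves. σ = 0 is the perfectly even pool.
- **Aggregation** `aggregation_theta` (default 5.0): every subplot
  realises the regional SAD *shape* exactly; which species occupies which
  abundance rank follows the ordering of noisy suitability scores
  `ln p_i + η/√θ` (η standard normal, fresh per subplot). θ → ∞ pins all
  subplots to the regional ranking (β → 1; implemented exactly above
  1e8); small θ decorrelates species identities across subplots —
  intraspecific clumping that raises β-S_n while leaving every α-scale
  metric's distribution untouched. A species-level Dirichlet-multinomial
  was rejected for this role because overdispersing the abundance values
  themselves collapses subplot evenness (E[Σq²] = (θΣp² + 1)/(θ + 1)),
  confounding the aggregation knob with S_PIE; the 1/√θ noise scale makes
  θ behave like an effective number of observations behind each species'
  local suitability and responds over the same θ range.

With all multipliers at 1 the two groups are exchangeable draws from one
generator — an exact null used for type-I-error calibration. Measured
calibration (1,000 null experiments, λ=100, 50 species, 2 plots × 10
subplots per group, 199 permutations): rejection at 0.05 lies within
[0.03, 0.07] for N, S_n, S_PIE, β-S_n and β-S_PIE. Observed γ-scale
richness S is the exception by construction: at these densities both
pooled groups see nearly the whole species pool, most null datasets have
LRR exactly 0, and the tie-respecting permutation p is valid but strongly
conservative — a saturation property any exact test of a discrete
statistic shares, not an implementation artefact.

What the generator does **not** emulate: spatially explicit coordinates or
dispersal, within-site environmental gradients (plots are exchangeable
within a group), temporal dynamics, detection error in cover estimates,
and sequencing artefacts (chimeras, tag switching) upstream of the OTU
table. Passing recovery tests therefore show the *estimators and tests*
behave correctly under the design, not that any particular field system
satisfies the generator's assumptions.

## Problem sizes and numerical choices

Validation workloads are sized for a laptop-class single core: the
exhaustive rarefaction oracle covers all abundance vectors with N ≤ 8
(closed form vs subset enumeration, agreement 1e−12); the PIE oracle 500
random vectors with N ≤ 50 in rational arithmetic; type-I calibration
1,000 simulated experiments; component recovery 20 simulations per
scenario at λ=200, 100 species, 30 subplots per group (density ×2 recovers
LRR(N) within 0.05 of ln 2 with |LRR(S_n)| < 0.05; evenness σ×2 moves
LRR(S_PIE) below −0.1 with N untouched; aggregation θ×0.1 raises
LRR(β-S_n) above 0.1 with α-scale S_PIE untouched). All randomness flows
from one master seed through named substreams (CRC-32 of the stream name
folded into a `SeedSequence`), so any component can be re-run in
isolation; identical configurations produce byte-identical CSV outputs.

## Known limitations

- Cover discretisation fixes a 1%-cover ≙ 1-individual convention;
  S_n/PIE on cover data inherit that resolution.
- The harmonic-mean combination is descriptive; it is not calibrated as a
  frequentist combined test under dependence.
- γ-scale permutation reassigns subplots by default; if plots are strongly
  autocorrelated the plot-level option is the safer (more conservative)
  exchangeability unit.
- β = γ/ᾱ with finite counts is biased slightly below its asymptotic value
  (see above); comparisons between groups at similar N are unaffected.
- The classification applies a fixed 0.05 threshold per scale with no
  correction across the many site × taxon × metric tests.
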