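# scalediv

Scale-dependent biodiversity partitioning of land-management effects on
hierarchical community data.

Grassland management (grazing vs mowing), like most ecological drivers, can
change biodiversity in opposite directions at different spatial scales: a
treatment that lowers richness within 1 m² subplots may raise it at the
pooled site level, or vice versa. `scalediv` implements the individual-based
framework that disentangles *why* richness responds — through the density of
individuals, the shape of the species-abundance distribution (evenness), or
intraspecific spatial aggregation — and tests those responses at each scale.
It is aimed at community ecologists and microbial ecologists working with
subplot × species abundance tables (plant percent cover, OTU read counts)
collected under a nested site / plot / subplot design with a two-level
treatment.

## Metrics and model

For an abundance vector with species counts $N_i$, $N = \sum_i N_i$:

- **Rarefied richness** — the expected species count in a random subsample
  of $n$ individuals,
  $S_n = \sum_i \left[ 1 - \binom{N - N_i}{n} \middle/ \binom{N}{n} \right]$,
  evaluated with log-gamma arithmetic (stable to $N \ge 10^7$). The base
  $n$ is the minimum subplot total across both treatment groups of a site;
  the γ-scale uses $n \times$ (number of subplots).
- **PIE** — the probability of interspecific encounter,
  $\mathrm{PIE} = \frac{N}{N-1}\left(1 - \sum_i p_i^2\right)$, the chance
  that two individuals drawn without replacement are different species.
- **S_PIE** $= 1/(1-\mathrm{PIE})$ — PIE as an effective number of equally
  abundant species (a Hill-number-of-order-2 analogue emphasising common
  species).
- **Multiplicative β-diversity** — $\beta = \gamma / \bar{\alpha}$ for $S$,
  $S_n$ and $S_{PIE}$; $\beta\text{-}S_n$ uses the *same* $n$ at both
  scales, isolating spatial aggregation from density and SAD effects.

Treatment effects are log-response ratios $\ln(\text{pasture}/\text{meadow})$,
tested with one-way ANOVA at the α-scale and a 199-permutation null
(subplot labels reshuffled, add-one two-sided p) at the γ- and β-scales.
Unequal plot counts are standardized by enumerating every balanced plot
subset of the larger group; replicate effect sizes are mean-combined and
p-values combined by harmonic mean. Each metric is then classified by its
α/γ response pattern (consistent, one-scale-only, or a qualitative
reversal).

A synthetic-community generator reproduces the nested design with three
orthogonal knobs — Poisson subplot density λ, lognormal SAD shape σ, and an
aggregation parameter θ that shuffles species identities among abundance
ranks across subplots — so every inferential claim can be checked against a
known truth.

## Worked example

Simulate one site whose pastures have a less even community (SAD shape
σ multiplied by 1.5) but unchanged density, then run the full analysis:

```python
import scalediv as sd

cfg = sd.SimulationConfig(
    seed=42, n_sites=1, species_pool=100, density_lambda=100.0,
    treatment=sd.TreatmentMultipliers(sigma_mult=1.5),
)
table, truth = sd.simulate_experiment(cfg)

n = sd.rarefaction_base_n(table, "site01")
print(f"rarefaction base n = {n}")
result = sd.run_site_taxon_analysis(
    table, "site01", "plants", sd.AnalysisConfig(n_perm=199, seed=7)
)
for (metric, scale), comb in sorted(result.combined.items()):
    print(f"{metric:10s} {scale:6s} LRR={comb.lrr:+.3f}  p={comb.p_value:.3f}")
for metric, cls in sorted(result.classifications.items()):
    print(f"{metric:10s} -> {cls.category}")
```

```
rarefaction base n = 78
N          alpha  LRR=-0.007  p=0.788
N          gamma  LRR=-0.007  p=0.790
S          alpha  LRR=-0.149  p=0.000
S          gamma  LRR=-0.030  p=0.005
S_PIE      alpha  LRR=-0.643  p=0.000
S_PIE      gamma  LRR=-0.763  p=0.005
S_n        alpha  LRR=-0.144  p=0.000
S_n        gamma  LRR=-0.035  p=0.005
beta_S_PIE beta   LRR=-0.119  p=0.065
beta_S_n   beta   LRR=-0.002  p=0.855
N          -> none
S          -> consistent_both
S_PIE      -> consistent_both
S_n        -> consistent_both
```

The evenness manipulation is recovered exactly where it should appear:
total abundance N is unaffected (LRR ≈ 0), while S_PIE drops strongly and
significantly at both scales (LRR −0.64 α, −0.76 γ; p = 0.005 is the
minimum reportable value under 199 permutations), dragging S and S_n down
with it. β-diversity is untouched — the treatment changed the SAD, not
spatial aggregation.

A command-line interface mirrors the library
(`scalediv simulate|filter|metrics|run`); `scalediv run` takes a YAML
configuration and writes `metrics.csv`, `effects.csv`,
`classification.csv`, a filter report and a reproducibility manifest.

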