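# poolfilter

Two-phase analysis of plant community assembly: how strongly is local
community composition limited by **seed arrival** versus **microsite
conditions**?

`poolfilter` is for community ecologists working with nested species-pool
data: per site, a regional species pool (species recorded in the
surroundings, with ordinal commonness codes), a local propagule pool
(species caught in seed traps, germinated from soil cores, or already
growing in the plot), and the local community itself. From these it
computes:

- **Filtering fractions** — the share of the regional pool reaching the
  propagule pool (dispersal phase; its complement measures seed
  limitation) and the share of the propagule pool found in the community
  (establishment phase; microsite limitation), as cross-site mean ± SE.
- **Dispersal origin** — each arriving species classified Local /
  Regional-only / Distant (long-distance dispersal).
- **Monte Carlo richness tests** — is local richness a random draw from
  [0, regional richness], or does it track the regional pool (the
  species-pool hypothesis)? One-tailed p from 4999 simulated Spearman
  correlations.
- **Trait-based null models** — per site and transition, observed mean,
  variance and nearest-trait-distance SD (sdNTD) of height, seed mass,
  SLA, clonal growth index, dispersal method and regional abundance,
  compared with 4999 random assemblies of equal size drawn from the
  source pool, either equiprobably (EP) or weighted by regional
  abundance (WP, sampling without replacement proportional to remaining
  weights). Two-tailed outcome at α = 0.025 per side; variance/sdNTD
  below the null indicates trait convergence (environmental filtering),
  above it divergence (limiting similarity).
- **Abundance correlations** — per-site Spearman correlations between
  pool abundance vectors (RSP–VEG, RSP–SB, RSP–SR, VEG–SB, VEG–SR) and
  cross-site counts of positive-significant sites.
- A **synthetic data generator** that simulates the whole design
  (abundance- and trait-dependent dispersal, trap-based rain sampling
  with trap loss, persistent seed bank, neutral or height-filtered
  establishment) with the generating truth stored for calibration and
  parameter-recovery experiments.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
from poolfilter import (SyntheticConfig, generate_dataset, standardize_rain,
                        build_pools, filtering_fractions, classify_origin,
                        richness_by_pool, mc_richness_test)

dataset = generate_dataset(SyntheticConfig(), seed=1)
rain = standardize_rain(dataset.observations)          # trap-loss standardization
pools = build_pools(dataset.observations, rain)        # per-site species pools

filt = filtering_fractions(pools)
print(f"regional -> propagule: {filt.mean_regional_to_propagule:.1%} "
      f"(SE {filt.se_regional_to_propagule:.1%})")
print(f"propagule -> community: {filt.mean_propagule_to_vegetation:.1%} "
      f"(SE {filt.se_propagule_to_vegetation:.1%})")

origin = classify_origin(pools).summary
prop = origin[origin["pool"] == "propagule"]
for _, row in prop.iterrows():
    print(f"propagule pool, {row['origin']:>13}: {row['mean']:.1%} (SE {row['se']:.1%})")

rich = richness_by_pool(pools)
res = mc_richness_test(rich["regional"], rich["vegetation"],
                       seed=11, pool_pair="regional-vegetation")
print(f"richness correlation (vegetation): rho = {res.obs_rho:.2f}, p = {res.p_value:.4f}")
```

prints

```
regional -> propagule: 37.8% (SE 0.8%)
propagule -> community: 70.6% (SE 1.0%)
propagule pool,         local: 70.6% (SE 1.0%)
propagule pool, regional_only: 18.9% (SE 1.1%)
propagule pool,       distant: 10.5% (SE 1.1%)
richness correlation (vegetation): rho = 0.78, p = 0.0084
```

Under this simulated design, roughly a third of the candidate colonizers
around each site actually arrive (strong seed limitation) while some 70%
of arrivals establish (weaker microsite limitation); about a tenth of
arrivals come from beyond the regional survey; and local richness tracks
regional richness far more closely than the uniform null allows
(p ≈ 0.008), the species-pool signal built into the generator.

The same pipeline runs from the shell on any observation/trait CSVs in
the documented long format:

```sh
poolfilter simulate --out data/ --seed 1
poolfilter report --input data/observations.csv --traits data/traits.csv \
    --out results/ --seed 4
```

`report` writes the standardized rain, per-site pool membership,
filtering and origin summaries, richness tests, the full null-model
grid with its signed cross-site summary table, and the abundance
correlations, each CSV carrying the config digest and seed in a header
comment.

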