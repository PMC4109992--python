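# Methods

## The analysis

`poolfilter` quantifies the two phases of plant community assembly from
species lists observed at three nested levels per site:

- **regional species pool** — every species recorded within a 100-m
  radius of the site, excluding trees and non-seed-bearing plants: the
  candidate colonizer set, with an ordinal commonness code 0–3;
- **local propagule pool** — every species detected in the site's seed
  rain, seed bank, or established vegetation: the species that
  demonstrably reached the site;
- **local community** — species growing in the site's 10 × 10 m plot,
  with cover-abundance 0–8 (sentinel 0.1 for species seen in the plot
  but in no subplot).

The fraction of the regional pool that appears in the propagule pool
measures the *dispersal phase* (its complement is seed limitation); the
fraction of the propagule pool that appears in the community measures
the *establishment phase* (its complement is microsite limitation).
Cross-site summaries report mean ± SE, with SE = sample SD (n − 1
denominator) across sites divided by √n.

Species in a propagule pool (or seed rain / seed bank) are classified by
origin: **local** (also in the site's vegetation), **regional-only** (in
the regional survey but not the vegetation) and **distant** (absent from
the regional survey, indicating long-distance dispersal).

### Seed-rain standardization

Summer and winter trap sets are standardized separately for trap loss,
then summed into a total site seed rain per species. Two conventions are
implemented:

- `as_printed` (default): cumulative seedling count × (traps recovered /
  20). This is the rule as stated for the reference design.
- `scale_up`: count × (20 / traps recovered), which extrapolates to a
  full trap set and is arguably what an estimate of the total yearly
  rain requires.

Both preserve zeros, so pool membership — and everything built on
presence/absence — is identical under either; only downstream abundance
correlations can differ. The rule used is recorded in the output.

### Monte Carlo richness test

Whether local richness tracks regional richness is tested against a null
in which site *j*'s local richness is an integer drawn uniformly on
[0, R_j] (inclusive), R_j being the site's regional richness. Spearman's
rho (tie-corrected, i.e. Pearson on average ranks) between regional and
simulated local richness is computed for 4999 replicates; the one-tailed
p is the proportion of simulated rho ≥ observed rho. Replicates whose
draw is constant across sites have undefined rho and are counted as not
exceeding the observed value. The observed rho is invariant to strictly
monotone transforms of either richness vector; note that the *null
distribution* is not, since the draw ranges [0, R_j] are part of the
null hypothesis.

### Trait null models

For each site and transition — regional → {propagule, seed rain, seed
bank} and propagule → community — the observed value of a test statistic
on the assembly's trait values is compared with its distribution over
4999 random assemblies of the same size drawn without replacement from
the source pool. Statistics:

- **mean** trait value;
- **variance** (sample variance, n − 1);
- **sdNTD** — the sample SD across species of each species' distance to
  its nearest neighbour on the trait axis (duplicates → distance 0).
  The SD uses the n − 1 denominator by default (`sdntd_ddof` toggles);
- **category proportion** — for the categorical dispersal-method trait,
  the proportion of the focal category (default `unassisted`).

Randomization is **EP** (equiprobable) or **WP** (weighted by regional
abundance). WP uses successive sampling: each draw is proportional to
the weights of the species still available. The vectorized engine
implements this with exponential keys (the k smallest values of
Exp(1)/w_i), which is distribution-identical to the draw-by-draw scheme;
the public `weighted_sample_wor` implements the literal sequential
scheme and the test suite verifies their agreement against exact
enumeration. WP weights default to the per-site 0–3 commonness codes
(restricted to the source pool, where codes are ≥ 1); a configurable
transform can replace them with derived abundances.

Both one-sided p-values are the proportions of simulated values at or
below / at or above the observed value; **ties count toward both
tails**, a conservative and symmetric convention. The observed
configuration is not added to the null sample; a `plus_one` toggle
switches to the (count + 1)/(n_iter + 1) convention. An assembly is
`lower` / `higher` when the corresponding p < α (default 0.025,
two-tailed rule), else `random`.

The full grid per site: regional transitions test mean (EP, WP),
variance (EP, WP) and sdNTD (EP only) for height, seed mass, CGI and
SLA; the unassisted-dispersal proportion with mean (EP, WP); and
regional abundance — the commonness code itself treated as a trait —
with mean (EP) only. The propagule → community transition is tested
under EP only, without the abundance test. The cross-site summary
reports signed counts per cell: sites significantly lower (printed with
a minus) and higher (plus).

Design choices worth noting:

- **Pool restriction.** Targets are intersected with their source pool
  before testing: long-distance dispersers present in a propagule pool
  but absent from the regional survey cannot be "reassigned from the
  regional pool" and are excluded from regional → X tests.
- **Missing traits.** Species missing the focal trait are dropped from
  source and target for that test only, keeping the observed statistic
  and its null commensurable.
- **Degenerate assemblies.** A target equal in size to its source is
  reported `random` with both p = 1 (every draw reproduces it); targets
  smaller than the statistic's minimum n (mean 1, variance 2, sdNTD 3)
  propagate as `not_testable`, never as a numeric 0.
- **Interpretation mapping.** Variance or sdNTD significantly *below*
  the null is labelled convergence (underdispersion, environmental
  filtering), *above* divergence (limiting similarity), following the
  standard summary-table sign convention. Some writings of this method
  state the reverse; the mapping here is a documented dictionary
  (`OUTCOME_INTERPRETATION`) and can be swapped without touching the
  statistics.
- Traits are tested on the scale given in the trait table; optional
  per-trait log transforms are available and off by default.

### Abundance correlations

Per site, Spearman correlations between abundance vectors of pool pairs
(RSP–VEG, RSP–SB, RSP–SR, VEG–SB, VEG–SR). The species universe is
configurable: `union` of species present in either pool (default;
absences coded 0), `intersection`, or the full `regional` pool. p-values
use the large-sample t approximation; an exact permutation option exists
for n < 10. Cross-site counts report sites with rho > 0 and p < 0.05
(no multiple-testing correction, matching the reference analysis).
The reported counts are sensitive to both the universe and the
threshold, which is why all three scopes are implemented.

## The synthetic generator

`poolfilter.synthetic` simulates the full study design with known truth,
for calibration and parameter-recovery testing. Defaults (all chosen
once, a priori, to emulate the reference design):

| parameter | default | meaning |
|---|---|---|
| `n_sites`, `n_regional` | 12, 278 | study layout |
| abundance | lognormal(0, 1) | regional abundance; commonness codes 1–3 by terciles |
| `occupancy_floor` | 0.35 | minimum per-site presence probability (shared-pool fraction); occupancy rises with abundance rank |
| height | lognormal(−0.7, 0.6) m | median ≈ 0.50 m, grassland-like |
| seed mass | lognormal(0, 1.2) mg | median 1 mg, broad range |
| SLA | normal(25, 8) mm²/mg, truncated > 0 | |
| CGI | uniform {0..3} | ordinal clonal growth index |
| dispersal method | unassisted .45 / wind .25 / animal .20 / other .10 | grazed-grassland mix |
| `beta0, beta_abund, beta_seedmass, beta_unassisted` | −1.8, 1.0, 0.35, 0.9 | dispersal logit; β₀ set so the mean dispersal probability ≈ 0.36, the regional → propagule fraction of the emulated design |
| `distant_rate` | 0.10 | share of arrivals drawn from outside the site's regional pool (abundance-weighted), giving all three origin classes |
| `n_traps`, `trap_loss_prob` | 20, 0.10 | per season; recovered-trap count is Binomial |
| `rain_intensity` | 3.0 | Poisson seed-rain intensity per unit abundance |
| `local_rain_boost` | 3.0 | rain multiplier for locally established species — a site's own vegetation dominates its measured rain, which is what makes VEG–SR correlations near-universal |
| `summer_fraction` | 0.9 | dominant summer cohort |
| `bank_retention` | 0.3 | seed-bank Poisson intensity relative to rain; the bank uses the *unboosted* intensity (it integrates past regional input), keeping VEG–SB coupling weak |
| establishment | `neutral`, p = 0.78 | the establishment fraction of the emulated design; `gaussian_height` applies exp(−(h−μ_site)²/2σ²) with a site-specific optimum instead |

Dispersal probability is
logistic(β₀ + β_abund·log(a+1) − β_seedmass·log m + β_unassisted·1[unassisted]).
With all β = 0 and neutral establishment the community is trait-neutral
and the null models reject at their nominal ≈ 2α rate. Seed counts are
Poisson (negative-binomial toggle for overdispersion studies).
Establishment applies only to arrivals that belong to the site's
regional pool, so vegetation ⊆ regional holds by construction.

What the generator does *not* emulate: spatial structure within sites or
dispersal kernels, multi-year dynamics, phylogenetic trait correlation,
observation error in trait measurement, and taxonomic ambiguity. Passing
recovery tests therefore show that the statistics detect the modelled
filters at realistic sizes and noise levels — not that real communities
obey this generative model.

Note that the *observed* establishment fraction (propagule →
community) is slightly below the establishment probability: the observed
propagule pool also contains distant arrivals, which cannot establish,
so its expectation is ≈ p_establish × (1 − distant share) ≈ 0.70 under
defaults. The recovery tests use this corrected anchor.

## Numerical choices and problem sizes

- All randomness flows through `numpy.random.Generator` seeded from
  user-supplied integers; batteries spawn one child seed per test in a
  fixed grid order, so results are bit-identical across runs and
  independent of which subset of tests is inspected.
- Tie comparisons of simulated vs observed statistics use a relative
  tolerance of 1e-9 to make exact combinatorial ties robust to float
  summation order.
- Spearman rho is scipy's tie-corrected statistic; the richness-test
  internals compute the identical rank-Pearson formula vectorized so
  observed and simulated values share one float path.
- Default iteration counts are 4999 throughout. The type-I calibration
  experiment uses 1000 replicate assemblies at 999 iterations each, and
  parameter-recovery experiments 20 replicate datasets, sizes at which
  every experiment completes in seconds while binomial error on the
  reported rates stays below about 1.5 percentage points.

## Known limitations

- The ordinal commonness codes are a coarse abundance proxy; WP results
  can shift if derived abundances are substituted (a transform hook is
  provided).
- The exact-permutation correlation p is limited to n < 10 species.
- The regional commonness scale's 0–3 coding is assumed monotone in
  commonness; no finer calibration is attempted.
- Sites whose propagule pool is empty are excluded (with a warning) from
  establishment-fraction and origin summaries rather than imputed.
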