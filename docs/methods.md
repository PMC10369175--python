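# Methods

## The model

`lmcsim` simulates the co-evolution of sex allocation and density-dependent
dispersal in a viscous population: an island-model metapopulation of
`n_patches` discrete patches, each founded by `n` mated females
("foundresses").  Generations are discrete and non-overlapping.  One
generation proceeds as:

1. **Brood production.**  Each mother bears `brood` (default 10) offspring
   and dies.  Each offspring is a son independently with probability z, the
   mother's expressed sex-allocation phenotype.  On every occupied patch one
   uniformly chosen mother bears one extra guaranteed son and one
   independently chosen mother one extra guaranteed daughter, so every patch
   can mate all of its daughters.  The two forced offspring mean a patch of
   k mothers yields `brood`·k + 2 juveniles; in the single-foundress
   treatment each patch produces exactly 12 offspring, so even an
   all-daughter strategy realizes a son fraction of 1/12 ≈ 0.083 — the
   finite-brood floor on sex allocation.
2. **Mating.**  Every daughter mates once with a uniformly chosen male of
   her natal patch (males mate repeatedly); the mate's genetic contribution
   is stored with her.  Males then die.
3. **Dispersal.**  Each mated daughter assesses the normalized daughter
   density of her natal patch, ρ = D / D_max with D the patch's post-mating
   daughter count and D_max = `brood`·n + 1 the largest locally producible
   count (an all-daughter brood from every mother plus the forced daughter;
   the forced son makes this the tight bound).  She attempts dispersal with
   probability p(ρ) = p₀ + (p₁ − p₀)·ρ, the linear reaction norm between her
   expressed zero-density and maximum-density endpoints, clipped to [0, 1].
   An attempter dies with probability c (the dispersal cost) and otherwise
   relocates to a uniformly chosen non-natal patch.  Density is assessed
   once, before anyone moves.
4. **Regulation.**  On each patch at most `n` of the present mated daughters
   are retained (uniformly without replacement) as next-generation mothers.
   Patches can be under-filled or empty; empty patches remain valid
   dispersal destinations and can be recolonized.

## Genetics

Each individual carries three real-valued loci: sex allocation, dispersal at
zero density, dispersal at maximum density.  Allelic values are unbounded;
phenotypes are the additive (mean-of-alleles) expression clipped to [0, 1]
at the point of use — a sex-allocation value below 0 is an all-daughter
strategy, above 1 an all-son strategy, and the reaction norm is interpolated
on the raw endpoint values before clipping.  Three genetic systems are
supported: haploidy (sexual, with a fair maternal/paternal coin flip per
locus), diploidy (one uniform draw from each parent's pair per locus), and
haplodiploidy (diploid daughters from one maternal draw plus the father's
single allele; haploid sons from an unfertilized maternal draw).  Loci
assort independently.  Every transmitted gene mutates with probability 0.01,
gaining a Normal(0, 0.1²) increment.

Internally the population is held as structure-of-arrays cohorts (patch
index plus an (N, 3, 2) allele array; haploid genomes store their single
allele duplicated so that additive expression and gamete draws are
ploidy-agnostic, with mutation applied to logical genes).  The per-individual
object API in `lmcsim.genetics` carries the same rules and serves as the
reference semantics in the test suite.

## Initialization

All dispersal alleles start at the unbeatable density-independent dispersal
probability d* = 2/(1 + 2cn + √(1 + 4n(n−1)c²)), i.e. both reaction-norm
endpoints equal d*, a flat norm.  Sex-allocation alleles start at the
classical local-mate-competition value z₀ = (n−1)/(2n) for all three
systems (`TreatmentConfig.z0` overrides).  Founding mothers' mates carry the
same allelic values.  Because every treatment is run through a long
mutation–selection burn-in, the equilibrium does not depend on z₀; the test
suite verifies that founding populations at z₀ = 0.05 and 0.45 converge to
statistically indistinguishable equilibria.

## Reported statistics

* **mean_z** — the realized population sex ratio: sons / all juveniles,
  pooled over patches, averaged over the final `record_window` generations.
  The forced extras are part of the population, so a population whose
  genotypic value is z* realizes (brood·n·z* + 1)/(brood·n + 2) — e.g.
  0.2727 rather than 0.25 at n = 2.  Tests against analytic baselines use
  this corrected value.
* **mean_d** — the realized dispersal attempt rate: attempts / mated
  daughters, counted before dispersal mortality, averaged over the window.
* **undersized_fraction** — the under-dense patch diagnostic.  Each
  generation the population-mean reaction norm (genotypic means of the
  mated-daughter cohort's endpoints, unclipped) defines a constant
  non-disperser threshold K: the smallest daughter count at which the mean
  norm turns positive (0 if positive at zero density; D_max if never
  positive).  The statistic is the fraction of occupied patches with D < K,
  averaged over the window.  Patches below K export nobody even at full
  retention, so density-dependent dispersal cannot relieve their local
  competition.

## The randomization test

The dispersal–sex-allocation relationship is summarized by the fixed-effect
coefficient of mean_z regressed on mean_d in a mixed-effects linear model
with a by-group random slope for the foundress number,
z = b₀ + b₁·d + u_g·d + e, fitted by maximum likelihood on the 24-cell
haploid+diploid table (n ∈ {2, 5, 10}; the single-foundress cells are
excluded because no dispersal effect is predicted there, and the
haplodiploid cells because the invariance null is not exact under
haplodiploidy).  Significance uses a Monte Carlo randomization test: z
values are permuted uniformly within each n group (d and the grouping
fixed), the model is refitted per permutation, and P = (R + 1)/(N + 1) with
R the number of permuted coefficients ≥ the observed one — one-sided, by
construction.  The default is N = 100,000 randomizations.

Within-group permutation is the scheme that actually addresses the
invariance null.  Sex allocation increases with n whatever dispersal does,
and the treatment design ties d to n, so z and d are strongly related
*between* groups for reasons the null does not dispute.  A global
permutation folds that between-group spread into the null distribution and
swamps the within-group alignment: on a representative desk-scale table the
observed coefficient ranks near the null median under global permutation
(P ≈ 0.4) under every variant of the mixed model we examined (slope-only,
random intercept + slope, pooled within-group estimator), while
within-group permutation puts it beyond every one of 999 draws (P = 0.001)
— matching the decisive full-scale rejection this machinery is meant to
reproduce.  The global scheme remains available (`within_group=False`;
`--global-perm` on the CLI) for sensitivity analysis.

The ML fit is computed by profiling the likelihood over the variance ratio
λ = σ_u²/σ_e².  Sherman–Morrison reduces each group's marginal covariance
inverse to scalar cross-products, so the profile likelihood and GLS
coefficients are closed-form in λ and thousands of permuted datasets are
fitted simultaneously (coarse λ grid, then a vectorized golden-section
refinement; λ = 0 — ordinary least squares — lies inside the search domain,
so the boundary case needs no fallback).  The implementation is
cross-checked against `statsmodels.MixedLM` (ML) in the test suite; the two
agree to ~1e-10 in log-likelihood on reference datasets.  The hand-rolled
path exists because the randomization and type-I-error suites refit the
model ~10⁶ times, which general-purpose mixed-model machinery cannot do in
reasonable time.

## Problem sizes

Three named profiles ship with the package:

| profile  | patches | generations | window | purpose                         |
|----------|---------|-------------|--------|---------------------------------|
| `paper`  | 1000    | 100,000     | 50,000 | the full-scale study design     |
| `scaled` | 250     | 20,000      | 10,000 | desk-scale focal treatments     |
| `quick`  | 100     | 8,000       | 4,000  | desk-scale treatment grids      |

The full study grid crosses three genetic systems with n ∈ {1, 2, 5, 10}
and c ∈ {0.2, 0.4, 0.6, 0.8} (48 cells).  The acceptance suite runs the
24-cell haploid+diploid table at `quick`, the focal n = 10, c = 0.8
treatment at `scaled`, and the flat-norm control at 200 patches / 6,000
generations.  Haplodiploid trend cells run 24,000 generations: reaction-norm
evolution is distinctly slower under haplodiploidy at desk scale, and 8,000
generations leaves the norm essentially flat in the high-cost cells.
Desk-scale equilibria are compared to analytic baselines with an absolute
tolerance of 0.03 (and 0.04 for cross-cost invariance differences),
reflecting the drift of window means in populations of a few hundred
breeding sites.

Per-cell seeds are derived from a master seed with `numpy.random.SeedSequence`
keyed on (master, mode, n, c), so grid cells are independent and a cell's
result does not depend on which other cells are run.  Identical
configurations with identical seeds reproduce bit-for-bit.

## What the simulations do and do not show

The generator *is* the study system: there is no external data, and the
simulated conditions (1000 patches, 10-offspring broods, mutation rate 0.01,
increment SD 0.1, the n and c grids) are the study design itself, scaled
down along patches × generations for desk hardware.  Passing desk-scale
tests shows the mechanism — density-dependent dispersal breaking the
Bulmer-Frank invariance toward greater female bias at higher dispersal
cost — is present and detectable at reduced scale; it does not certify the
full-scale equilibrium values, which carry less drift.

Known limitations:

* **The under-dense diagnostic is the least scale-robust quantity.**  The
  linear reaction norm is selected only on the narrow band of densities a
  patch actually realizes; outside that band the endpoint alleles accumulate
  mutation–drift variance without consequence, so the extrapolated
  population-mean endpoints spread over time (p₀ drifts strongly negative,
  p₁ compensates) while realized dispersal stays at its equilibrium.  The
  zero-crossing K of the mean norm therefore creeps upward with run length
  and with drift strength (i.e. at smaller population sizes), and the
  fraction of patches below K measures substantially higher at desk scale
  (~0.8 in the n = 10, c = 0.8 treatment at 250 patches) than the ~0.3 the
  full-scale design reports.  The realized dispersal rate in that treatment
  (~0.03) is also roughly half the density-independent baseline d* ≈ 0.06,
  consistent with a mean-norm crossing sitting above the typical patch
  density.  The diagnostic is reported exactly as defined
  (`metrics.estimate_threshold` / `metrics.undersized_patch_fraction`);
  treat its absolute magnitude at desk scale with caution.
* Single mating per female, no male dispersal, no overlapping generations,
  and no within-patch structure — all by design of the study system.
* The n = 1 treatment's sex allocation is floored at 1/12 by the forced
  extra offspring, so it sits well above the near-zero large-brood
  prediction; this is a property of finite broods, not a numerical artefact.
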