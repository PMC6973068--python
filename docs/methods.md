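# Methods

## Survival model

The model is deliberately minimal: one focal individual, one target species,
no spatial structure, no groups of more than two species. Detection,
dilution and competition are treated as independent filters whose product
gives survival, `S = (1 − D)(1 − K)`.

Assumptions worth keeping in mind:

- **Alarm information is multiplicative**: a group member only helps if it
  is vigilant *and* calls *and* its call means something to the focal
  (`V_T · A_PT · R_TF`), and informants contribute linearly with group size
  before the saturating transform.
- **Dilution follows predator preference**, not raw headcount: `N_T`
  companions dilute risk only in proportion to their own vulnerability
  `Z_PT`. If no member of the group is vulnerable to a predator, that
  predator takes nobody (`Y = 1`); it also never targets the group
  (`L = 0`), so the two conventions never conflict.
- **Empty groups are solitary life**: with `N_T = 0` the predator has no
  target individual to prefer, so the group-targeting probability reduces
  to the focal's own vulnerability (`L = Z_PF`, not `max(Z_PF, Z_PT)`).
  Without this the "group of zero" would inherit the phantom target's
  vulnerability and solitary baselines would be wrong.
- **Competition is absolute, not per-capita**: mortality depends on the
  share of patch resources the whole group consumes, so large groups of
  heavy consumers are costly even to a frugal focal.

### Constants

| constant | default | meaning |
|---|---|---|
| `c1` | 0.8 | detection half-saturation (raw detection of 0.8 → X = 0.5) |
| `c2` | 10 | competition logistic steepness (smooth, neither linear nor step) |
| `c3` | 0.5 | logistic inflection: a group eating half the patch dies of competition with probability 0.5 |
| `C_tot` | 22 | patch resources; chosen so a unit-consumption conspecific group of the median scan size (N = 10) sits exactly at the inflection: (1 + 10·1)/0.5 |

All overridable via `ModelConstants` or the scan YAML config.

### The scan and its two statistics

Trait grids: targets vary vigilance, alarm probability, vulnerability and
consumption over {0, 0.25, 0.5, 0.75, 1} and alarm relevance over
{0, 0.5, 1} (1875 combinations); focals vary the four traits over
{0, 0.5, 1} with a binary responsiveness flag (162 combinations). The flag
gates the use of *heterospecific* alarm calls only — a species always
responds to its own alarms, so the conspecific baseline uses full relevance
(R = 1) regardless. Group sizes {2, 5, 10, 20, 40} are enumerated exactly
(no Monte Carlo), so the scan is deterministic.

`proportion_better` counts heterospecific scenarios whose survival strictly
exceeds the conspecific group *of the same size* (sizes are drawn from the
same distribution for both, so the matched-size comparison is the natural
one; comparing size-averaged expectations instead lets the competition
channel mask the detection signal once vigilance saturates, and the
vigilance pattern disappears). `max_gain` compares size-averaged expected
survivals, since "the best heterospecific species" is a species-level
notion. Ties never count as better.

## Empirical layers

- **Vigilance** is the plain mean proportion of time vigilant per species;
  the group-size effect is checked (linear model with species factor) and
  reported as a diagnostic, not corrected for — the records are restricted
  to a narrow 4–10 band on purpose.
- **Alarm probability** comes from a binomial GLM with full
  species × predator cells plus distance and young-present covariates;
  predictions are taken at covariate sample means (the standard marginal
  convention; the study leaves the choice open) and summed over predators
  into a per-species index. Complete separation (saturated cells) triggers
  a ridge-penalised refit, flagged in the run report.
- **Alarm relevance** reduces the four playback response variables to their
  first principal component (correlation PCA; latency sign-flipped so
  larger PC1 = stronger response; the PC1 variance share is reported — ~0.9
  on synthetic data), models PC1 on receiver × caller cells with grass
  height, wind and speaker distance as covariates, predicts at covariate
  means, and min-max rescales to [0, 1]. The layer is directed:
  `R[F, T]` is F's responsiveness to T's calls.
- **Diet overlap** is the Pianka index (cosine of the graze/browse
  proportion vectors). **Habitat** is the absolute NDVI difference — a
  distance, despite often being called an overlap; it enters the regression
  as a control, so only the monotone labelling matters. **Movement
  similarity** is 1 iff both species share migratory status.
  **Relatedness** rescales patristic distances from a newick tree to [0, 1]
  similarity (1 = closest pair).
- **Competition** on the empirical side is `k_FT = O_FT · M_T^0.71`: diet
  overlap times the target's metabolic food intake (Kleiber scaling of
  body mass).
- **Group-size distributions** smooth the observed monospecific size
  frequencies with a Poisson GLM (`frequency ~ log(size) + species`),
  normalised over each species' observed support (truncation at the
  observed maximum is implicit). Species with a single observed size fall
  back to the empirical point mass.

## Affinity network

The pairwise index `W_FT` is evaluated exactly as written, over groups with
at least two individuals (a solitary group carries no association
information; its `N_i − 1` denominator would divide by zero). Population
totals still count every individual. The two ordered evaluations are
averaged — the index is conceptually undirected but the formula is not
manifestly symmetric. The diagonal is undefined and excluded everywhere.

The gregariousness correction `w = W·ΣW/(ΣW_F ΣW_T)` uses off-diagonal sums
and is invariant to global rescaling of W. Note a structural property:
a dyad that dominates its members' affinity budgets partially deflates
itself (its own W inflates both row sums), while species with small budgets
get boosted. This is the correction doing its job — measuring *relative*
preference — but it means the strongest absolute association need not be
the top corrected dyad in every finite sample.

Directing the network multiplies `w_FT` by the focal's share of the dyad's
payoffs, where each payoff is expected survival in the partner's groups
(partner's fitted size distribution, all five predators with their
pressures `Q_P`, predator-specific A and Z) divided by solitary survival.
`C_tot` for the payoff model defaults to placing the median species'
typical conspecific group at the logistic inflection, mirroring the scan
convention. The two directed weights of a dyad sum to `w` by construction.

Social differentiation uses the Poisson approximation: dyadic group
co-occurrence counts are Poisson around dyad-specific rates, so
`S² = (var − mean)/mean²` on the counts estimates the squared CV of the
true rates (method of moments, the default); a gamma-rate (negative
binomial) maximum-likelihood variant is provided as a cross-check.
Bands: < 0.3 homogeneous, 0.3–0.5 moderate, 0.5–2 well differentiated,
> 2 extreme.

Group assignment from coordinates chains individuals at < 100 m
(single linkage, strict inequality): two animals 160 m apart belong to one
group if a third stands between them.

## MRQAP

Off-diagonal dyads (n·(n−1) rows, 132 for 12 species) are fitted by OLS
with an intercept; coefficients and t values match any standard solver.
Inference uses double semi-partialing: each predictor's residuals (given
all others) are reshaped to a node × node matrix, rows and columns are
jointly permuted by a single node permutation (the defining QAP move —
dyad-level shuffles would destroy row/column dependence), the model is
refitted with the permuted matrix in place of the predictor, and the t
statistic is collected. p = (1 + #{|t*| ≥ |t|})/(1 + n_perm), so p is never
zero and its resolution is 1/(n_perm + 1). Coefficients are always the
unpermuted estimates. Internally the refit uses the Frisch–Waugh identity,
which makes 20 000 permutations per predictor a batched matrix product.

Backward selection starts from the full model (all four trait interactions
first) and repeatedly removes the highest-p term among those with p > 0.1
whose removal does not worsen AIC by more than 2, keeping main effects
while their interaction survives. The "does not worsen" direction matters:
removing one parameter can *lower* AIC by at most 2 (ΔAIC = 2 − t² at the
removed term), so demanding an AIC *drop* greater than 2 would make every
term irremovable; the implemented rule is the standard
retain-only-if-it-earns-its-keep reading. Each removal is logged
(term, p, AIC before/after) for audit, and the model is refitted and
re-permuted after every step.

Mass and group size are log-transformed, then every variable (trait vectors
and dyad layers alike) is min-max standardised to [0, 1] once, in the
design assembly; interactions are products of standardised values.
The alarm terms use the predator-summed index (the regression has a single
alarm term per role, not five).

## Synthetic community

The generator emulates the study design at its native scale: 12 herbivore
species (with literature-plausible masses, graze fractions, mean group
sizes, and two migratory species), 5 predators with realistic
abundance × meat-intake pressures, 66 censuses, 651 predator-simulation
trials, 2434 playbacks, 109 vigilance groups. All draws derive from a
single mandatory seed; every generator is a pure function of (spec, seed).

Planted structure and what recovery tests show:

- Trait means (V, per-predator A, dyadic R) are drawn with wide spreads so
  rank recovery is informative; alarm outcomes follow a logit model with
  distance decay and a young-present boost; playback responses load on one
  latent strength calibrated so PC1 explains ≈ 0.9 of the variance
  (a 0.8825 factor corrects the attenuation the binary presence column
  introduces).
- Mixed groups form by merging one group of each species in a pair with
  probability `mix_rate · kernel`, processed in random order (merges
  compete for groups; a fixed order would starve late dyads). The kernel
  uses three tiered background levels (0.05/0.14/0.25) plus one standout
  pair (impala–thomson's gazelle, 0.9): well-separated tiers keep dyad
  ranks identifiable from 66 censuses of Poisson-ish counts, where a
  continuous background with many near-identical values would not be.
- The kernel is a *group-level* merge rate; the affinity index weights by
  individual counts and corrects for gregariousness, so kernel recovery is
  measured against dyadic group co-occurrence counts (its direct
  estimand), while the standout pair is required to top the corrected
  network in a clear majority of replicates and sit in the top three
  almost always (see the structural note on the correction above).
- Group sizes are overdispersed negative-binomial around species means;
  coordinates, when emitted, place groups ≥ 300 m apart with individuals
  chained at < 100 m, so spatial clustering reproduces the group labels.

Not emulated: seasonality, migration dynamics, spatial landscape structure,
groups of more than two species, and any facilitative (rather than
competitive) resource interaction. Passing recovery tests therefore show
the estimators work under the planted statistical structure, not that real
communities satisfy that structure.

## Numerical conventions and edge cases

- Probability-like inputs are validated to [0, 1]; `c1 ≤ 0` or
  `C_tot ≤ 0` raise configuration errors (degenerate transforms).
- An empty predator set yields D = 0 with a warning.
- `Y`'s zero-denominator branch returns 1 (defined, not an error).
- Expected survival enumerates the size distribution's support exactly;
  distributions must sum to 1 within 1e−8.
- Dyadic layers carry NaN diagonals; regressions and exports mask
  non-finite entries.
- Both payoffs zero in a dyad → the directed split defaults to 50/50 with
  a warning; a zero gregariousness row sum makes the corrected index
  undefined (absent, warned) rather than infinite.
- Permutation seeds are mandatory; scan outputs are seed-free because the
  scan contains no randomness.

## Problem sizes used in validation

The test suite and the acceptance script run at desk scale: 10⁴ random
scenarios for the survival-model oracle, the full 162 × 1875 × 5 scan,
500 replicates × 1000 permutations for the MRQAP null calibration, one
synthetic community at study-scale effort per recovery statistic (three
replicate communities for the kernel ranks), and 2000 permutations for the
pipeline's regression table. These sizes keep Monte-Carlo error well below
the assertion margins while the whole suite runs in well under a minute of
compute per component.
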