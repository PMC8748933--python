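# Methods

This note documents the models, procedures and numerical choices behind
the package, the way a statistics library documents its estimators: what
each stage assumes, which knobs matter, and what the synthetic study
system does and does not emulate.

## The analysis pipeline

The package reimplements, end to end, a continental analysis of the
imprint that extinct Pleistocene megafauna left on woody-plant
antiherbivory traits. Its unit of analysis is the **ecoregion**; its
stages run in a fixed order:

1. trait scaling (species records → ecoregion trait values),
2. fauna metrics (presence grids → assemblage indicators),
3. disturbance metrics (fire hotspots, hurricane tracks),
4. regression protocol per trait,
5. matrix-randomization robustness test,
6. antiherbiome clustering (PCA + Ward),
7. biome-shift classification + fossil validation.

### Trait scaling

Species records collapse to one value per species and trait: arithmetic
mean for the continuous traits (wood density, g/cm³; leaf size), maximum
for the binary ones (stem spines, leaf spines, latex) — a recorded
presence is trusted over an omission because overlooking spines or latex
is far likelier than inventing them.

Ecoregion values follow three aggregation paths, all restricted to the
species with a value for the trait in question (missing values are
dropped per trait, never imputed — real databases cover different
species subsets per trait):

- **continuous**: per grid cell, the community-weighted mean
  Σ(abundance × value)/Σ(abundance); per ecoregion, the unweighted mean
  over its cells. Cells with no covered abundance are excluded; an
  ecoregion with none is missing. Cell averaging is unweighted by cell
  abundance; a config switch is not offered because the single-cell path
  is proven identical to the pooled path in tests.
- **stem spines / latex**: presences = Σ(abundance × indicator),
  absences = covered abundance − presences. These integer pairs are the
  binomial response counts downstream.
- **leaf spines** (palms only): abundance is collapsed to species
  presence/absence first, because the occurrence signal for the small
  palm species pool is too unreliable to weight by. Non-palm species are
  excluded with a logged count.

### Fauna metrics

The megafauna subset keeps prehistorically extinct species (status
"EP"), body mass **strictly above 50 kg**, and ≥ 90 % plant diet. The
extant subset keeps extant strict herbivores that feed mainly on
above-ground vegetative tissue, with **no** size threshold (few extant
Neotropical herbivores exceed 50 kg; the body-mass metric carries the
size signal instead).

Every indicator is computed per grid cell and averaged over the
ecoregion's cells: richness (overall and per diet guild — species with
unknown diet count toward overall richness but no guild), mean body
mass (cells with no species are excluded from the mean: the mean of an
empty set is undefined), and the grazer-minus-browser richness
difference (MGB_dif / HGB_dif) used as the diet axis because per-guild
richnesses are too collinear to enter one model. An allometric density
index (c·mass^b per species, Damuth-type b = −0.75 by default) is
provided only as a correlation diagnostic against richness; the
coefficients stay user-supplied because no canonical values are pinned
here.

### Disturbance

Fire hotspots are kept when detection confidence ≥ 95 %, the date falls
in November 2000 – December 2019 (inclusive), and at most 10 % of the
land-cover cells within a 1000 m Euclidean buffer of the hotspot are
agricultural, urban or water. Buffer membership is cell-centre distance
on the lattice — reproducible without projection machinery. The
per-ecoregion fire rate is count/area × vegetated proportion; fire
intensity is the mean fire radiative power; hurricane activity is
six-hourly track points per km². Ecoregions whose vegetated proportion
falls below 0.5 are flagged excluded ("lacking large preserved
vegetated areas" — the source criterion is qualitative; 0.5 is this
package's operationalization, config-exposed). The "other" land-cover
class counts as neither anthropogenic nor vegetated by default.

### Regression protocol

Predictors are z-scored. Candidate sets hold the fauna indicators
(M_rich, M_bm, MGB_dif, H_rich, H_bm, HGB_dif), climate (MAT, MAR or
pH, RS), soil (CEC, SND), fire (FI), and — for wood density only —
hurricane counts. Stem-spine models always carry quadratic body-mass
terms (squared z-scores; mid-size herbivores select for spines).

1. **Screen**: pairs with |r| ≥ 0.60 may not co-occur. MAR and pH (r ≈
   −0.78 by construction) split selection into two branches; the winner
   is the branch with the lower AIC (ΔAIC recorded; > 2 in practice).
2. **Stepwise AIC**: bidirectional search from the full model
   (gaussian AIC on the least-squares likelihood; binomial AIC on the
   unit-weight likelihood), respecting the quadratic hierarchy (a
   squared term never without its linear term).
3. **Significance pruning**: drop the least significant term until all
   p ≤ 0.05.
4. **Sign discard**: a significant herbivory coefficient whose sign
   implies *less* defence under *more* herbivory (for leaf size, the
   defended state is *small*) is discarded together with its quadratic,
   and selection re-runs without it.
5. **Overdispersion** (binomial): Williams-type weights
   w_i = 1/(1 + φ(n_i − 1)), φ found by bracketing + bisection until the
   weighted residual deviance falls below the residual df. With no
   overdispersion φ = 0 and the fit is the plain logit; with equal trial
   counts the weights are constant, so coefficients are unchanged and
   only the inference scales.
6. **Diagnostics**: KS on standardized residuals against N(0, 1) (the
   estimated-parameter caveat is noted in the output), Breusch–Pagan,
   and Moran's I over the ecoregion adjacency graph using the analytic
   normal approximation (binary symmetric weights; a disconnected graph
   is reduced to its largest component and flagged). If BP rejects at
   0.05, coefficient tests are redone under an HC3 covariance and the
   pruning loop re-entered. VIF = 1/(1 − R²_j) is asserted ≤ 3.33 for
   every selected predictor; the pipeline resolves a violation by
   dropping the worst-inflated predictor from the candidates and
   re-selecting.
7. **Effect sizes**: per-coefficient Pearson r = t/√(t² + df), i.e. the
   partial correlation; the 95 % CI uses the Fisher z transform with
   standard error 1/√(df − 1). t-based rather than bootstrap — the
   choice is noted because the source protocol does not state one.
8. **Dominance analysis**: general dominance — the gain in fit
   statistic from adding a predictor, averaged over subsets of the other
   selected predictors within each subset size and then across sizes.
   Plain R² for gaussian models (contributions then sum exactly to the
   full-model R², a property the tests assert at 1e-8) and McFadden's
   pseudo-R² for binomial models, the statistic most comparable to R².
   Subset enumeration is capped at 12 predictors. The *reported* fit
   statistic is adjusted R² (gaussian) or McFadden (binomial).

Two-sided p-values throughout.

### Randomization test

Observed coefficients are compared against coefficients re-estimated on
randomized species-abundance matrices, the selected formula held fixed
(re-selection per replicate is not the default: the comparison is of
*the original coefficient values* to re-estimates). Default scheme:
independent permutation of each species' abundances across ecoregions,
which severs trait geography from ecoregion identity while preserving
every species' prevalence; row-shuffle and fixed-marginal 2×2-swap
schemes are available and recorded in the output. The verdict per
coefficient is "outside band" iff the observed value falls below the
0.05 or above the 0.95 quantile of the replicate values — a two-sided
0.10 test, so on null data the flag rate is 10 % by construction (the
tests measure 10 ± 3 % over 500 null worlds). Replicates whose refit
fails are dropped and counted; more than 5 % failures aborts.

### Antiherbiomes

The defence matrix holds, per ecoregion: wood density, leaf size, and
the proportions of spiny-stemmed plants, spiny-leaved palm species and
latex-bearing plants; binary proportions come from the count pairs.
Ecoregions without palms get their leaf-spine proportion from the
fitted leaf-spine model's predicted probability (fills are logged);
rows still incomplete are excluded. Columns are standardized to zero
mean, unit variance.

PCA is the eigendecomposition of the resulting correlation structure.
Signs are pinned deterministically (axis 1 loads positively on stem
spines — the physical-defence pole; other axes make their largest
loading positive). All five components feed the clustering by default
(the retained-axis count is config-exposed; the source procedure does
not state a cut).

Ward clustering runs on the component scores. The cluster count k
maximizes D(k)/D(k+1), where D(k) = W(k−1) − W(k) is the inertia gain
of refining to k groups — the partition after which further splits stop
paying. A plain argmax of the inertia loss itself always elects k = 2
on three-cluster data (the first split removes the most inertia), which
is why the ratio form is used; a maximal ratio below 2 logs a
weak-structure warning. Ties go to the lower k. Cluster *names* (SLT:
small leaves + stem spines; ILW: high wood density; BCL: large leaves +
latex) are assigned by matching cluster trait profiles to these
archetypes via optimal assignment — indices are permutation-arbitrary,
profiles are not.

Group contrasts use Kruskal–Wallis plus pairwise Dunn z tests
(tie-corrected) with Benjamini–Hochberg correction across each
variable's pairs; groups under 2 members are excluded and flagged.

### Biome shifts

Richness thresholds are the nearest-rank (type-1) 0.75 quantiles of
M_rich and MG_rich over non-insular ecoregions — nearest-rank so the
thresholds are reproducible integers on integer-valued distributions.
An ecoregion is a savanna-to-forest **shift** when it is currently
forest-dominated (moist vs dry read from the biome label), belongs to
the SLT or ILW antiherbiome, and passes both thresholds; a **stable
savanna** when currently savanna-dominated with the same fauna
criteria. Manual overrides (e.g. a savanna one species short of the
megafauna threshold) are applied last and quoted verbatim in the rule
trace; every classification is reproducible from its trace alone.

A fossil site with evidence of past savanna supports the shift
hypothesis iff its current local vegetation is forest and it lies
inside — or adjacent to ("vicinity" is operationalized as shared
ecoregion boundary; no distance is stated at the source) — a
shift-classified ecoregion.

## The synthetic world

The generator produces the complete study system with known ground
truth. Defaults are the study conditions: 179 ecoregions (16 cells of
96.5 km each), ~16 % insular, 1000 woody plant species (20 % palms), 66
extinct megafauna (diet guilds 22 browsers / 16 grazers / 15 mixed, the
rest unknown) plus 120 extant species, MAR–pH sample correlation
exactly −0.78 (residualized-Gaussian construction, so the target holds
at any n ≥ 10), shift-rule quantile 0.75, and the planted standardized
trait slopes listed in `default_effect_sizes()`.

Structural choices, and why:

- **Abundance**: negative-binomial counts (occurrence-record counts are
  overdispersed), with each species holding a "home" ecoregion where
  its mean abundance dominates (60 vs 0.05 background). Community
  means therefore track the home ecoregion's planted expectation.
  Homes are **i.i.d. uniform** across ecoregions — this makes every
  abundance column exchangeable, which in turn makes the
  matrix-randomization null exactly calibrated. (A balanced one-home-
  per-ecoregion assignment, tried first, broke exchangeability and
  inflated the null flag rate to ~0.19.)
- **Traits**: the ecoregion-level expectation is
  archetype offset (three antiherbiome trait profiles, scaled by
  `cluster_separation`) + Σ β·z(predictor); species values add noise
  (continuous traits through clipped-linear or log links, binary traits
  through a logit link).
- **Fauna**: occupancy is logistic in the covariates; extinct and
  extant pools use different gradient sets so their richness indicators
  are only weakly correlated (as in the study system — otherwise
  selection cannot attribute effects). Grazers are pulled toward open
  (dry, alkaline) ecoregions; islands carry a −2 logit penalty.
- **Planted shift set**: ecoregions whose planted antiherbiome is
  SLT/ILW and whose generated fauna passes the 0.75-quantile rule are
  split at random between present-day forest (true shifts) and savanna
  (stable savannas); fossil sites are then placed 13 inside / 3
  adjacent / 6 stable by default, so the validator's expected summary
  is 16 of 22 supporting.
- One RNG stream per component (covariates, fauna, occurrences,
  biomes, hotspots, tracks, sites): regenerating one leaves the others
  bit-identical, and a fixed seed fixes the world bit-exactly.

What the generator does **not** emulate: real spatial autocorrelation
ranges or coastlines (lattice geometry only), taxonomic structure,
sampling-effort gradients in occurrence data, and any correlation
between abundance and traits beyond the home-ecoregion mechanism.
Passing tests therefore demonstrate correctness and calibration of the
*procedures* under a controlled data-generating process, not the
robustness of the scientific conclusions to real-data pathologies.

## Problem sizes used in the test suite

The suite exercises the stated study sizes where the property depends
on them: null calibration over 500 worlds of 150 ecoregions at 200
randomization replicates; planted-effect recovery (β = 0.5,
megafauna-richness → wood density) over 100 seeds at n = 143
ecoregions; cluster recovery over 100 seeds of 90 points; aggregation
oracles over 200 random fixtures. The acceptance script runs the full
pipeline at the default 179-ecoregion world with 200 randomization
replicates per model and one dedicated recovery run at n = 143.

## Known limitations

- The binomial branch of the randomization test refits the Williams
  weighting per replicate, which is exact but slow; gaussian responses
  use a vectorized least-squares path.
- The KS normality test is applied with estimated parameters (noted in
  every diagnostics record); its p-values are conservative.
- Dominance analysis enumerates 2^k subsets and is capped at k = 12.
- With very small species pools the leaf-spine (palm) proportion is
  dominated by presence noise; the corresponding PCA axis then carries
  little structure — mirroring the weakness of that trait in real data.
- The exact randomization scheme of the source protocol is not public;
  the default here is config-pinned and recorded in every output.
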