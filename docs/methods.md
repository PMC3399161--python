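# Methods

## Problem and data model

The package analyses sympatric stands of two cattail species and their
hybrids. The sampling unit is the ramet (one shoot); each ramet carries
a codominant multilocus genotype at six SSR loci (unordered pairs of
integer fragment sizes, stored sorted ascending; missing = `None`,
serialised as `0` per the GenAlEx convention), a site ID, a shoot
elevation in integer millimetres (raw laser-rangefinder scale) and a
shoot height in cm (longest leaf). Elevation is treated as a within-site
proxy for water depth. Allele identity is the integer fragment size; no
binning is applied — sizing is assumed done upstream.

Tables are exchanged in a GenAlEx-style CSV (two header rows of
counts/title, then two allele columns per locus) or a plain long CSV;
both round-trip bit-exactly. Ramets that did not amplify at every locus
are removed before analysis (`drop_incomplete`), and unparseable allele
tokens become missing calls that are counted, never silently coerced.

## Species and hybrid classification

The diagnostic key lists, per locus, the alleles private to each
parental species (species A = *T. latifolia*, B = *T. angustifolia*).
The key is an input, not hard-coded; the simulator emits a matching key
with each synthetic dataset. Each locus scores AA, BB, AB, or ambiguous
(any allele absent from the key); the ramet-level call is then a
deterministic function of the six-locus evidence vector: pure A iff all
AA, pure B iff all BB, F1 iff all AB, later-generation hybrid for any
other ambiguity-free mixture, unresolved if any locus is ambiguous.
Unresolved is a category, not an error: real keys can miss rare
alleles, and surfacing those ramets is safer than pooling them with
later-generation hybrids. Later-generation classes (backcrosses,
advanced intercrosses) are pooled; the per-locus evidence is retained
so users can subdivide.

### Ordination corroboration

A model-free check ordinates the pairwise squared codominant genotypic
distances. Per locus the squared distance depends only on the
allele-sharing pattern (0 for identical pairs, 1 for one shared allele
or homozygote-vs-containing-heterozygote, 2 for disjoint heterozygotes,
3 for a homozygote vs a disjoint heterozygote, 4 for disjoint
homozygotes), summed over loci. Classical principal-coordinates
analysis (Gower double-centering of −D²/2, symmetric
eigen-decomposition, coordinates = eigenvectors × √eigenvalues) yields
axes whose variance fractions are shares of the positive-eigenvalue
total. Eigenvector sign is arbitrary, so axis 1 is oriented to place
the pure-A mean below zero; concordance is then the fraction of pure-A
ramets below −t, pure-B above +t and F1 within ±t for a user threshold
t (default 0.4). The implementation is checked in the test suite
against an independent double-centering oracle and against
scikit-bio's PCoA.

## Clonal genet inference

The distance between two complete genotypes is the number of allele
copies not matchable within loci (per-locus multiset difference, summed;
0–12 for six diploid loci). "Same genet" means distance ≤ 1 — a single
mis-called allele copy should not split a clone. Design choices:

* **Transitive closure.** Ramets are nodes, distance ≤ threshold makes
  an edge, genets are connected components (networkx). Any
  non-transitive rule would make the partition depend on input order;
  components keep it order-invariant, and genet IDs (site plus lowest
  member ramet ID) are canonical for a given partition.
* **Site-scoped.** Genets never span sites; the rule is a repair for
  within-population genotyping error, not a dispersal model.
* **All ramets of a site are eligible**, regardless of species call.
  With fully diagnostic loci a parental ramet and an F1 are at distance
  ≥ 6, so the choice is inconsequential there, but it matters when loci
  are ambiguous; clustering before classification avoids conditioning
  the partition on the key.

Genotypic richness per species per site is R = (G − 1)/(n − 1), with
G the inferred genet count among the n ramets of that species at that
site. R is 0 for a monoclonal sample and 1 when all ramets are
distinct; for n = 1 the statistic is undefined and carried as NaN
(excluded from across-site means). Species summaries are unweighted
means across sites with SE = sample SD/√(number of sites).

## Niche-segregation analyses

**Standardization.** Standardized elevation = raw elevation − site
median, computed on the integer-mm scale (so centering is exact and
bit-for-bit translation-invariant) and reported in cm. All ramets of a
site contribute to the median, before any filtering by species.
Later-generation and unresolved ramets are excluded from the three
inferential analyses below, not from standardization.

**Elevation LMM.** Standardized elevation ~ species + shoot height,
with random intercepts for site and genet-nested-in-site, fitted by
REML (statsmodels `MixedLM`; site as the grouping factor, genets as a
variance component). A raw-elevation response is available by flag.
The species term is tested with a Wald chi-square rescaled to an F.
Denominator degrees of freedom follow the containment convention by
default: species is constant within genets, so df = genets − sites −
(number of species contrasts); the height covariate varies within
genets, so df = observations − genets − 1. A `residual` convention
(observations − fixed parameters) is available; no convention is
canonical for REML Wald tests, and calibration simulations in the
acceptance suite show the default attains nominal type-I error at
survey scale. With the standardized response the site variance
component is legitimately near zero, so boundary ("singular") fits are
flagged in the result rather than treated as failures. Adjusted
species means are evaluated at the mean height.

**Richness GLMM.** G successes of n trials ~ species with a site
random intercept, binomial-logit. Rows are expanded to Bernoulli
observations (identical likelihood, simpler contract) and fitted with
statsmodels' variational-Bayes binomial mixed GLM; posterior mean/SD
serve as estimate/SE for a Wald Z per contrast against the reference
species (*T. angustifolia*). The VB optimizer's start values are drawn
from a pinned RNG so identical inputs give identical fits. With a
single site the model reduces to an ordinary binomial GLM. Estimates
with |β| > 10 flag possible complete separation.

**KS comparisons.** The two-sample statistic D = max |ECDF_x −
ECDF_y| is evaluated over the pooled sample points; the p-value uses
the asymptotic Kolmogorov distribution with the standard
√(mn/(m+n)) + 0.12 + 0.11/√(mn/(m+n)) correction. Ties across samples
trigger a warning (mm-scale elevations make them rare); no tie
correction is applied. scipy's implementation is used only as an
independent oracle in the tests.

No multiple-testing correction is applied; the report prints raw
p-values for the default comparisons (pure A vs pure B, pure A vs F1).

## Synthetic communities

The generator draws, per site: a site elevation effect ~ N(0,
site SD); genets lineage-first from the mixture (pure A, pure B, F1,
later-generation); each genet a genotype, an elevation offset ~ N(0,
genet SD) and a ramet count 1 + Poisson(clonality − 1), truncated at
the site's target size; then per ramet a residual ~ N(0, residual SD)
and a height from a linear model on within-site elevation. Pure
genotypes are two draws from the species' pool per locus, F1s one from
each, later-generation hybrids first-generation backcrosses (per locus
50/50 heterospecific vs parental pattern) — deeper pedigrees are
indistinguishable under a private-allele key and would add no testable
structure. Genotyping error replaces each observed allele copy, with
probability e, by another allele of the locus pool; truth labels are
kept untouched. Allele pools give each species a configurable number
of private alleles per locus (sizes stepping 2 bp), optional shared
alleles, and flat-Dirichlet frequencies. All randomness flows from the
config seed; identical configs give bit-identical output.

### Survey-scale preset (defaults)

| parameter | value | rationale |
|---|---|---|
| sites × ramets | 18 × 15 (270) | field-survey scale of the motivating system |
| loci | TA3 TA5 TA7 TA8 TA16 TA20 | standard six-locus Typha panel |
| private alleles/species/locus | 4, no shared | the real key is fully diagnostic at these loci |
| lineage mixture | 0.25 / 0.20 / 0.52 / 0.03 | F1 most common; later-generation hybrids rare (~3%) |
| clonality | 3 ramets/genet | puts per-species R in the observed 0.1–0.3 band |
| genotyping error | 0.005/allele copy | occasional single-allele mis-calls |
| elevation | site SD 25, offsets −2.6 / −2.0 / +1.2, genet SD 4, residual SD 6 cm | small species offsets of the magnitude reported for such stands; within-site spread dominated by genet + residual |
| height | 150 cm, slope 0, noise 25 | height uncorrelated with elevation by default |

What the generator does **not** emulate: spatial transect geometry and
autocorrelation, seasonal water-depth dynamics, allele-size
homoplasy/binning error, null alleles, and population structure within
species. Passing tests therefore demonstrate correctness of the
inference machinery under the assumed hierarchical model, not
robustness to those field complications.

## Validation design

Tests pair every non-trivial operation with an independent oracle:
classification against a brute-force rule table over all 4⁶ evidence
patterns; genet inference against all-pairs union-find on random ≤12
ramet instances; PCoA against a naive centering-matrix
eigendecomposition and scikit-bio; the KS statistic against an
exhaustive ECDF scan and scipy; the LMM against OLS in the
zero-variance limit and against R's nlme on an identical frame.
Statistical calibration uses 200-replicate simulations at the preset
scale: the species F-test's null rejection rate must lie inside the
binomial 95% band around 0.05, power at ±5 cm offsets (residual SD
2 cm) must exceed 0.95, and the diversity GLMM must recover the sign of
a 0.30-vs-0.15 genet-fraction contrast in >90% of replicates. These
replicate counts keep the full suite within a few minutes while leaving
Monte-Carlo error well below the margins being asserted.

## Known limitations

* The later-generation category is a pooled class; the package does not
  attempt model-based hybrid-class posteriors (NewHybrids-style).
* The binomial GLMM is a variational approximation; its SEs are
  posterior SDs under weak priors, adequate for sign/contrast tests at
  survey scale but not a substitute for a likelihood-ratio analysis.
* F-test denominator df in REML mixed models is convention, not truth;
  both available conventions are approximations.
* With very small allele pools, distinct genets can coincide in
  genotype and be merged; the probability is negligible at the preset's
  pool sizes but grows as pools shrink.
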