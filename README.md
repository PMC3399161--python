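# hybridzone

Microsatellite-based analysis of plant hybrid zones with clonal growth,
built around the North American cattail complex: broad-leaved cattail
(*Typha latifolia*), narrow-leaved cattail (*T. angustifolia*) and their
hybrid *T. × glauca*. Given a ramet-level table of codominant SSR
genotypes (six loci, two integer allele sizes each) plus site, shoot
elevation and shoot height, the package:

1. **classifies** each ramet as pure parent, F1 or later-generation
   hybrid from *private diagnostic alleles* — a ramet with one allele
   from each species at every locus is an F1 — and corroborates the
   calls with a principal-coordinates ordination of codominant
   genotypic distances (the Smouse–Peakall metric);
2. **infers clonal genets** by merging ramets of the same site whose
   multilocus genotypes differ by at most one allele copy (a tolerance
   that compensates for genotyping error), via transitive closure;
3. computes **genotypic richness** per species per site,

   R = (G − 1) / (n − 1),

   where G is the number of distinct genets among n ramets (0 =
   monoclonal, 1 = all distinct);
4. tests for **elevation niche segregation**: shoot elevations are
   standardized by each site's median (elevation is a within-site proxy
   for water depth), then compared across species with a REML linear
   mixed model (species fixed effect, shoot-height covariate, random
   intercepts for site and genet-within-site), a binomial-logit mixed
   model of G-of-n clonal diversity, and two-sample
   Kolmogorov–Smirnov tests.

A fully seeded **synthetic hybrid-zone generator** produces communities
with known truth (lineages, genets, elevation effects) at field-survey
scale — 18 sites, ~270 ramets — for validation and power analysis.

## Worked example

```python
from hybridzone import (
    paper_scale_preset, simulate_community_with_key, drop_incomplete,
    classify_collection, lineage_frequencies, infer_genets,
    richness_by_species_site, fit_elevation_lmm,
)

collection, truth, key = simulate_community_with_key(paper_scale_preset(42))
collection, _ = drop_incomplete(collection)
classify_collection(collection, key)
print(lineage_frequencies(collection)["count"].to_dict())
genets = infer_genets(collection, max_mismatch=1)
table, summary = richness_by_species_site(collection, genets)
lmm = fit_elevation_lmm(collection)
st = lmm.species_test
print(f"species: F({st.df_num},{st.df_den}) = {st.F:.2f}, P = {st.p:.2f}")
```

prints

```
{'pure_A': 62, 'pure_B': 59, 'F1': 126, 'later_gen': 23, 'unresolved': 0}
species: F(2,77) = 3.14, P = 0.05
```

The frequency table shows the classified community (F1 hybrids most
common, a handful of apparent backcrosses — some of them pure or F1
plants whose genotype carries a simulated scoring error). The F-test
asks whether the three lineages sit at different median-centred
elevations once site and clone structure are absorbed by random
effects; at P ≈ 0.05 there is at best weak evidence of segregation.
Running exact-match clone inference versus the one-allele tolerance on
the same community gives 122 versus 103 genets — the difference is the
clones that scoring errors would otherwise split.

The `examples/` directory holds one short script per capability
(simulation, classification + ordination, genets + richness, niche
tests, full pipeline). A thin CLI wraps the same functions:
`hybridzone simulate|classify|genets|ordinate|analyze|run`.

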