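"""Infer clonal genets with error tolerance and compute genotypic richness.

Ramets from the same site whose genotypes differ by at most one allele
copy are merged into one genet (a single mis-called allele should not
split a clone). Genotypic richness R = (G - 1)/(n - 1) summarises clonal
diversity: 0 = monoclonal stand, 1 = every ramet genetically distinct.
"""

from hybridzone import (
    classify_collection,
    drop_incomplete,
    infer_genets,
    paper_scale_preset,
    richness_by_species_site,
    simulate_community_with_key,
)

collection, truth, key = simulate_community_with_key(paper_scale_preset(42))
collection, _ = drop_incomplete(collection)
classify_collection(collection, key)

strict = infer_genets(collection, max_mismatch=0)
tolerant = infer_genets(collection, max_mismatch=1)
print(
    f"genets: {strict.n_genets} (exact matching) -> "
    f"{tolerant.n_genets} (one-allele tolerance), "
    f"true: {truth.frame['genet_id'].nunique()}"
)

table, summary = richness_by_species_site(collection, tolerant)
print("\nper-species genotypic richness (mean ± SE across sites):")
for _, row in summary.iterrows():
    print(
        f"  {row['species']:8s} R = {row['mean_R']:.2f} ± "
        f"{row['se_R']:.2f} ({row['n_sites']} sites)"
    )
# The drop from exact matching to one-allele tolerance is the number of
# genets that genotyping errors would otherwise have split.
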