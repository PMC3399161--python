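"""Genet inference with genotyping-error tolerance, and genotypic richness."""

import itertools
import math
import random

import numpy as np
import pytest

from hybridzone import (
    DEFAULT_LOCI,
    Lineage,
    MultilocusGenotype,
    StudyCollection,
    allele_mismatch_distance,
    classify_collection,
    genet_richness,
    infer_genets,
    richness_by_species_site,
)


def matching_distance_oracle(g1, g2):
    """Independent distance: per locus, min mismatches over allele matchings."""
    total = 0
    for locus in g1.loci:
        (a1, a2), (b1, b2) = g1.call(locus), g2.call(locus)
        total += min(
            (a1 != b1) + (a2 != b2),
            (a1 != b2) + (a2 != b1),
        )
    return total


def union_find_oracle(records, max_mismatch):
    """Brute-force partition: all-pairs distances + union-find, per site."""
    parent = {r.ramet_id: r.ramet_id for r in records}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for r1, r2 in itertools.combinations(records, 2):
        if r1.site_id != r2.site_id:
            continue
        if allele_mismatch_distance(r1.genotype, r2.genotype) <= max_mismatch:
            parent[find(r1.ramet_id)] = find(r2.ramet_id)
    groups = {}
    for r in records:
        groups.setdefault(find(r.ramet_id), set()).add(r.ramet_id)
    return {frozenset(g) for g in groups.values()}


def random_instance(rng, n_max=12, n_sites=2, alleles=(101, 103, 105)):
    recs = []
    from hybridzone import RametRecord

    n = rng.randint(2, n_max)
    for i in range(n):
        calls = {
            l: tuple(sorted(rng.choices(alleles, k=2))) for l in DEFAULT_LOCI
        }
        recs.append(
            RametRecord(
                ramet_id=f"r{i:02d}",
                site_id=f"s{rng.randint(1, n_sites)}",
                elevation_mm=0,
                shoot_height_cm=1.0,
                genotype=MultilocusGenotype(calls),
            )
        )
    return StudyCollection(recs)


class TestDistance:
    def test_identical_genotypes_distance_zero(self, make_genotype):
        g = make_genotype((101, 103))
        assert allele_mismatch_distance(g, g) == 0

    def test_single_allele_difference(self, make_genotype):
        g1 = make_genotype((101, 103))
        per_locus = {l: (101, 103) for l in DEFAULT_LOCI}
        per_locus["TA3"] = (101, 105)
        g2 = make_genotype(per_locus=per_locus)
        assert allele_mismatch_distance(g1, g2) == 1

    def test_disjoint_pair_at_one_locus(self, make_genotype):
        per1 = {l: (101, 103) for l in DEFAULT_LOCI}
        per2 = dict(per1)
        per1["TA5"] = (101, 105)
        per2["TA5"] = (103, 107)
        g1 = make_genotype(per_locus=per1)
        g2 = make_genotype(per_locus=per2)
        assert allele_mismatch_distance(g1, g2) == 2

    def test_differing_locus_sets_rejected(self, make_genotype):
        g1 = make_genotype((101, 103))
        g2 = MultilocusGenotype({"TA3": (101, 103)})
        with pytest.raises(ValueError, match="locus sets"):
            allele_mismatch_distance(g1, g2)

    def test_matches_matching_oracle_on_random_genotypes(self):
        rng = random.Random(42)
        alleles = (101, 103, 105, 107)
        for _ in range(300):
            g1 = MultilocusGenotype(
                {
                    l: tuple(sorted(rng.choices(alleles, k=2)))
                    for l in DEFAULT_LOCI
                }
            )
            g2 = MultilocusGenotype(
                {
                    l: tuple(sorted(rng.choices(alleles, k=2)))
                    for l in DEFAULT_LOCI
                }
            )
            expected = matching_distance_oracle(g1, g2)
            assert allele_mismatch_distance(g1, g2) == expected
            assert allele_mismatch_distance(g2, g1) == expected


class TestInferGenets:
    def test_identical_ramets_form_one_genet(self, make_ramet):
        col = StudyCollection(
            [make_ramet(f"r{i}", (101, 103)) for i in range(5)]
        )
        assert infer_genets(col).n_genets == 1

    def test_zero_mismatch_gives_exact_classes(self, make_ramet):
        base = {l: (101, 103) for l in DEFAULT_LOCI}
        near = dict(base, TA3=(101, 105))  # distance 1 from base
        col = StudyCollection(
            [
                make_ramet("r1", per_locus=base),
                make_ramet("r2", per_locus=base),
                make_ramet("r3", per_locus=near),
            ]
        )
        assert infer_genets(col, max_mismatch=0).n_genets == 2
        assert infer_genets(col, max_mismatch=1).n_genets == 1

    def test_transitive_chain_merges(self, make_ramet):
        # A-B distance 1, B-C distance 1, A-C distance 2
        pa = {l: (101, 103) for l in DEFAULT_LOCI}
        pb = dict(pa, TA3=(101, 105))
        pc = dict(pa, TA3=(105, 107))
        col = StudyCollection(
            [
                make_ramet("A", per_locus=pa),
                make_ramet("B", per_locus=pb),
                make_ramet("C", per_locus=pc),
            ]
        )
        gA = col.records[0].genotype
        gB = col.records[1].genotype
        gC = col.records[2].genotype
        assert allele_mismatch_distance(gA, gB) == 1
        assert allele_mismatch_distance(gB, gC) == 1
        assert allele_mismatch_distance(gA, gC) == 2
        assignment = infer_genets(col, max_mismatch=1)
        assert assignment.n_genets == 1
        assert assignment.as_partition() == {frozenset({"A", "B", "C"})}

    def test_genets_never_span_sites(self, make_ramet):
        col = StudyCollection(
            [
                make_ramet("r1", (101, 103), site="s1"),
                make_ramet("r2", (101, 103), site="s2"),
            ]
        )
        assignment = infer_genets(col)
        assert assignment.n_genets == 2

    def test_partition_invariant_to_shuffling(self):
        rng = random.Random(7)
        for _ in range(20):
            col = random_instance(rng)
            base = infer_genets(col, max_mismatch=1)
            shuffled = list(col.records)
            rng.shuffle(shuffled)
            other = infer_genets(
                StudyCollection(shuffled, col.loci), max_mismatch=1
            )
            assert base.genet_of == other.genet_of

    def test_genet_count_non_increasing_in_mismatch(self):
        rng = random.Random(11)
        for _ in range(20):
            col = random_instance(rng)
            counts = [
                infer_genets(col, max_mismatch=m).n_genets for m in range(4)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_matches_union_find_oracle(self):
        rng = random.Random(3)
        for _ in range(100):
            col = random_instance(rng)
            m = rng.randint(0, 2)
            assert (
                infer_genets(col, max_mismatch=m).as_partition()
                == union_find_oracle(col.records, m)
            )

    def test_negative_mismatch_rejected(self, make_ramet):
        col = StudyCollection([make_ramet("r1", (101, 103))])
        with pytest.raises(ValueError, match="max_mismatch"):
            infer_genets(col, max_mismatch=-1)


class TestRichness:
    @pytest.mark.parametrize(
        "G,n,expected",
        [(1, 10, 0.0), (10, 10, 1.0), (5, 9, 0.5), (2, 2, 1.0), (1, 2, 0.0)],
    )
    def test_endpoint_and_interior_values(self, G, n, expected):
        assert genet_richness(G, n) == expected

    def test_single_ramet_undefined(self):
        assert math.isnan(genet_richness(1, 1))

    @pytest.mark.parametrize("G,n", [(0, 5), (6, 5), (-1, 3)])
    def test_domain_errors(self, G, n):
        with pytest.raises(ValueError):
            genet_richness(G, n)


class TestRichnessBySpeciesSite:
    def test_single_site_single_genet(self, make_ramet, simple_key):
        col = StudyCollection(
            [make_ramet(f"r{i}", (11, 21)) for i in range(5)]
        )
        classify_collection(col, simple_key)
        genets = infer_genets(col)
        table, summary = richness_by_species_site(col, genets)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["species"], row["G"], row["n"], row["R"]) == (
            "F1",
            1,
            5,
            0.0,
        )

    def test_absent_species_has_no_row(self, make_ramet, simple_key):
        col = StudyCollection(
            [make_ramet(f"r{i}", (11, 13)) for i in range(3)]
        )
        classify_collection(col, simple_key)
        genets = infer_genets(col)
        table, summary = richness_by_species_site(col, genets)
        assert set(table["species"]) == {"pure_A"}
        assert summary.loc[
            summary["species"] == "pure_B", "n_sites"
        ].iloc[0] == 0

    def test_per_site_G_matches_truth_without_errors(
        self, errorfree_community
    ):
        collection, truth, _, _, genets = errorfree_community
        table, _ = richness_by_species_site(collection, genets)
        truth_frame = truth.frame.merge(
            collection.to_dataframe()[["ramet_id", "species"]], on="ramet_id"
        )
        for _, row in table.iterrows():
            mask = (truth_frame["site_id"] == row["site_id"]) & (
                truth_frame["species"] == row["species"]
            )
            assert truth_frame.loc[mask, "genet_id"].nunique() == row["G"]

    def test_invariants_G_le_n(self, errorfree_community):
        collection, _, _, _, genets = errorfree_community
        table, _ = richness_by_species_site(collection, genets)
        assert ((table["G"] >= 1) & (table["G"] <= table["n"])).all()
        defined = table["n"] > 1
        assert (
            table.loc[defined, "R"]
            == (table.loc[defined, "G"] - 1) / (table.loc[defined, "n"] - 1)
        ).all()
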