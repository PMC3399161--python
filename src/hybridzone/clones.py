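"""Clonal genet inference and genotypic richness.

Clonal plants replicate vegetatively, so several sampled shoots (ramets)
may belong to one genetic individual (genet). Exact genotype matching
over-splits genets whenever a single allele is mis-called, so ramets from
the same site whose multilocus genotypes differ by at most one allele copy
are merged into one genet; chains are merged transitively (connected
components), keeping the partition order-independent. Genets never span
sites.

Genotypic richness for a sample of n ramets containing G distinct genets
is R = (G − 1)/(n − 1): 0 when the sample is monoclonal, 1 when every
ramet is a distinct genet. R is undefined (NaN) for n = 1.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .classify import Lineage, SpeciesCall
from .genotypes import MultilocusGenotype, StudyCollection

logger = logging.getLogger(__name__)

#: Reported per-species categories (later-generation hybrids are rare and
#: excluded from species-level comparisons).
SPECIES_CATEGORIES: tuple[Lineage, ...] = (
    Lineage.PURE_A,
    Lineage.PURE_B,
    Lineage.F1,
)


def allele_mismatch_distance(
    g1: MultilocusGenotype, g2: MultilocusGenotype
) -> int:
    """Number of allele copies that differ between two complete genotypes.

    Per locus, the two unordered pairs are matched as multisets and the
    unmatched copies counted; summed over loci this is symmetric and
    ranges 0–12 for six diploid loci. Two genotypes "differing by only
    one allele" are at distance 1.
    """
    if set(g1.loci) != set(g2.loci):
        raise ValueError("genotypes cover different locus sets")
    total = 0
    for locus in g1.loci:
        p1, p2 = g1.call(locus), g2.call(locus)
        if p1 is None or p2 is None:
            raise ValueError(f"missing call at locus {locus}")
        shared = sum((Counter(p1) & Counter(p2)).values())
        total += 2 - shared
    return total


@dataclass
class GenetAssignment:
    """Partition of ramets into genets, namespaced by site.

    ``genet_of`` maps each ramet ID to its genet ID; a genet ID is
    ``"<site>:<lowest member ramet_id>"``, so IDs are deterministic for a
    given partition regardless of input order.
    """

    genet_of: dict[str, str]

    @property
    def n_genets(self) -> int:
        return len(set(self.genet_of.values()))

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for ramet, genet in self.genet_of.items():
            out.setdefault(genet, []).append(ramet)
        return {g: sorted(ms) for g, ms in out.items()}

    def as_partition(self) -> set[frozenset[str]]:
        return {frozenset(ms) for ms in self.members().values()}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.genet_of.items()), columns=["ramet_id", "genet_id"]
        )


def infer_genets(
    collection: StudyCollection, max_mismatch: int = 1
) -> GenetAssignment:
    """Partition ramets into genets within each site.

    Within a site, ramets at allele-mismatch distance <= ``max_mismatch``
    are linked and genets are the connected components of that graph.
    Annotates each record's ``genet_id`` in place.
    """
    if max_mismatch < 0:
        raise ValueError(f"max_mismatch must be >= 0, got {max_mismatch}")
    genet_of: dict[str, str] = {}
    by_site: dict[str, list] = {}
    for rec in collection:
        by_site.setdefault(rec.site_id, []).append(rec)
    for site, recs in by_site.items():
        graph = nx.Graph()
        graph.add_nodes_from(r.ramet_id for r in recs)
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                d = allele_mismatch_distance(
                    recs[i].genotype, recs[j].genotype
                )
                if d <= max_mismatch:
                    graph.add_edge(recs[i].ramet_id, recs[j].ramet_id)
        for component in nx.connected_components(graph):
            genet_id = f"{site}:{min(component)}"
            for ramet_id in component:
                genet_of[ramet_id] = genet_id
    for rec in collection:
        rec.genet_id = genet_of[rec.ramet_id]
    return GenetAssignment(genet_of=genet_of)


def genet_richness(G: int, n: int) -> float:
    """Genotypic richness R = (G − 1)/(n − 1); NaN for a single ramet."""
    if not 1 <= G <= n:
        raise ValueError(f"need 1 <= G <= n, got G={G}, n={n}")
    if n == 1:
        return float("nan")
    return (G - 1) / (n - 1)


def richness_by_species_site(
    collection: StudyCollection,
    genets: Optional[GenetAssignment] = None,
    categories: Sequence[Lineage] = SPECIES_CATEGORIES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotypic richness per species per site, plus per-species summaries.

    Requires classified records with genet IDs (``classify_collection``
    and ``infer_genets`` annotate in place). Returns a table with one row
    per (species, site) pair that has at least one ramet — columns
    species, site_id, G, n, R — and a per-species summary of the
    unweighted across-site mean R with its standard error
    (sample SD / sqrt(number of sites); single-ramet sites have
    undefined R and are excluded from the mean).
    """
    genet_of = genets.genet_of if genets is not None else None
    rows = []
    wanted = set(categories)
    for site in collection.site_ids:
        for cat in categories:
            members = [
                rec
                for rec in collection
                if rec.site_id == site
                and rec.species_call is not None
                and rec.species_call.category == cat
            ]
            if not members:
                continue
            ids = set()
            for rec in members:
                gid = (
                    genet_of[rec.ramet_id]
                    if genet_of is not None
                    else rec.genet_id
                )
                if gid is None:
                    raise ValueError(
                        f"ramet {rec.ramet_id!r} has no genet assignment"
                    )
                ids.add(gid)
            G, n = len(ids), len(members)
            rows.append(
                {
                    "species": cat.value,
                    "site_id": site,
                    "G": G,
                    "n": n,
                    "R": genet_richness(G, n),
                }
            )
    table = pd.DataFrame(rows, columns=["species", "site_id", "G", "n", "R"])
    summaries = []
    for cat in categories:
        vals = table.loc[table["species"] == cat.value, "R"].dropna()
        n_sites = len(vals)
        mean = float(vals.mean()) if n_sites else float("nan")
        se = (
            float(vals.std(ddof=1) / math.sqrt(n_sites))
            if n_sites > 1
            else float("nan")
        )
        summaries.append(
            {
                "species": cat.value,
                "n_sites": n_sites,
                "mean_R": mean,
                "se_R": se,
            }
        )
    summary = pd.DataFrame(
        summaries, columns=["species", "n_sites", "mean_R", "se_R"]
    )
    return table, summary
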