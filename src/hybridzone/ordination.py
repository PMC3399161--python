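"""Principal-coordinates ordination of codominant genotypic distances.

Corroborates the private-allele classification with a model-free view of
the genotype data: pairwise squared codominant genotypic distances
(the Smouse–Peakall metric used by GenAlEx) are double-centred (Gower) and
eigen-decomposed, yielding ordination axes whose first coordinate
separates the two parental clusters with hybrids in between.

The per-locus squared distance between two diploid genotypes depends only
on the allele-sharing pattern (i, j, k, l denote distinct alleles):

====================  =====
pattern               d²
====================  =====
ii vs ii / ij vs ij   0
ii vs ij, ij vs ik    1
ij vs kl              2
ii vs jk              3
ii vs jj              4
====================  =====

Summed over loci, the squared distances feed a classical PCoA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classify import Lineage, SpeciesCall
from .genotypes import AllelePair, MultilocusGenotype, StudyCollection

logger = logging.getLogger(__name__)


class OrdinationError(ValueError):
    pass


def locus_squared_distance(p1: AllelePair, p2: AllelePair) -> int:
    """Squared codominant distance for one locus (0, 1, 2, 3 or 4)."""
    a, b = sorted(p1)
    c, d = sorted(p2)
    if (a, b) == (c, d):
        return 0
    hom1, hom2 = a == b, c == d
    if hom1 and hom2:
        return 4  # ii vs jj
    if hom1 or hom2:
        homo_allele = a if hom1 else c
        het = (c, d) if hom1 else (a, b)
        return 1 if homo_allele in het else 3  # ii vs ij / ii vs jk
    shared = len({a, b} & {c, d})
    return 1 if shared == 1 else 2  # ij vs ik / ij vs kl


def genotypic_distance_matrix(collection: StudyCollection) -> np.ndarray:
    """Pairwise squared genotypic distances summed over all loci."""
    genos = [rec.genotype for rec in collection]
    n = len(genos)
    D2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d2 = 0
            for locus in collection.loci:
                c1, c2 = genos[i].call(locus), genos[j].call(locus)
                if c1 is None or c2 is None:
                    raise OrdinationError(
                        f"missing call at {locus} "
                        f"({collection.records[i].ramet_id!r}/"
                        f"{collection.records[j].ramet_id!r}); "
                        "run drop_incomplete first"
                    )
                d2 += locus_squared_distance(c1, c2)
            D2[i, j] = D2[j, i] = d2
    return D2


@dataclass
class OrdinationResult:
    """Centered PCoA coordinates with variance-explained fractions.

    ``coordinates[i, k]`` is ramet i's score on axis k (axes ordered by
    decreasing eigenvalue); ``variance_fractions`` are eigenvalue shares
    of the total positive-eigenvalue variance.
    """

    ramet_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray

    @property
    def axis1(self) -> np.ndarray:
        return self.coordinates[:, 0]


def pcoa_from_distances(
    D2: np.ndarray, ramet_ids: list[str], atol: float = 1e-9
) -> OrdinationResult:
    """Classical (Gower) PCoA of a squared-distance matrix."""
    n = D2.shape[0]
    A = -0.5 * D2
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    G = A - row - col + A.mean()
    eigvals, eigvecs = np.linalg.eigh(G)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > atol * max(1.0, abs(eigvals[0]))
    if not positive.any():
        raise OrdinationError(
            "degenerate ordination: all genotypes identical"
        )
    vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(vals)
    fractions = vals / vals.sum()
    return OrdinationResult(
        ramet_ids=list(ramet_ids),
        coordinates=coords,
        eigenvalues=vals,
        variance_fractions=fractions,
    )


def ordinate(collection: StudyCollection) -> OrdinationResult:
    """PCoA of the collection's pairwise genotypic distance matrix."""
    if len(collection) < 3:
        raise OrdinationError(
            f"need at least 3 genotypes, have {len(collection)}"
        )
    D2 = genotypic_distance_matrix(collection)
    return pcoa_from_distances(D2, collection.ramet_ids)


@dataclass
class ConcordanceReport:
    """Agreement between private-allele calls and axis-1 ordination scores."""

    threshold: float
    fraction_pure_a_concordant: float
    fraction_pure_b_concordant: float
    fraction_f1_concordant: float
    n_pure_a: int
    n_pure_b: int
    n_f1: int
    discordant_ramet_ids: list[str]
    axis_flipped: bool


def corroborate(
    calls: list[SpeciesCall],
    ordination: OrdinationResult,
    threshold: float = 0.4,
) -> ConcordanceReport:
    """Check that axis-1 scores reproduce the private-allele classes.

    Axis 1 is oriented so the pure-A (T. latifolia) mean is negative
    (eigenvector sign is arbitrary); concordance then means pure-A scores
    below ``-threshold``, pure-B above ``+threshold`` and F1 in between.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if len(calls) != len(ordination.ramet_ids):
        raise ValueError("calls and ordination are not aligned")
    axis1 = ordination.axis1.copy()
    cats = np.array([c.category for c in calls], dtype=object)
    a_mask = cats == Lineage.PURE_A
    b_mask = cats == Lineage.PURE_B
    f1_mask = cats == Lineage.F1
    if not (a_mask.any() or b_mask.any() or f1_mask.any()):
        logger.warning("corroborate: no classified parental or F1 ramets")
        return ConcordanceReport(
            threshold, float("nan"), float("nan"), float("nan"),
            0, 0, 0, [], False,
        )
    flipped = False
    if a_mask.any() and axis1[a_mask].mean() > 0:
        axis1 = -axis1
        flipped = True
    elif not a_mask.any() and b_mask.any() and axis1[b_mask].mean() < 0:
        axis1 = -axis1
        flipped = True

    ok_a = axis1 < -threshold
    ok_b = axis1 > threshold
    ok_f1 = np.abs(axis1) <= threshold
    discordant = [
        rid
        for rid, cat, ga, gb, gf in zip(
            ordination.ramet_ids, cats, ok_a, ok_b, ok_f1
        )
        if (cat == Lineage.PURE_A and not ga)
        or (cat == Lineage.PURE_B and not gb)
        or (cat == Lineage.F1 and not gf)
    ]

    def _frac(mask: np.ndarray, ok: np.ndarray) -> float:
        return float(ok[mask].mean()) if mask.any() else float("nan")

    return ConcordanceReport(
        threshold=threshold,
        fraction_pure_a_concordant=_frac(a_mask, ok_a),
        fraction_pure_b_concordant=_frac(b_mask, ok_b),
        fraction_f1_concordant=_frac(f1_mask, ok_f1),
        n_pure_a=int(a_mask.sum()),
        n_pure_b=int(b_mask.sum()),
        n_f1=int(f1_mask.sum()),
        discordant_ramet_ids=discordant,
        axis_flipped=flipped,
    )
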