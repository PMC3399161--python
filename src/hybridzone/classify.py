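"""Species and hybrid-class assignment from private diagnostic alleles.

Two co-occurring cattail species — *Typha latifolia* (species A here) and
*T. angustifolia* (species B) — carry disjoint ("private") allele sets at
each locus of a diagnostic microsatellite panel. A ramet whose alleles all
come from one species' private set is a pure parent; one heterospecific
allele pair at every locus marks a first-generation hybrid (*T. × glauca*);
any other unambiguous mixture marks a later-generation hybrid (backcross or
advanced intercross). Alleles absent from the key leave a locus — and hence
the ramet — unresolved rather than silently mis-binned.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import pandas as pd

from .genotypes import AllelePair, MultilocusGenotype, StudyCollection

logger = logging.getLogger(__name__)


class Lineage(str, Enum):
    """Species/hybrid category of a ramet."""

    PURE_A = "pure_A"  # T. latifolia
    PURE_B = "pure_B"  # T. angustifolia
    F1 = "F1"  # T. x glauca
    LATER_GEN = "later_gen"  # backcross or advanced intercross
    UNRESOLVED = "unresolved"  # allele(s) absent from the key

    def __str__(self) -> str:  # pandas-friendly label
        return self.value


class LocusEvidence(str, Enum):
    """Per-locus diagnostic state of an allele pair."""

    AA = "AA"  # both alleles private to species A
    BB = "BB"  # both private to species B
    AB = "AB"  # one from each species
    AMBIGUOUS = "ambiguous"  # at least one allele not in the key

    def __str__(self) -> str:
        return self.value


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class DiagnosticKey:
    """Per-locus private allele sets for the two parental species.

    Within each locus the two private sets must be disjoint; alleles in
    neither set (shared or unknown) yield ambiguous evidence.
    """

    private_a: Mapping[str, frozenset[int]]
    private_b: Mapping[str, frozenset[int]]

    def __post_init__(self) -> None:
        if set(self.private_a) != set(self.private_b):
            raise ClassificationError(
                "diagnostic key: locus sets differ between species"
            )
        for locus in self.private_a:
            overlap = self.private_a[locus] & self.private_b[locus]
            if overlap:
                raise ClassificationError(
                    f"diagnostic key: alleles {sorted(overlap)} at {locus} "
                    "listed as private to both species"
                )

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.private_a)


@dataclass(frozen=True)
class SpeciesCall:
    """Classification outcome plus the per-locus evidence behind it."""

    category: Lineage
    evidence: tuple[tuple[str, LocusEvidence], ...]

    @property
    def evidence_string(self) -> str:
        return ";".join(f"{locus}={ev.value}" for locus, ev in self.evidence)


def score_locus(
    call: AllelePair, key: DiagnosticKey, locus: str
) -> LocusEvidence:
    """Diagnostic state of one allele pair against the key.

    AA/BB when both alleles are private to one species, AB for one of
    each, ambiguous when any allele is absent from the key at this locus.
    """
    if locus not in key.private_a:
        raise ClassificationError(f"locus {locus!r} not in diagnostic key")
    in_a = [a in key.private_a[locus] for a in call]
    in_b = [a in key.private_b[locus] for a in call]
    if all(in_a):
        return LocusEvidence.AA
    if all(in_b):
        return LocusEvidence.BB
    if (in_a[0] and in_b[1]) or (in_b[0] and in_a[1]):
        return LocusEvidence.AB
    return LocusEvidence.AMBIGUOUS


def classify_ramet(
    genotype: MultilocusGenotype, key: DiagnosticKey
) -> SpeciesCall:
    """Deterministic lineage call from the per-locus evidence vector.

    Pure parent iff every locus is homospecific for that parent; F1 iff
    every locus is heterospecific; any other ambiguity-free pattern is a
    later-generation hybrid; any ambiguous locus leaves the ramet
    unresolved.
    """
    if not genotype.is_complete:
        raise ClassificationError(
            f"genotype has missing loci {genotype.missing_loci}; "
            "run drop_incomplete first"
        )
    evidence = tuple(
        (locus, score_locus(genotype.call(locus), key, locus))
        for locus in genotype.loci
    )
    states = [ev for _, ev in evidence]
    if any(ev is LocusEvidence.AMBIGUOUS for ev in states):
        category = Lineage.UNRESOLVED
    elif all(ev is LocusEvidence.AA for ev in states):
        category = Lineage.PURE_A
    elif all(ev is LocusEvidence.BB for ev in states):
        category = Lineage.PURE_B
    elif all(ev is LocusEvidence.AB for ev in states):
        category = Lineage.F1
    else:
        category = Lineage.LATER_GEN
    return SpeciesCall(category=category, evidence=evidence)


def classify_collection(
    collection: StudyCollection, key: DiagnosticKey
) -> list[SpeciesCall]:
    """Classify every ramet, annotating records in place; returns the calls."""
    calls = []
    for rec in collection:
        call = classify_ramet(rec.genotype, key)
        rec.species_call = call
        calls.append(call)
    return calls


def lineage_frequencies(
    collection: StudyCollection, per_site: bool = False
) -> pd.DataFrame:
    """Counts of each lineage, overall or per site.

    Later-generation classes are already pooled by the classifier; counts
    sum to the number of classified records.
    """
    for rec in collection:
        if rec.species_call is None:
            raise ClassificationError(
                f"ramet {rec.ramet_id!r} is unclassified; "
                "run classify_collection first"
            )
    categories = [l.value for l in Lineage]
    if per_site:
        rows = []
        for site in collection.site_ids:
            counts = Counter(
                rec.species_call.category.value
                for rec in collection
                if rec.site_id == site
            )
            rows.append(
                {"site_id": site, **{c: counts.get(c, 0) for c in categories}}
            )
        return pd.DataFrame(
            rows, columns=["site_id"] + categories
        ).set_index("site_id")
    counts = Counter(rec.species_call.category.value for rec in collection)
    return pd.DataFrame(
        {"count": [counts.get(c, 0) for c in categories]}, index=categories
    )
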