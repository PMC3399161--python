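"""Core domain types for ramet-level microsatellite data.

The sampling unit is the *ramet* (a single shoot of a clonal plant); each
ramet carries a codominant multilocus genotype — an unordered pair of
integer allele fragment sizes (base pairs) at each of a fixed panel of
microsatellite loci — plus its site, shoot elevation and shoot height.

Allele identity is the integer fragment size; no binning is applied.
Unordered pairs are stored sorted ascending so genotypes compare
canonically. A missing (non-amplified) call is ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

#: The six SSR loci of the standard Typha panel, used as the default.
DEFAULT_LOCI: tuple[str, ...] = ("TA3", "TA5", "TA7", "TA8", "TA16", "TA20")

AllelePair = tuple[int, int]


class GenotypeError(ValueError):
    """Raised when genotype data violate a structural invariant."""


@dataclass(frozen=True)
class MultilocusGenotype:
    """Unordered allele-size pairs at a fixed set of loci.

    Parameters
    ----------
    calls
        Mapping from locus ID to a pair of positive integer allele sizes,
        or ``None`` for a locus that failed to amplify. Pairs are
        canonicalised to ascending order on construction.
    """

    calls: Mapping[str, Optional[AllelePair]]

    def __post_init__(self) -> None:
        canon: dict[str, Optional[AllelePair]] = {}
        for locus, pair in self.calls.items():
            if pair is None:
                canon[locus] = None
                continue
            if len(pair) != 2:
                raise GenotypeError(
                    f"locus {locus}: expected 2 alleles, got {len(pair)}"
                )
            a, b = int(pair[0]), int(pair[1])
            if a <= 0 or b <= 0:
                raise GenotypeError(
                    f"locus {locus}: allele sizes must be positive, got {pair}"
                )
            canon[locus] = (a, b) if a <= b else (b, a)
        object.__setattr__(self, "calls", canon)

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.calls)

    def call(self, locus: str) -> Optional[AllelePair]:
        return self.calls[locus]

    @property
    def missing_loci(self) -> tuple[str, ...]:
        return tuple(l for l, p in self.calls.items() if p is None)

    @property
    def is_complete(self) -> bool:
        return not self.missing_loci

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultilocusGenotype):
            return NotImplemented
        return dict(self.calls) == dict(other.calls)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.calls.items(), key=lambda kv: kv[0])))


@dataclass
class RametRecord:
    """One sampled shoot: location, morphology, genotype and derived labels.

    ``elevation_mm`` is the raw instrument-scale shoot elevation in integer
    millimetres; ``shoot_height_cm`` is the length of the longest leaf.
    ``species_call`` and ``genet_id`` start unset and are filled by the
    classification and genet-inference stages.
    """

    ramet_id: str
    site_id: str
    elevation_mm: int
    shoot_height_cm: float
    genotype: MultilocusGenotype
    species_call: Optional[object] = None  # classify.SpeciesCall once assigned
    genet_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.site_id:
            raise GenotypeError(f"ramet {self.ramet_id!r}: empty site_id")
        self.elevation_mm = int(self.elevation_mm)
        self.shoot_height_cm = float(self.shoot_height_cm)
        if not (self.shoot_height_cm == self.shoot_height_cm):  # NaN guard
            raise GenotypeError(f"ramet {self.ramet_id!r}: height is NaN")

    @property
    def elevation_cm(self) -> float:
        return self.elevation_mm / 10.0


@dataclass
class StudyCollection:
    """Ordered collection of ramet records sharing one locus panel.

    Invariants: ramet IDs are unique and every record's genotype covers
    exactly ``loci`` (missing calls allowed).
    """

    records: list[RametRecord]
    loci: tuple[str, ...] = DEFAULT_LOCI

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        seen: set[str] = set()
        for rec in self.records:
            if rec.ramet_id in seen:
                raise GenotypeError(f"duplicate ramet_id {rec.ramet_id!r}")
            seen.add(rec.ramet_id)
            if rec.genotype.loci != self.loci:
                missing = set(self.loci) - set(rec.genotype.loci)
                extra = set(rec.genotype.loci) - set(self.loci)
                raise GenotypeError(
                    f"ramet {rec.ramet_id!r}: genotype loci do not match the "
                    f"panel (missing {sorted(missing)}, extra {sorted(extra)})"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RametRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyCollection):
            return NotImplemented
        return self.loci == other.loci and self.records == other.records

    @property
    def ramet_ids(self) -> list[str]:
        return [r.ramet_id for r in self.records]

    @property
    def site_ids(self) -> list[str]:
        return sorted({r.site_id for r in self.records})

    def record(self, ramet_id: str) -> RametRecord:
        for rec in self.records:
            if rec.ramet_id == ramet_id:
                return rec
        raise KeyError(ramet_id)

    def subset(self, ramet_ids: Iterable[str]) -> "StudyCollection":
        keep = set(ramet_ids)
        return StudyCollection(
            [r for r in self.records if r.ramet_id in keep], self.loci
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Wide table: one row per ramet, two allele columns per locus."""
        rows = []
        for rec in self.records:
            row: dict[str, object] = {
                "ramet_id": rec.ramet_id,
                "site_id": rec.site_id,
                "elevation_mm": rec.elevation_mm,
                "height_cm": rec.shoot_height_cm,
            }
            for locus in self.loci:
                pair = rec.genotype.call(locus)
                row[f"{locus}_1"] = 0 if pair is None else pair[0]
                row[f"{locus}_2"] = 0 if pair is None else pair[1]
            if rec.species_call is not None:
                category = getattr(
                    rec.species_call, "category", rec.species_call
                )
                row["species"] = getattr(category, "value", category)
            if rec.genet_id is not None:
                row["genet_id"] = rec.genet_id
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class RemovalReport:
    """Ramets excluded for incomplete amplification."""

    removed_ramet_ids: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed_ramet_ids)


def drop_incomplete(
    collection: StudyCollection,
) -> tuple[StudyCollection, RemovalReport]:
    """Remove ramets that did not amplify fully across all loci.

    Returns the filtered collection plus a report listing the removed
    ramet IDs. Idempotent: a complete collection passes through unchanged.
    """
    import logging

    kept = [r for r in collection.records if r.genotype.is_complete]
    removed = [
        r.ramet_id for r in collection.records if not r.genotype.is_complete
    ]
    if kept == []:
        logging.getLogger(__name__).warning(
            "drop_incomplete: no complete genotypes remain (%d removed)",
            len(removed),
        )
    return (
        StudyCollection(kept, collection.loci),
        RemovalReport(removed),
    )
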