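"""Read and write ramet genotype tables and diagnostic-key tables.

Two CSV dialects are supported:

* ``"genalex"`` (default) — a GenAlEx-style codominant export: a first
  header row with counts (n loci, n samples, n sites), a free-text title
  row, then a column-header row ``ramet_id, site_id, elevation_mm,
  height_cm`` followed by two columns per locus (the locus name over the
  first of its pair). Missing alleles are coded ``0``.
* ``"long"`` — a plain long-format CSV with columns ``ramet_id, site_id,
  elevation_mm, height_cm, locus, allele1, allele2`` (one row per ramet
  per locus).

Parsing never silently coerces allele sizes: a token that is not a
positive integer becomes a missing call and is counted in the read report
(and logged).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .genotypes import (
    DEFAULT_LOCI,
    GenotypeError,
    MultilocusGenotype,
    RametRecord,
    StudyCollection,
)

logger = logging.getLogger(__name__)

MISSING_TOKEN = "0"  # GenAlEx convention for a missing allele


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass
class ReadReport:
    """Per-file parse accounting: coerced (unparseable) allele tokens."""

    n_rows: int = 0
    coerced_tokens: list[tuple[str, str, str]] = field(default_factory=list)
    # (ramet_id, locus, offending token)

    @property
    def n_coerced(self) -> int:
        return len(self.coerced_tokens)


def _parse_allele(token: str) -> Optional[int]:
    """Positive-integer allele size, or None for missing/unparseable."""
    token = token.strip()
    if token in ("", MISSING_TOKEN, "NA", "nan", "NaN"):
        return None
    try:
        value = int(token)
    except ValueError:
        return None
    return value if value > 0 else None


def _record_from_fields(
    ramet_id: str,
    site_id: str,
    elevation: str,
    height: str,
    allele_tokens: dict[str, tuple[str, str]],
    report: ReadReport,
) -> RametRecord:
    calls: dict[str, Optional[tuple[int, int]]] = {}
    for locus, (t1, t2) in allele_tokens.items():
        a1, a2 = _parse_allele(t1), _parse_allele(t2)
        if a1 is None or a2 is None:
            calls[locus] = None
            for tok in (t1, t2):
                if _parse_allele(tok) is None and tok.strip() not in (
                    "",
                    MISSING_TOKEN,
                ):
                    report.coerced_tokens.append((ramet_id, locus, tok))
        else:
            calls[locus] = (a1, a2)
    try:
        elev = int(elevation)
    except ValueError as exc:
        raise FormatError(
            f"ramet {ramet_id!r}: unparseable elevation {elevation!r}"
        ) from exc
    try:
        h = float(height)
    except ValueError as exc:
        raise FormatError(
            f"ramet {ramet_id!r}: unparseable height {height!r}"
        ) from exc
    return RametRecord(
        ramet_id=ramet_id,
        site_id=site_id,
        elevation_mm=elev,
        shoot_height_cm=h,
        genotype=MultilocusGenotype(calls),
    )


def read_genotype_table(
    path: str | Path,
    loci: Sequence[str] = DEFAULT_LOCI,
    dialect: str = "genalex",
    return_report: bool = False,
):
    """Read a ramet genotype table into a validated :class:`StudyCollection`.

    Rows with an unparseable allele retain a missing call at that locus;
    the count is available via ``return_report=True`` and is logged.
    Duplicate ramet IDs raise :class:`~hybridzone.genotypes.GenotypeError`;
    a header missing a required column raises :class:`FormatError` naming it.
    """
    path = Path(path)
    if dialect == "genalex":
        collection, report = _read_genalex(path, tuple(loci))
    elif dialect == "long":
        collection, report = _read_long(path, tuple(loci))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if report.n_coerced:
        logger.warning(
            "%s: %d unparseable allele tokens set to missing",
            path.name,
            report.n_coerced,
        )
    if return_report:
        return collection, report
    return collection


def _read_genalex(
    path: Path, loci: tuple[str, ...]
) -> tuple[StudyCollection, ReadReport]:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3:
        raise FormatError(f"{path}: expected 3 header rows, found {len(rows)}")
    header = rows[2]
    fixed = ["ramet_id", "site_id", "elevation_mm", "height_cm"]
    for i, name in enumerate(fixed):
        if i >= len(header) or header[i].strip() != name:
            raise FormatError(f"{path}: missing required column {name!r}")
    locus_cols: dict[str, int] = {}
    for locus in loci:
        try:
            locus_cols[locus] = header.index(locus, len(fixed))
        except ValueError:
            raise FormatError(f"{path}: missing locus column {locus!r}")
    report = ReadReport()
    records = []
    for row in rows[3:]:
        if not row or not any(cell.strip() for cell in row):
            continue
        report.n_rows += 1
        tokens = {
            locus: (
                row[col] if col < len(row) else "",
                row[col + 1] if col + 1 < len(row) else "",
            )
            for locus, col in locus_cols.items()
        }
        records.append(
            _record_from_fields(
                row[0].strip(), row[1].strip(), row[2], row[3], tokens, report
            )
        )
    return StudyCollection(records, loci), report


def _read_long(
    path: Path, loci: tuple[str, ...]
) -> tuple[StudyCollection, ReadReport]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {
            "ramet_id",
            "site_id",
            "elevation_mm",
            "height_cm",
            "locus",
            "allele1",
            "allele2",
        }
        have = set(reader.fieldnames or ())
        missing = required - have
        if missing:
            raise FormatError(
                f"{path}: missing required column(s) {sorted(missing)}"
            )
        per_ramet: dict[str, dict] = {}
        order: list[str] = []
        for row in reader:
            rid = row["ramet_id"].strip()
            if rid not in per_ramet:
                per_ramet[rid] = {
                    "site_id": row["site_id"].strip(),
                    "elevation_mm": row["elevation_mm"],
                    "height_cm": row["height_cm"],
                    "alleles": {},
                }
                order.append(rid)
            per_ramet[rid]["alleles"][row["locus"].strip()] = (
                row["allele1"],
                row["allele2"],
            )
    report = ReadReport(n_rows=len(order))
    records = []
    for rid in order:
        info = per_ramet[rid]
        tokens = {
            locus: info["alleles"].get(locus, (MISSING_TOKEN, MISSING_TOKEN))
            for locus in loci
        }
        records.append(
            _record_from_fields(
                rid,
                info["site_id"],
                info["elevation_mm"],
                info["height_cm"],
                tokens,
                report,
            )
        )
    return StudyCollection(records, loci), report


def _format_height(h: float) -> str:
    # repr round-trips floats exactly; integers stay compact
    return repr(h) if h != int(h) else str(int(h))


def write_genotype_table(
    collection: StudyCollection,
    path: str | Path,
    dialect: str = "genalex",
    title: str = "hybridzone genotype export",
) -> None:
    """Write a collection so that reading it back reproduces every field.

    Missing calls serialise as ``0`` per the GenAlEx convention.
    """
    path = Path(path)
    loci = collection.loci
    if dialect == "genalex":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            n_cols = 4 + 2 * len(loci)
            w.writerow(
                [len(loci), len(collection), len(collection.site_ids)]
                + [""] * (n_cols - 3)
            )
            w.writerow([title] + [""] * (n_cols - 1))
            header = ["ramet_id", "site_id", "elevation_mm", "height_cm"]
            for locus in loci:
                header += [locus, ""]
            w.writerow(header)
            for rec in collection:
                row = [
                    rec.ramet_id,
                    rec.site_id,
                    str(rec.elevation_mm),
                    _format_height(rec.shoot_height_cm),
                ]
                for locus in loci:
                    pair = rec.genotype.call(locus)
                    row += (
                        [MISSING_TOKEN, MISSING_TOKEN]
                        if pair is None
                        else [str(pair[0]), str(pair[1])]
                    )
                w.writerow(row)
    elif dialect == "long":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                [
                    "ramet_id",
                    "site_id",
                    "elevation_mm",
                    "height_cm",
                    "locus",
                    "allele1",
                    "allele2",
                ]
            )
            for rec in collection:
                for locus in loci:
                    pair = rec.genotype.call(locus)
                    a1, a2 = (
                        (MISSING_TOKEN, MISSING_TOKEN)
                        if pair is None
                        else (str(pair[0]), str(pair[1]))
                    )
                    w.writerow(
                        [
                            rec.ramet_id,
                            rec.site_id,
                            str(rec.elevation_mm),
                            _format_height(rec.shoot_height_cm),
                            locus,
                            a1,
                            a2,
                        ]
                    )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_diagnostic_key(path: str | Path):
    """Read a diagnostic-key CSV (columns: locus, allele, species in {A, B})."""
    from .classify import DiagnosticKey

    path = Path(path)
    private_a: dict[str, set[int]] = {}
    private_b: dict[str, set[int]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"locus", "allele", "species"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise FormatError(
                f"{path}: missing required column(s) {sorted(missing)}"
            )
        for row in reader:
            locus = row["locus"].strip()
            allele = int(row["allele"])
            species = row["species"].strip().upper()
            if species == "A":
                private_a.setdefault(locus, set()).add(allele)
                private_b.setdefault(locus, set())
            elif species == "B":
                private_b.setdefault(locus, set()).add(allele)
                private_a.setdefault(locus, set())
            else:
                raise FormatError(
                    f"{path}: species must be 'A' or 'B', got {species!r}"
                )
    return DiagnosticKey(
        private_a={l: frozenset(s) for l, s in private_a.items()},
        private_b={l: frozenset(s) for l, s in private_b.items()},
    )


def write_diagnostic_key(key, path: str | Path) -> None:
    """Write a diagnostic key as a locus/allele/species CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["locus", "allele", "species"])
        for locus in key.loci:
            for allele in sorted(key.private_a[locus]):
                w.writerow([locus, allele, "A"])
            for allele in sorted(key.private_b[locus]):
                w.writerow([locus, allele, "B"])
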