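"""Synthetic hybrid-zone communities with known truth.

Generates ramet-level datasets with the statistical structure the
analysis assumes: two parental species with private (diagnostic) SSR
alleles at six loci, F1 and first-generation-backcross hybrids, clonal
replication within sites, occasional single-allele genotyping errors, and
a hierarchical elevation model

    elevation = base + site effect + species offset + genet effect + noise

with shoot height tied (optionally) to within-site elevation. Every draw
derives from the config seed, so a config reproduces its dataset
bit-for-bit.

The ``paper_scale_preset`` emulates a field survey of 18 sympatric sites
with ~15 ramets each (~270 total), an F1-dominated lineage mixture with
rare later-generation hybrids, and clonality giving per-species
genotypic richness around 0.1–0.3.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .classify import DiagnosticKey, Lineage
from .genotypes import (
    DEFAULT_LOCI,
    MultilocusGenotype,
    RametRecord,
    StudyCollection,
)

#: Lineages the generator can draw (unresolved is an analysis outcome,
#: never a truth label).
SIMULATED_LINEAGES: tuple[Lineage, ...] = (
    Lineage.PURE_A,
    Lineage.PURE_B,
    Lineage.F1,
    Lineage.LATER_GEN,
)


class SimulationError(ValueError):
    pass


@dataclass
class ElevationModel:
    """Hierarchical elevation effects, all in centimetres."""

    base_cm: float = 100.0
    site_sd_cm: float = 25.0
    offsets_cm: dict[str, float] = field(
        default_factory=lambda: {
            Lineage.PURE_A.value: -2.6,
            Lineage.PURE_B.value: -2.0,
            Lineage.F1.value: 1.2,
            Lineage.LATER_GEN.value: 0.0,
        }
    )
    genet_sd_cm: float = 4.0
    residual_sd_cm: float = 6.0


@dataclass
class HeightModel:
    """Shoot height as a linear function of within-site elevation (cm)."""

    intercept_cm: float = 150.0
    slope_per_cm: float = 0.0
    noise_sd_cm: float = 25.0


@dataclass
class SimulationConfig:
    """All generator knobs.

    ``ramets_per_site`` is either a fixed count or an inclusive
    ``(low, high)`` range sampled per site. ``clonality`` is the mean
    number of ramets per genet (>= 1), either one value or a per-lineage
    mapping. ``genotyping_error_rate`` is the per-allele-copy probability
    that a scored allele is replaced by another allele from the same
    locus's pool.
    """

    seed: int = 0
    n_sites: int = 18
    ramets_per_site: Union[int, tuple[int, int]] = 15
    loci: tuple[str, ...] = DEFAULT_LOCI
    alleles_per_species_per_locus: int = 4
    shared_allele_fraction: float = 0.0
    lineage_mixture: dict[str, float] = field(
        default_factory=lambda: {
            Lineage.PURE_A.value: 0.25,
            Lineage.PURE_B.value: 0.20,
            Lineage.F1.value: 0.52,
            Lineage.LATER_GEN.value: 0.03,
        }
    )
    clonality: Union[float, dict[str, float]] = 3.0
    genotyping_error_rate: float = 0.005
    elevation: ElevationModel = field(default_factory=ElevationModel)
    height: HeightModel = field(default_factory=HeightModel)

    def __post_init__(self) -> None:
        total = sum(self.lineage_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(
                f"lineage mixture must sum to 1, sums to {total}"
            )
        if not 0 <= self.genotyping_error_rate < 1:
            raise SimulationError(
                "genotyping_error_rate must be in [0, 1)"
            )
        if not 0 <= self.shared_allele_fraction < 1:
            raise SimulationError(
                "shared_allele_fraction must be in [0, 1)"
            )
        for sd in (
            self.elevation.site_sd_cm,
            self.elevation.genet_sd_cm,
            self.elevation.residual_sd_cm,
            self.height.noise_sd_cm,
        ):
            if sd < 0:
                raise SimulationError("standard deviations must be >= 0")

    def clonality_of(self, lineage: Lineage) -> float:
        if isinstance(self.clonality, Mapping):
            c = float(self.clonality[lineage.value])
        else:
            c = float(self.clonality)
        if c < 1:
            raise SimulationError(f"clonality must be >= 1, got {c}")
        return c

    # --- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["loci"] = list(self.loci)
        if isinstance(self.ramets_per_site, tuple):
            d["ramets_per_site"] = list(self.ramets_per_site)
        return d

    def to_yaml(self, path: Union[str, Path, None] = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "elevation" in d and isinstance(d["elevation"], Mapping):
            d["elevation"] = ElevationModel(**d["elevation"])
        if "height" in d and isinstance(d["height"], Mapping):
            d["height"] = HeightModel(**d["height"])
        if "loci" in d:
            d["loci"] = tuple(d["loci"])
        if isinstance(d.get("ramets_per_site"), list):
            d["ramets_per_site"] = tuple(d["ramets_per_site"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "SimulationConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class AllelePools:
    """Per-species allele frequencies per locus, plus the matching key."""

    frequencies_a: dict[str, dict[int, float]]
    frequencies_b: dict[str, dict[int, float]]
    key: DiagnosticKey

    def union_alleles(self, locus: str) -> list[int]:
        return sorted(
            set(self.frequencies_a[locus]) | set(self.frequencies_b[locus])
        )


@dataclass
class TruthLabels:
    """Ground truth per ramet, aligned with the emitted collection."""

    frame: pd.DataFrame  # ramet_id, site_id, lineage, genet_id, effects...

    def lineage_of(self, ramet_id: str) -> Lineage:
        row = self.frame.loc[self.frame["ramet_id"] == ramet_id]
        return Lineage(row["lineage"].iloc[0])

    def partition(self) -> set[frozenset[str]]:
        """True genet partition as a set of ramet-ID sets."""
        return {
            frozenset(g["ramet_id"])
            for _, g in self.frame.groupby("genet_id")
        }


def simulate_allele_pools(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> AllelePools:
    """Draw per-species allele pools with disjoint private sets.

    Allele sizes step by 2 bp (dinucleotide repeats); each species gets
    ``alleles_per_species_per_locus`` private alleles, plus enough shared
    alleles that they make up ``shared_allele_fraction`` of the locus
    pool. Frequencies are flat-Dirichlet draws per species.
    """
    if config.alleles_per_species_per_locus < 1:
        raise SimulationError("alleles_per_species_per_locus must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_priv = config.alleles_per_species_per_locus
    f = config.shared_allele_fraction
    n_shared = int(round(2 * n_priv * f / (1 - f)))
    freqs_a: dict[str, dict[int, float]] = {}
    freqs_b: dict[str, dict[int, float]] = {}
    priv_a: dict[str, frozenset[int]] = {}
    priv_b: dict[str, frozenset[int]] = {}
    for idx, locus in enumerate(config.loci):
        base = 100 + 40 * idx
        sizes = [base + 2 * k for k in range(2 * n_priv + n_shared)]
        a_sizes = sizes[:n_priv]
        b_sizes = sizes[n_priv : 2 * n_priv]
        shared = sizes[2 * n_priv :]
        priv_a[locus] = frozenset(a_sizes)
        priv_b[locus] = frozenset(b_sizes)
        fa = rng.dirichlet(np.ones(n_priv + n_shared))
        fb = rng.dirichlet(np.ones(n_priv + n_shared))
        freqs_a[locus] = dict(zip(a_sizes + shared, fa.tolist()))
        freqs_b[locus] = dict(zip(b_sizes + shared, fb.tolist()))
    return AllelePools(
        frequencies_a=freqs_a,
        frequencies_b=freqs_b,
        key=DiagnosticKey(private_a=priv_a, private_b=priv_b),
    )


def _draw_allele(freqs: dict[int, float], rng: np.random.Generator) -> int:
    alleles = list(freqs)
    probs = np.array([freqs[a] for a in alleles])
    return int(rng.choice(alleles, p=probs / probs.sum()))


def _draw_genotype(
    lineage: Lineage,
    pools: AllelePools,
    rng: np.random.Generator,
) -> MultilocusGenotype:
    calls: dict[str, tuple[int, int]] = {}
    backcross_parent = None
    if lineage is Lineage.LATER_GEN:
        backcross_parent = (
            Lineage.PURE_A if rng.random() < 0.5 else Lineage.PURE_B
        )
    for locus in pools.frequencies_a:
        fa, fb = pools.frequencies_a[locus], pools.frequencies_b[locus]
        if lineage is Lineage.PURE_A:
            pair = (_draw_allele(fa, rng), _draw_allele(fa, rng))
        elif lineage is Lineage.PURE_B:
            pair = (_draw_allele(fb, rng), _draw_allele(fb, rng))
        elif lineage is Lineage.F1:
            pair = (_draw_allele(fa, rng), _draw_allele(fb, rng))
        else:  # first-generation backcross: each locus AB or parental, 50/50
            fp = fa if backcross_parent is Lineage.PURE_A else fb
            fo = fb if backcross_parent is Lineage.PURE_A else fa
            if rng.random() < 0.5:
                pair = (_draw_allele(fp, rng), _draw_allele(fo, rng))
            else:
                pair = (_draw_allele(fp, rng), _draw_allele(fp, rng))
        calls[locus] = pair
    return MultilocusGenotype(calls)


def _apply_genotyping_errors(
    genotype: MultilocusGenotype,
    pools: AllelePools,
    rate: float,
    rng: np.random.Generator,
) -> tuple[MultilocusGenotype, int]:
    """Replace each allele copy with prob ``rate``; returns (obs, n_errors)."""
    if rate == 0:
        return genotype, 0
    n_err = 0
    calls: dict[str, tuple[int, int]] = {}
    for locus in genotype.loci:
        pair = list(genotype.call(locus))
        pool = pools.union_alleles(locus)
        for k in range(2):
            if rng.random() < rate:
                alternatives = [a for a in pool if a != pair[k]]
                if alternatives:
                    pair[k] = int(rng.choice(alternatives))
                    n_err += 1
        calls[locus] = (pair[0], pair[1])
    return MultilocusGenotype(calls), n_err


def simulate_community(
    config: SimulationConfig,
) -> tuple[StudyCollection, TruthLabels]:
    """Generate one community with ground-truth labels.

    Per site: genets are drawn lineage-first from the mixture, each genet
    replicated into 1 + Poisson(clonality − 1) ramets (truncated to the
    site's target count); elevations follow the hierarchical model and
    heights the linear height model; genotyping errors are applied to the
    observed (not true) genotypes.
    """
    rng = np.random.default_rng(config.seed)
    pools = simulate_allele_pools(config, rng)
    lineages = [l for l in SIMULATED_LINEAGES]
    mix = np.array([config.lineage_mixture[l.value] for l in lineages])
    records: list[RametRecord] = []
    truth_rows: list[dict] = []
    ramet_counter = 0
    for s in range(config.n_sites):
        site_id = f"s{s + 1:02d}"
        site_effect = rng.normal(0.0, config.elevation.site_sd_cm)
        if isinstance(config.ramets_per_site, tuple):
            lo, hi = config.ramets_per_site
            target = int(rng.integers(lo, hi + 1))
        else:
            target = int(config.ramets_per_site)
        placed = 0
        genet_counter = 0
        while placed < target:
            lineage = lineages[int(rng.choice(len(lineages), p=mix))]
            true_genotype = _draw_genotype(lineage, pools, rng)
            genet_effect = rng.normal(0.0, config.elevation.genet_sd_cm)
            c = config.clonality_of(lineage)
            size = 1 + int(rng.poisson(c - 1.0))
            size = min(size, target - placed)
            genet_counter += 1
            genet_id = f"{site_id}:g{genet_counter:03d}"
            for _ in range(size):
                ramet_counter += 1
                ramet_id = f"r{ramet_counter:04d}"
                resid = rng.normal(0.0, config.elevation.residual_sd_cm)
                elev_cm = (
                    config.elevation.base_cm
                    + site_effect
                    + config.elevation.offsets_cm.get(lineage.value, 0.0)
                    + genet_effect
                    + resid
                )
                # round half away from zero, store integer mm
                elev_mm = int(
                    np.sign(elev_cm * 10)
                    * np.floor(abs(elev_cm * 10) + 0.5)
                )
                within_site = elev_cm - (
                    config.elevation.base_cm + site_effect
                )
                height = (
                    config.height.intercept_cm
                    + config.height.slope_per_cm * within_site
                    + rng.normal(0.0, config.height.noise_sd_cm)
                )
                observed, n_err = _apply_genotyping_errors(
                    true_genotype, pools, config.genotyping_error_rate, rng
                )
                records.append(
                    RametRecord(
                        ramet_id=ramet_id,
                        site_id=site_id,
                        elevation_mm=elev_mm,
                        shoot_height_cm=round(height, 1),
                        genotype=observed,
                    )
                )
                truth_rows.append(
                    {
                        "ramet_id": ramet_id,
                        "site_id": site_id,
                        "lineage": lineage.value,
                        "genet_id": genet_id,
                        "site_effect_cm": site_effect,
                        "genet_effect_cm": genet_effect,
                        "residual_cm": resid,
                        "n_genotyping_errors": n_err,
                    }
                )
                placed += 1
    collection = StudyCollection(records, config.loci)
    truth = TruthLabels(pd.DataFrame(truth_rows))
    return collection, truth


def simulate_community_with_key(
    config: SimulationConfig,
) -> tuple[StudyCollection, TruthLabels, DiagnosticKey]:
    """Like :func:`simulate_community` but also returns the diagnostic key."""
    pools = simulate_allele_pools(config)
    collection, truth = simulate_community(config)
    return collection, truth, pools.key


def paper_scale_preset(seed: int = 0) -> SimulationConfig:
    """Field-survey-scale defaults: 18 sites, ~270 ramets, F1-dominated.

    Fully diagnostic loci (no shared alleles), clonality tuned so
    per-species genotypic richness falls around 0.1–0.3, small realistic
    species elevation offsets and a rare genotyping error rate.
    """
    return SimulationConfig(seed=seed)
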