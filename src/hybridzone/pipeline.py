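"""End-to-end pipeline: simulate/load → classify → genets → analyze → report.

A run is fully described by a :class:`PipelineConfig`; with a fixed seed
two runs of the same config produce byte-identical report JSON. Each run
writes a manifest (config hash, seed, stage row counts) sufficient to
reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import __version__
from .classify import Lineage, classify_collection, lineage_frequencies
from .clones import infer_genets, richness_by_species_site
from .genotypes import StudyCollection, drop_incomplete
from .io import (
    read_diagnostic_key,
    read_genotype_table,
    write_diagnostic_key,
    write_genotype_table,
)
from .niche import (
    fit_elevation_lmm,
    fit_richness_glmm,
    ks_compare,
    standardize_elevations,
)
from .report import build_report, dump_json, render_markdown
from .simulate import SimulationConfig, simulate_community_with_key

logger = logging.getLogger(__name__)

DEFAULT_KS_PAIRS: tuple[tuple[str, str], ...] = (
    (Lineage.PURE_A.value, Lineage.PURE_B.value),
    (Lineage.PURE_A.value, Lineage.F1.value),
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Paths and analysis options for one pipeline run.

    Either ``simulation`` is given (a community is generated and written
    to the output directory) or ``genotypes_path``/``key_path`` point at
    existing input files.
    """

    out_dir: Union[str, Path] = "hybridzone_run"
    genotypes_path: Optional[Union[str, Path]] = None
    key_path: Optional[Union[str, Path]] = None
    simulation: Optional[SimulationConfig] = None
    seed: Optional[int] = None
    max_mismatch: int = 1
    alpha: float = 0.05
    df_method: str = "containment"
    lmm_response: str = "standardized"
    ks_pairs: tuple[tuple[str, str], ...] = DEFAULT_KS_PAIRS
    dialect: str = "genalex"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "genotypes_path": (
                None if self.genotypes_path is None else str(self.genotypes_path)
            ),
            "key_path": None if self.key_path is None else str(self.key_path),
            "simulation": (
                None if self.simulation is None else self.simulation.to_dict()
            ),
            "seed": self.seed,
            "max_mismatch": self.max_mismatch,
            "alpha": self.alpha,
            "df_method": self.df_method,
            "lmm_response": self.lmm_response,
            "ks_pairs": [list(p) for p in self.ks_pairs],
            "dialect": self.dialect,
        }

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "ks_pairs" in d:
            d["ks_pairs"] = tuple(tuple(p) for p in d["ks_pairs"])
        return cls(**d)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle; returns the report.

    Outputs under ``out_dir``: genotypes.csv / key.csv / truth.csv (when
    simulating), calls.csv, genets.csv, richness.csv, report.json,
    report.md and manifest.json. On failure a FAILED marker naming the
    stage is left in the output directory and the error re-raised.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    counts: dict[str, int] = {}
    notes: list[str] = []
    try:
        stage = "input"
        if config.simulation is not None:
            sim = config.simulation
            if config.seed is not None and sim.seed != config.seed:
                sim = SimulationConfig.from_dict(
                    {**sim.to_dict(), "seed": config.seed}
                )
            collection, truth, key = simulate_community_with_key(sim)
            write_genotype_table(collection, out / "genotypes.csv")
            write_diagnostic_key(key, out / "key.csv")
            truth.frame.to_csv(out / "truth.csv", index=False)
            seed = sim.seed
        else:
            if config.genotypes_path is None or config.key_path is None:
                raise PipelineError(
                    "config must provide either a simulation block or both "
                    "genotypes_path and key_path"
                )
            for p in (config.genotypes_path, config.key_path):
                if not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
            collection = read_genotype_table(
                config.genotypes_path, dialect=config.dialect
            )
            key = read_diagnostic_key(config.key_path)
            seed = config.seed
        counts["ramets_read"] = len(collection)

        stage = "filter"
        collection, removal = drop_incomplete(collection)
        counts["ramets_complete"] = len(collection)
        counts["ramets_removed_incomplete"] = removal.n_removed
        if removal.n_removed:
            notes.append(
                f"{removal.n_removed} ramet(s) removed for incomplete "
                f"amplification: {', '.join(removal.removed_ramet_ids)}"
            )

        stage = "classify"
        classify_collection(collection, key)
        freqs = lineage_frequencies(collection)
        collection.to_dataframe().to_csv(out / "calls.csv", index=False)

        stage = "genets"
        genets = infer_genets(collection, max_mismatch=config.max_mismatch)
        genets.to_dataframe().to_csv(out / "genets.csv", index=False)
        counts["genets"] = genets.n_genets

        stage = "richness"
        richness_table, richness_summary = richness_by_species_site(
            collection, genets
        )
        richness_table.to_csv(out / "richness.csv", index=False)

        stage = "lmm"
        lmm = None
        try:
            lmm = fit_elevation_lmm(
                collection,
                response=config.lmm_response,
                df_method=config.df_method,
            )
        except ValueError as exc:
            notes.append(f"elevation LMM not fitted: {exc}")

        stage = "glmm"
        glmm = None
        try:
            glmm = fit_richness_glmm(richness_table)
        except ValueError as exc:
            notes.append(f"richness GLMM not fitted: {exc}")

        stage = "ks"
        std = standardize_elevations(collection).set_index("ramet_id")
        by_species: dict[str, list[float]] = {}
        for rec in collection:
            if rec.species_call is None:
                continue
            by_species.setdefault(rec.species_call.category.value, []).append(
                float(std.loc[rec.ramet_id, "std_elev_cm"])
            )
        ks_results = {}
        for a, b in config.ks_pairs:
            if by_species.get(a) and by_species.get(b):
                ks_results[f"{a}_vs_{b}"] = ks_compare(
                    by_species[a], by_species[b]
                )
            else:
                notes.append(
                    f"KS comparison {a} vs {b} skipped: a class is empty"
                )

        stage = "report"
        report = build_report(
            collection,
            freqs,
            richness_table,
            richness_summary,
            lmm,
            glmm,
            ks_results,
            seed=seed,
            notes=notes,
        )
        dump_json(report, out / "report.json")
        (out / "report.md").write_text(render_markdown(report))

        manifest = {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
            "seed": seed,
            "stage_counts": counts,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
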