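"""Machine- and human-readable analysis reports.

Bundles the lineage frequency table, genotypic-richness table, the three
inferential results and per-species standardized-elevation summaries into
one JSON-serialisable dict plus a Markdown rendering. All elevations are
reported in centimetres.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .classify import Lineage
from .clones import SPECIES_CATEGORIES
from .genotypes import StudyCollection
from .niche import (
    GlmmResult,
    KsResult,
    LmmResult,
    standardize_elevations,
)

SCHEMA_VERSION = "1"


def _clean(obj):
    """JSON-safe copy: numpy scalars to python, NaN to None."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    return obj


def elevation_summaries(
    collection: StudyCollection,
) -> dict[str, dict[str, float]]:
    """Per-species mean/median/SD of standardized elevation (cm)."""
    std = standardize_elevations(collection).set_index("ramet_id")
    out: dict[str, dict[str, float]] = {}
    for cat in SPECIES_CATEGORIES:
        vals = np.array(
            [
                std.loc[rec.ramet_id, "std_elev_cm"]
                for rec in collection
                if rec.species_call is not None
                and rec.species_call.category == cat
            ]
        )
        if vals.size == 0:
            continue
        out[cat.value] = {
            "n": int(vals.size),
            "mean_cm": float(vals.mean()),
            "median_cm": float(np.median(vals)),
            "sd_cm": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
        }
    return out


def elevation_histograms(
    collection: StudyCollection, bin_width_cm: float = 5.0
) -> dict[str, dict[str, list[float]]]:
    """Per-species histogram bins of standardized elevations (cm)."""
    std = standardize_elevations(collection).set_index("ramet_id")
    values = {
        cat.value: [
            float(std.loc[rec.ramet_id, "std_elev_cm"])
            for rec in collection
            if rec.species_call is not None
            and rec.species_call.category == cat
        ]
        for cat in SPECIES_CATEGORIES
    }
    all_vals = [v for vs in values.values() for v in vs]
    if not all_vals:
        return {}
    lo = bin_width_cm * math.floor(min(all_vals) / bin_width_cm)
    hi = bin_width_cm * math.ceil(max(all_vals) / bin_width_cm)
    n_bins = max(int(round((hi - lo) / bin_width_cm)), 1)
    edges = np.linspace(lo, hi, n_bins + 1)
    out = {}
    for sp, vs in values.items():
        if not vs:
            continue
        counts, _ = np.histogram(vs, bins=edges)
        out[sp] = {
            "bin_edges_cm": edges.tolist(),
            "counts": counts.tolist(),
        }
    return out


def build_report(
    collection: StudyCollection,
    frequencies: pd.DataFrame,
    richness_table: pd.DataFrame,
    richness_summary: pd.DataFrame,
    lmm: Optional[LmmResult],
    glmm: Optional[GlmmResult],
    ks_results: dict[str, KsResult],
    seed: Optional[int] = None,
    notes: Optional[list[str]] = None,
) -> dict:
    """Assemble a JSON-serialisable analysis report."""
    report = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": seed,
        "n_ramets": len(collection),
        "n_sites": len(collection.site_ids),
        "lineage_frequencies": _clean(frequencies["count"].to_dict()),
        "richness": {
            "per_species_site": _clean(
                richness_table.to_dict(orient="records")
            ),
            "per_species_summary": _clean(
                richness_summary.to_dict(orient="records")
            ),
        },
        "standardized_elevation_cm": _clean(
            elevation_summaries(collection)
        ),
        "elevation_lmm": _clean(asdict(lmm)) if lmm is not None else None,
        "richness_glmm": _clean(asdict(glmm)) if glmm is not None else None,
        "ks_tests": {
            name: _clean(asdict(res)) for name, res in ks_results.items()
        },
        "notes": list(notes or []),
    }
    return report


def render_markdown(report: dict) -> str:
    """Human-readable Markdown rendering of a report dict."""
    lines = [
        "# Hybrid-zone analysis report",
        "",
        f"- package version: {report['package_version']}",
        f"- seed: {report['seed']}",
        f"- ramets: {report['n_ramets']} across {report['n_sites']} sites",
        "",
        "## Lineage frequencies",
        "",
        "| lineage | count |",
        "|---|---|",
    ]
    for lineage, count in report["lineage_frequencies"].items():
        lines.append(f"| {lineage} | {count} |")
    lines += ["", "## Genotypic richness (per species)", ""]
    lines += ["| species | sites | mean R | SE |", "|---|---|---|---|"]
    for row in report["richness"]["per_species_summary"]:
        mean = row["mean_R"]
        se = row["se_R"]
        lines.append(
            f"| {row['species']} | {row['n_sites']} | "
            f"{'—' if mean is None else f'{mean:.3f}'} | "
            f"{'—' if se is None else f'{se:.3f}'} |"
        )
    lines += ["", "## Standardized elevations (cm)", ""]
    lines += [
        "| species | n | mean | median | SD |",
        "|---|---|---|---|---|",
    ]
    for sp, s in report["standardized_elevation_cm"].items():
        sd = s["sd_cm"]
        lines.append(
            f"| {sp} | {s['n']} | {s['mean_cm']:.2f} | "
            f"{s['median_cm']:.2f} | {'—' if sd is None else f'{sd:.2f}'} |"
        )
    lmm = report.get("elevation_lmm")
    lines += ["", "## Elevation mixed model", ""]
    if lmm is None:
        lines.append("not fitted")
    else:
        st, ht = lmm["species_test"], lmm["height_test"]
        lines += [
            f"- species: F({st['df_num']},{st['df_den']}) = "
            f"{st['F']:.2f}, P = {st['p']:.3g}",
            f"- height covariate: F({ht['df_num']},{ht['df_den']}) = "
            f"{ht['F']:.2f}, P = {ht['p']:.3g}",
            f"- adjusted means (cm): "
            + ", ".join(
                f"{k} = {v:.2f}"
                for k, v in lmm["adjusted_means_cm"].items()
            ),
        ]
        if lmm["singular"]:
            lines.append("- note: singular random-effects fit")
    glmm = report.get("richness_glmm")
    lines += ["", "## Richness mixed model (binomial, logit)", ""]
    if glmm is None:
        lines.append("not fitted")
    else:
        for c in glmm["contrasts"]:
            lines.append(
                f"- {glmm['reference']} vs {c['species']}: estimate = "
                f"{c['estimate']:.2f} ± {c['se']:.2f} SE, Z = {c['z']:.2f}, "
                f"P = {c['p']:.3g}"
            )
        if glmm["separation_flag"]:
            lines.append("- note: possible complete separation")
    lines += ["", "## Kolmogorov–Smirnov comparisons", ""]
    if not report["ks_tests"]:
        lines.append("none")
    for name, ks in report["ks_tests"].items():
        lines.append(
            f"- {name}: D = {ks['D']:.3f}, P = {ks['p']:.3g} "
            f"(n = {ks['n_x']}, {ks['n_y']})"
        )
    for note in report.get("notes", []):
        lines.append(f"\n> {note}")
    lines.append("")
    return "\n".join(lines)


def dump_json(report: dict, path) -> None:
    """Deterministic JSON serialisation (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
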