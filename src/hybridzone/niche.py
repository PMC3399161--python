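"""Elevation niche-segregation tests.

Shoot elevation is a within-site proxy for water depth, so elevations are
first standardized by subtracting each site's median shoot elevation.
Three inferential analyses then ask whether the co-occurring lineages
segregate along the elevation gradient:

* a linear mixed model (REML) of standardized elevation on species with
  shoot height as covariate and random intercepts for site and for genet
  nested within site;
* a binomial-logit mixed model of the genets-per-ramets ratio (G of n)
  on species with a site random intercept, testing lineage differences in
  clonal (genotypic) diversity;
* two-sample Kolmogorov–Smirnov comparisons of the standardized
  elevation distributions.

Later-generation and unresolved ramets are excluded from the
species-level tests.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

from .classify import Lineage
from .clones import SPECIES_CATEGORIES, GenetAssignment
from .genotypes import StudyCollection

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Standardization
# --------------------------------------------------------------------------

def standardize_elevations(collection: StudyCollection) -> pd.DataFrame:
    """Site-median-centered shoot elevations in centimetres.

    Standardization uses all ramets at a site (before any filtering by
    species), so adding a constant to a site's elevations leaves its
    standardized values unchanged. Returns columns ramet_id, site_id,
    std_elev_cm.
    """
    rows = [
        (rec.ramet_id, rec.site_id, rec.elevation_mm) for rec in collection
    ]
    df = pd.DataFrame(rows, columns=["ramet_id", "site_id", "elev_mm"])
    # median on the raw integer-mm scale, so centering is exact and
    # translation-invariant to the bit; convert the difference to cm
    medians = df.groupby("site_id")["elev_mm"].transform("median")
    df["std_elev_cm"] = (df["elev_mm"] - medians) / 10.0
    return df[["ramet_id", "site_id", "std_elev_cm"]]


# --------------------------------------------------------------------------
# Linear mixed model for elevation
# --------------------------------------------------------------------------

@dataclass
class FTest:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass
class LmmResult:
    """Species and height F-tests from the elevation mixed model."""

    species_test: FTest
    height_test: FTest
    adjusted_means_cm: dict[str, float]
    n_obs: int
    n_sites: int
    n_genets: int
    singular: bool
    df_method: str
    fixed_effects: dict[str, float] = field(default_factory=dict)


def _species_frame(
    collection: StudyCollection,
    include: Sequence[Lineage],
    response: str,
) -> pd.DataFrame:
    std = standardize_elevations(collection).set_index("ramet_id")
    rows = []
    for rec in collection:
        if rec.species_call is None or rec.genet_id is None:
            raise ValueError(
                f"ramet {rec.ramet_id!r} lacks a species call or genet ID; "
                "run classify_collection and infer_genets first"
            )
        if rec.species_call.category not in include:
            continue
        rows.append(
            {
                "ramet_id": rec.ramet_id,
                "site_id": rec.site_id,
                "genet_id": rec.genet_id,
                "species": rec.species_call.category.value,
                "height_cm": rec.shoot_height_cm,
                "elev": (
                    std.loc[rec.ramet_id, "std_elev_cm"]
                    if response == "standardized"
                    else rec.elevation_cm
                ),
            }
        )
    return pd.DataFrame(rows)


def _wald_f(
    res, names: list[str], df_num: int, df_den: int
) -> FTest:
    """Wald chi-square on a set of fixed effects, rescaled to an F."""
    all_names = list(res.model.exog_names)
    idx = [all_names.index(n) for n in names]
    beta = np.asarray(res.fe_params)[idx]
    cov = np.asarray(res.cov_params())[np.ix_(idx, idx)]
    chi2 = float(beta @ np.linalg.solve(cov, beta))
    F = chi2 / df_num
    p = float(scipy.stats.f.sf(F, df_num, df_den))
    return FTest(F=F, df_num=df_num, df_den=max(df_den, 1), p=p)


def fit_elevation_lmm(
    collection: StudyCollection,
    include: Sequence[Lineage] = SPECIES_CATEGORIES,
    response: str = "standardized",
    df_method: str = "containment",
    reference: Lineage = Lineage.PURE_B,
) -> LmmResult:
    """REML mixed model: elevation ~ species + height, (1|site/genet).

    Species is tested with a Wald F whose denominator df follows the
    containment convention by default (species varies at the genet
    level: total genets − sites − species contrasts; height varies at
    the residual level: observations − genets − 1); ``df_method
    ="residual"`` uses observations − fixed parameters for both. A fit
    whose random-effect variances collapse to zero is flagged as
    singular, not fatal.
    """
    if df_method not in ("containment", "residual"):
        raise ValueError(f"unknown df_method {df_method!r}")
    df = _species_frame(collection, include, response)
    counts = df["species"].value_counts()
    for sp, n in counts.items():
        if n < 2:
            logger.warning(
                "species %s has %d observation(s); dropping from LMM", sp, n
            )
            df = df[df["species"] != sp]
    levels = sorted(df["species"].unique())
    if len(levels) < 2:
        raise ValueError(
            f"need >=2 species categories with >=2 observations, "
            f"have {levels}"
        )
    ref = reference.value if reference.value in levels else levels[0]
    formula = f"elev ~ C(species, Treatment('{ref}')) + height_cm"
    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(
            formula,
            df,
            groups="site_id",
            re_formula="1",
            vc_formula={"genet": "0 + C(genet_id)"},
        )
        res = model.fit(reml=True)
        for w in caught:
            msg = str(w.message).lower()
            if "singular" in msg or "boundary" in msg:
                singular = True
    # variance components collapsing to ~0 also count as singular
    vcomp = np.concatenate(
        [np.atleast_1d(np.asarray(res.cov_re)).ravel(), np.atleast_1d(res.vcomp)]
    )
    if np.any(vcomp < 1e-8):
        singular = True

    n_obs = len(df)
    n_sites = df["site_id"].nunique()
    n_genets = df["genet_id"].nunique()
    exog_names = list(res.model.exog_names)
    species_names = [n for n in exog_names if n.startswith("C(species")]
    q = len(species_names)
    p_fixed = len(exog_names)
    if df_method == "containment":
        den_species = max(n_genets - n_sites - q, 1)
        den_height = max(n_obs - n_genets - 1, 1)
    else:
        den_species = den_height = max(n_obs - p_fixed, 1)
    species_test = _wald_f(res, species_names, q, den_species)
    height_test = _wald_f(res, ["height_cm"], 1, den_height)

    mean_height = float(df["height_cm"].mean())
    params = dict(zip(exog_names, np.asarray(res.fe_params)))
    base = params["Intercept"] + params["height_cm"] * mean_height
    adjusted = {ref: base}
    for name in species_names:
        level = name.split("[T.")[1].rstrip("]")
        adjusted[level] = base + params[name]
    return LmmResult(
        species_test=species_test,
        height_test=height_test,
        adjusted_means_cm={k: float(v) for k, v in adjusted.items()},
        n_obs=n_obs,
        n_sites=n_sites,
        n_genets=n_genets,
        singular=singular,
        df_method=df_method,
        fixed_effects={k: float(v) for k, v in params.items()},
    )


# --------------------------------------------------------------------------
# Binomial GLMM for genotypic diversity
# --------------------------------------------------------------------------

@dataclass
class GlmmContrast:
    species: str
    estimate: float
    se: float
    z: float
    p: float


@dataclass
class GlmmResult:
    """Species contrasts in the genets-per-ramets binomial mixed model."""

    reference: str
    contrasts: list[GlmmContrast]
    separation_flag: bool
    method: str


def _expand_binomial(richness_table: pd.DataFrame) -> pd.DataFrame:
    """G-of-n rows to Bernoulli rows (equivalent binomial likelihood)."""
    rows = []
    for _, row in richness_table.iterrows():
        if row["n"] == 0:
            raise ValueError("richness rows must have n >= 1")
        rows.extend(
            {"y": 1, "species": row["species"], "site_id": row["site_id"]}
            for _ in range(int(row["G"]))
        )
        rows.extend(
            {"y": 0, "species": row["species"], "site_id": row["site_id"]}
            for _ in range(int(row["n"]) - int(row["G"]))
        )
    return pd.DataFrame(rows)


def fit_richness_glmm(
    richness_table: pd.DataFrame,
    reference: Lineage = Lineage.PURE_B,
) -> GlmmResult:
    """Binomial-logit mixed model of G successes in n ramets ~ species.

    Site enters as a random intercept (variational Bayes fit; posterior
    mean/SD serve as estimate/SE for the Wald Z). With a single site the
    model reduces to an ordinary binomial GLM. Contrasts are reported
    against the reference species (T. angustifolia by default).
    """
    df = _expand_binomial(richness_table)
    levels = sorted(df["species"].unique())
    if len(levels) < 2:
        raise ValueError("need >=2 species categories for contrasts")
    ref = reference.value if reference.value in levels else levels[0]
    formula = f"y ~ C(species, Treatment('{ref}'))"
    n_sites = df["site_id"].nunique()
    if n_sites == 1:
        glm = smf.glm(formula, df, family=sm.families.Binomial()).fit()
        names = list(glm.model.exog_names)
        est = np.asarray(glm.params)
        se = np.asarray(glm.bse)
        method = "binomial_glm_single_site"
    else:
        # the VB optimizer draws start values from the global numpy RNG;
        # pin them so identical inputs give identical fits
        state = np.random.get_state()
        np.random.seed(0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = BinomialBayesMixedGLM.from_formula(
                    formula, {"site": "0 + C(site_id)"}, df
                )
                fit = model.fit_vb()
        finally:
            np.random.set_state(state)
        names = list(model.exog_names)
        est = np.asarray(fit.fe_mean)
        se = np.asarray(fit.fe_sd)
        method = "binomial_glmm_vb"
    contrasts = []
    for i, name in enumerate(names):
        if not name.startswith("C(species"):
            continue
        level = name.split("[T.")[1].rstrip("]")
        z = float(est[i] / se[i])
        contrasts.append(
            GlmmContrast(
                species=level,
                estimate=float(est[i]),
                se=float(se[i]),
                z=z,
                p=float(2 * scipy.stats.norm.sf(abs(z))),
            )
        )
    separation = any(abs(c.estimate) > 10 for c in contrasts)
    if separation:
        logger.warning("possible complete separation in richness GLMM")
    return GlmmResult(
        reference=ref,
        contrasts=contrasts,
        separation_flag=separation,
        method=method,
    )


# --------------------------------------------------------------------------
# Kolmogorov–Smirnov comparison
# --------------------------------------------------------------------------

@dataclass
class KsResult:
    """Two-sample KS statistic with asymptotic p-value."""

    D: float
    p: float
    n_x: int
    n_y: int
    ties: bool


def ks_compare(x: Sequence[float], y: Sequence[float]) -> KsResult:
    """Two-sample Kolmogorov–Smirnov test.

    D is the maximum absolute difference between the two empirical CDFs,
    evaluated over the pooled sample points; the p-value uses the
    asymptotic Kolmogorov distribution with the standard small-sample
    correction. Ties across samples are reported (the asymptotic p
    assumes continuity).
    """
    xs = np.sort(np.asarray(x, dtype=float))
    ys = np.sort(np.asarray(y, dtype=float))
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([xs, ys])
    cdf_x = np.searchsorted(xs, grid, side="right") / xs.size
    cdf_y = np.searchsorted(ys, grid, side="right") / ys.size
    D = float(np.max(np.abs(cdf_x - cdf_y)))
    m, n = xs.size, ys.size
    en = math.sqrt(m * n / (m + n))
    p = float(scipy.special.kolmogorov((en + 0.12 + 0.11 / en) * D))
    ties = bool(np.intersect1d(xs, ys).size)
    if ties:
        logger.warning(
            "ks_compare: samples share values; asymptotic p assumes "
            "continuous data"
        )
    return KsResult(
        D=D, p=min(max(p, 0.0), 1.0), n_x=m, n_y=n, ties=ties
    )
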