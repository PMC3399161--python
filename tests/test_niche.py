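"""Standardization, mixed models and KS comparisons for niche segregation."""

import math
import random
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, strategies as st

from hybridzone import (
    Lineage,
    StudyCollection,
    classify_collection,
    drop_incomplete,
    fit_elevation_lmm,
    fit_richness_glmm,
    infer_genets,
    ks_compare,
    paper_scale_preset,
    simulate_community_with_key,
    standardize_elevations,
)
from hybridzone.simulate import SimulationConfig


def small_community(seed=11, **overrides):
    d = paper_scale_preset(seed).to_dict()
    d["genotyping_error_rate"] = 0.0
    d.update(overrides)
    cfg = SimulationConfig.from_dict(d)
    collection, truth, key = simulate_community_with_key(cfg)
    collection, _ = drop_incomplete(collection)
    classify_collection(collection, key)
    infer_genets(collection)
    return collection


class TestStandardization:
    def _collection(self, make_ramet, elevations_mm, site="s1"):
        return StudyCollection(
            [
                make_ramet(f"r{i}", (101, 103), site=site, elev_mm=e)
                for i, e in enumerate(elevations_mm)
            ]
        )

    def test_odd_n_median_subtraction(self, make_ramet):
        col = self._collection(make_ramet, [100, 200, 300])  # 10/20/30 cm
        std = standardize_elevations(col)
        assert std["std_elev_cm"].tolist() == [-10.0, 0.0, 10.0]

    def test_single_ramet_site_is_zero(self, make_ramet):
        col = self._collection(make_ramet, [1234])
        assert standardize_elevations(col)["std_elev_cm"].tolist() == [0.0]

    def test_even_n_midpoint_median(self, make_ramet):
        col = self._collection(make_ramet, [100, 200, 300, 400])
        std = standardize_elevations(col)["std_elev_cm"]
        # sort-based oracle: median of even n is the midpoint of the two
        # central order statistics
        vals = sorted([10.0, 20.0, 30.0, 40.0])
        oracle_median = (vals[1] + vals[2]) / 2
        assert oracle_median == 25.0
        assert std.tolist() == [v - oracle_median for v in [10, 20, 30, 40]]

    @given(
        elevations=st.lists(st.integers(-5000, 5000), min_size=1, max_size=9),
        shift=st.integers(-10000, 10000),
    )
    def test_translation_invariance(self, make_ramet, elevations, shift):
        col = self._collection(make_ramet, elevations)
        shifted = self._collection(
            make_ramet, [e + shift for e in elevations]
        )
        a = standardize_elevations(col)["std_elev_cm"].to_numpy()
        b = standardize_elevations(shifted)["std_elev_cm"].to_numpy()
        assert np.allclose(a, b)

    def test_per_site_median_is_zero(self, errorfree_community):
        collection, _, _, _, _ = errorfree_community
        std = standardize_elevations(collection)
        medians = std.groupby("site_id")["std_elev_cm"].median()
        assert np.allclose(medians.to_numpy(), 0.0)


class TestElevationLmm:
    def test_near_zero_random_variance_matches_ols(self):
        import statsmodels.formula.api as smf

        from hybridzone.niche import _species_frame

        col = small_community(
            seed=5,
            elevation={
                "base_cm": 100.0,
                "site_sd_cm": 0.0,
                "offsets_cm": {
                    "pure_A": -3.0,
                    "pure_B": 0.0,
                    "F1": 2.0,
                    "later_gen": 0.0,
                },
                "genet_sd_cm": 0.0,
                "residual_sd_cm": 5.0,
            },
        )
        result = fit_elevation_lmm(col)
        df = _species_frame(
            col, (Lineage.PURE_A, Lineage.PURE_B, Lineage.F1), "standardized"
        )
        ols = smf.ols(
            "elev ~ C(species, Treatment('pure_B')) + height_cm", df
        ).fit()
        # REML still estimates small positive variance components from a
        # finite sample, so GLS weights differ slightly from OLS; the
        # species contrasts (true values -3 and +2 cm) must agree to a
        # fraction of the residual SD and the height slope essentially
        # exactly.
        for name, value in result.fixed_effects.items():
            if name == "Intercept":
                continue
            tol = 0.01 if name == "height_cm" else 0.3
            assert value == pytest.approx(ols.params[name], abs=tol)

    def test_matches_r_nlme_fixed_effects(self, tmp_path):
        """Independent oracle: nlme::lme on the identical data frame."""
        from hybridzone.niche import _species_frame

        rscript = shutil.which("Rscript")
        assert rscript, "Rscript expected on PATH"
        col = small_community(seed=21, n_sites=8)
        df = _species_frame(
            col, (Lineage.PURE_A, Lineage.PURE_B, Lineage.F1), "standardized"
        )
        csv_path = tmp_path / "frame.csv"
        df.to_csv(csv_path, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                library(nlme)
                d <- read.csv("{csv_path}")
                d$species <- relevel(factor(d$species), ref = "pure_B")
                m <- lme(elev ~ species + height_cm,
                         random = ~ 1 | site_id/genet_id,
                         data = d, method = "REML")
                fe <- fixef(m)
                cat(sprintf("%.8f\\n", fe))
                """
            )
        )
        out = subprocess.run(
            [rscript, "--vanilla", str(script)],
            capture_output=True,
            text=True,
            check=True,
        )
        r_fe = [float(x) for x in out.stdout.split()]
        result = fit_elevation_lmm(col)
        names = list(result.fixed_effects)
        # R order: intercept, speciesF1, speciespure_A, height_cm
        ours = [
            result.fixed_effects["Intercept"],
            result.fixed_effects[
                "C(species, Treatment('pure_B'))[T.F1]"
            ],
            result.fixed_effects[
                "C(species, Treatment('pure_B'))[T.pure_A]"
            ],
            result.fixed_effects["height_cm"],
        ]
        assert np.allclose(ours, r_fe, atol=1e-2)

    def test_species_with_single_observation_dropped(
        self, make_ramet, simple_key
    ):
        recs = [
            make_ramet(f"a{i}", (11, 13), elev_mm=1000 + 17 * i)
            for i in range(8)
        ]
        recs += [
            make_ramet(f"b{i}", (21, 23), elev_mm=900 + 23 * i)
            for i in range(8)
        ]
        recs += [make_ramet("f1", (11, 21), elev_mm=1100)]  # lone F1
        for i, r in enumerate(recs):
            r.shoot_height_cm = 100.0 + 3 * i
        col = StudyCollection(recs)
        classify_collection(col, simple_key)
        infer_genets(col)
        result = fit_elevation_lmm(col)
        assert "F1" not in result.adjusted_means_cm
        assert set(result.adjusted_means_cm) == {"pure_A", "pure_B"}

    def test_f_statistics_well_formed(self, errorfree_community):
        collection, _, _, _, _ = errorfree_community
        result = fit_elevation_lmm(collection)
        for test in (result.species_test, result.height_test):
            assert test.F >= 0
            assert test.df_num >= 1 and test.df_den >= 1
            assert 0 <= test.p <= 1
        assert result.species_test.df_num == 2
        assert result.n_obs == sum(
            1
            for r in collection
            if r.species_call.category
            in (Lineage.PURE_A, Lineage.PURE_B, Lineage.F1)
        )

    def test_residual_df_convention(self, errorfree_community):
        collection, _, _, _, _ = errorfree_community
        result = fit_elevation_lmm(collection, df_method="residual")
        assert result.species_test.df_den == result.n_obs - 4

    def test_unknown_df_method_rejected(self, errorfree_community):
        collection, _, _, _, _ = errorfree_community
        with pytest.raises(ValueError, match="df_method"):
            fit_elevation_lmm(collection, df_method="satterthwaite")


class TestRichnessGlmm:
    def test_single_site_reduces_to_analytic_glm(self):
        table = pd.DataFrame(
            [
                {"species": "pure_B", "site_id": "s1", "G": 4, "n": 10,
                 "R": 1 / 3},
                {"species": "pure_A", "site_id": "s1", "G": 8, "n": 10,
                 "R": 7 / 9},
            ]
        )
        result = fit_richness_glmm(table)
        assert result.method == "binomial_glm_single_site"
        contrast = result.contrasts[0]
        # analytic log-odds difference
        expected = math.log((8 / 2) / (4 / 6))
        assert contrast.estimate == pytest.approx(expected, abs=1e-6)
        assert contrast.z == pytest.approx(
            contrast.estimate / contrast.se, abs=1e-12
        )

    def test_identical_ratios_give_small_contrasts(self):
        rows = []
        for s in range(6):
            for sp in ("pure_A", "pure_B", "F1"):
                rows.append(
                    {"species": sp, "site_id": f"s{s}", "G": 3, "n": 10,
                     "R": 2 / 9}
                )
        result = fit_richness_glmm(pd.DataFrame(rows))
        for c in result.contrasts:
            assert abs(c.estimate) < 0.5
            assert abs(c.z) < 1.5
            assert c.p > 0.05

    def test_reference_level_is_pure_b(self, errorfree_community):
        from hybridzone import richness_by_species_site

        collection, _, _, _, genets = errorfree_community
        table, _ = richness_by_species_site(collection, genets)
        result = fit_richness_glmm(table)
        assert result.reference == "pure_B"
        assert {c.species for c in result.contrasts} == {"pure_A", "F1"}

    def test_zero_n_rows_rejected(self):
        table = pd.DataFrame(
            [{"species": "pure_A", "site_id": "s1", "G": 0, "n": 0, "R": 0}]
        )
        with pytest.raises(ValueError):
            fit_richness_glmm(table)

    def test_single_species_rejected(self):
        table = pd.DataFrame(
            [{"species": "pure_A", "site_id": "s1", "G": 2, "n": 5, "R": 0.25}]
        )
        with pytest.raises(ValueError, match=">=2 species"):
            fit_richness_glmm(table)


def ecdf_oracle(x, y):
    """Exhaustive-ECDF KS statistic: evaluate both ECDFs at every point."""
    points = sorted(set(x) | set(y))
    best = 0.0
    for t in points:
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best


class TestKsCompare:
    def test_identical_samples_d_zero(self):
        r = ks_compare([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert r.D == 0.0 and r.p == 1.0

    def test_disjoint_supports_d_one(self):
        r = ks_compare([1, 2, 3], [10, 11, 12])
        assert r.D == 1.0

    def test_small_sample_against_ecdf_oracle(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        r = ks_compare(x, y)
        assert r.D == pytest.approx(ecdf_oracle(x, y), abs=1e-12)
        assert r.ties

    def test_random_samples_match_oracle_and_scipy(self):
        rng = random.Random(13)
        for _ in range(100):
            x = [rng.gauss(0, 1) for _ in range(rng.randint(2, 15))]
            y = [rng.gauss(0.3, 1.2) for _ in range(rng.randint(2, 15))]
            r = ks_compare(x, y)
            assert r.D == pytest.approx(ecdf_oracle(x, y), abs=1e-12)
            assert r.D == pytest.approx(
                scipy.stats.ks_2samp(x, y).statistic, abs=1e-12
            )

    def test_symmetry(self):
        rng = random.Random(29)
        x = [rng.gauss(0, 1) for _ in range(9)]
        y = [rng.gauss(1, 2) for _ in range(6)]
        assert ks_compare(x, y).D == ks_compare(y, x).D

    def test_invariance_under_monotone_transform(self):
        rng = random.Random(31)
        x = [rng.uniform(0.1, 5) for _ in range(10)]
        y = [rng.uniform(0.5, 6) for _ in range(8)]
        d_raw = ks_compare(x, y).D
        d_log = ks_compare(np.log(x), np.log(y)).D
        assert d_raw == pytest.approx(d_log, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ks_compare([], [1.0])

    def test_asymptotic_p_close_to_scipy(self):
        rng = random.Random(37)
        x = [rng.gauss(0, 1) for _ in range(60)]
        y = [rng.gauss(0.4, 1) for _ in range(50)]
        r = ks_compare(x, y)
        p_ref = scipy.stats.ks_2samp(x, y, method="asymp").pvalue
        assert r.p == pytest.approx(p_ref, abs=0.05)
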