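import pytest
from hypothesis import HealthCheck, settings

from hybridzone import (
    DEFAULT_LOCI,
    DiagnosticKey,
    MultilocusGenotype,
    RametRecord,
    StudyCollection,
    classify_collection,
    drop_incomplete,
    infer_genets,
    paper_scale_preset,
    simulate_community_with_key,
)
from hybridzone.simulate import SimulationConfig

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def simple_key() -> DiagnosticKey:
    """Fully diagnostic key: alleles 11/13 private to A, 21/23 to B."""
    return DiagnosticKey(
        private_a={l: frozenset({11, 13}) for l in DEFAULT_LOCI},
        private_b={l: frozenset({21, 23}) for l in DEFAULT_LOCI},
    )


@pytest.fixture
def make_genotype():
    """Build a genotype from one pair applied to all loci, or per-locus pairs."""

    def _make(pair=None, per_locus=None, loci=DEFAULT_LOCI):
        if per_locus is None:
            per_locus = {l: pair for l in loci}
        return MultilocusGenotype(
            {l: per_locus.get(l, pair) for l in loci}
        )

    return _make


@pytest.fixture
def make_ramet(make_genotype):
    def _make(ramet_id, pair=None, site="s1", elev_mm=1000, height=150.0,
              per_locus=None):
        return RametRecord(
            ramet_id=ramet_id,
            site_id=site,
            elevation_mm=elev_mm,
            shoot_height_cm=height,
            genotype=make_genotype(pair=pair, per_locus=per_locus),
        )

    return _make


def errorfree_config(seed: int) -> SimulationConfig:
    d = paper_scale_preset(seed).to_dict()
    d["genotyping_error_rate"] = 0.0
    return SimulationConfig.from_dict(d)


@pytest.fixture(scope="session")
def errorfree_community():
    """Preset-scale community with error rate 0, classified + genet-inferred."""
    collection, truth, key = simulate_community_with_key(errorfree_config(7))
    collection, _ = drop_incomplete(collection)
    calls = classify_collection(collection, key)
    genets = infer_genets(collection)
    return collection, truth, key, calls, genets
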