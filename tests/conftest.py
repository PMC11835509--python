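import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tetracross as tc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_founders() -> tc.HaplotypeSet:
    """Compact founder panel: 16 clones, 3 chromosomes, 50 markers each."""
    return tc.generate_founders(
        n_founders=16, n_chrom=3, markers_per_chrom=50, seed=11
    )


@pytest.fixture(scope="session")
def arch_none(small_founders) -> tc.TraitArchitecture:
    return tc.sample_architecture(40, small_founders, seed=5, dominance_scale="none")


@pytest.fixture(scope="session")
def arch_strong(small_founders) -> tc.TraitArchitecture:
    return tc.sample_architecture(40, small_founders, seed=5, dominance_scale="strong")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(202)


def single_locus_parent(dosage: int) -> tuple[np.ndarray, tc.GeneticMap]:
    """A one-marker parent carrying ``dosage`` copies of allele 1."""
    gmap = tc.GeneticMap(np.array([1]), np.array([1000]), np.array([0.0]))
    hap = np.zeros((4, 1), dtype=np.uint8)
    hap[:dosage, 0] = 1
    return hap, gmap
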