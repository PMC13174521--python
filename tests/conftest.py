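import pytest

from dsakit.synthetic_data import (
    GenomeConfig,
    SomaticConfig,
    build_normal_genome,
    derive_tumor_genome,
)

SMALL_CONFIG = GenomeConfig(
    n_autosome_mimics=1,
    n_acrocentric_mimics=2,
    chrom_length=80_000,
    array_length=60 * 171,
    rdna_copies_per_arm=4,
    dj_unit_length=2_000,
    seed=7,
)


@pytest.fixture(scope="session")
def small_normal():
    return build_normal_genome(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_tumor_pair(small_normal):
    return derive_tumor_genome(small_normal, SomaticConfig(seed=7))


@pytest.fixture(scope="session")
def default_normal():
    return build_normal_genome(GenomeConfig(seed=11))
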