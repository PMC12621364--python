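"""Shared fixtures: one small synthetic trio reused across test modules."""

import pytest

from panmeth.config import TrioConfig
from panmeth.methio import united_profiles
from panmeth.simulate import simulate_trio


@pytest.fixture(scope="session")
def small_trio():
    """50 kb trio with annotations and methylomes (seed 1)."""
    cfg = TrioConfig(chrom_length=50_000, seed=1)
    truth, methylomes = simulate_trio(cfg)
    return cfg, truth, methylomes


@pytest.fixture(scope="session")
def small_profiles(small_trio):
    _, _, methylomes = small_trio
    return united_profiles(methylomes)
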