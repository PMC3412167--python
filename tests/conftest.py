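import numpy as np
import pytest

from gelpkit.synthetic import FamilySimConfig, simulate_family


@pytest.fixture(scope="session")
def small_config():
    """A 12-member family at mild divergence — shared, read-only."""
    return FamilySimConfig(
        n_taxa=12,
        block_sub_prob=0.02,
        planted_motifs=[("WYHKQFM", 7, "cladeA"), ("CRGPLIV", 7, "cladeB")],
        cluster_specs=[(3, [2, 4])],
        tandem_specs=[(2, 0.8)],
        segmental_pairs=1,
        n_decoy_proteins=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_family(small_config):
    return simulate_family(small_config)


@pytest.fixture(scope="session")
def zero_noise_family():
    """Zero block divergence, zero CT noise: exact-recovery conditions."""
    cfg = FamilySimConfig(
        n_taxa=12,
        block_sub_prob=0.0,
        ct_noise_sd=0.0,
        planted_motifs=[("WYHKQFM", 7, "cladeA"), ("CRGPLIV", 7, "cladeB")],
        cluster_specs=[(3, [2, 4])],
        tandem_specs=[(2, 0.8)],
        segmental_pairs=1,
        n_decoy_proteins=10,
        seed=11,
    )
    return simulate_family(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
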