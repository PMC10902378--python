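import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mlde.encoding import default_property_table, encode_variant
from mlde.synthetic import make_landscape, random_variants, true_activity

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FIVE_SITES = (174, 238, 241, 242, 245)


def parent_seq_for(landscape, length=300):
    """A parent sequence consistent with a landscape's parent residues."""
    seq = ["A"] * max(length, max(landscape.sites))
    for site in landscape.sites:
        seq[site - 1] = landscape.parent_residues[site]
    return "".join(seq)


def landscape_xy(landscape, n, seed, table, noise_sd=0.0):
    """Encoded features and (optionally noisy) true-activity labels."""
    sites = list(landscape.sites)
    pseq = parent_seq_for(landscape)
    variants = random_variants(landscape, n, seed=seed)
    X = np.vstack([encode_variant(v, sites, table, pseq) for v in variants])
    y = np.array([true_activity(landscape, v) for v in variants])
    if noise_sd > 0:
        y = y + np.random.default_rng(seed + 10_000).normal(0.0, noise_sd, n)
    return variants, X, y


@pytest.fixture(scope="session")
def aa_table():
    return default_property_table()


@pytest.fixture(scope="session")
def five_site_landscape():
    """Descriptor-linear additive landscape over the five cavity/tunnel sites."""
    return make_landscape(
        FIVE_SITES,
        "ACDEFGHIKLMNPQRSTVWY",
        effect_sd=0.5,
        seed=11,
        effect_model="descriptor_linear",
    )
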