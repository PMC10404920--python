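import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", message="ArviZ is undergoing a major refactor")

from avcue import DesignConfig, make_design  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def design_config():
    return DesignConfig(seed=42)


@pytest.fixture(scope="session")
def default_design(design_config):
    return make_design(design_config)


def make_conflict_data(n, w_p, w_v, sigma_n, seed, locations=(0.37, 0.43, 0.5, 0.57, 0.63)):
    """Model-generated conflict trials: (x_v, x_a, r) arrays of length ~n."""
    rng = np.random.default_rng(seed)
    locs = np.asarray(locations)
    x_v = rng.choice(locs, size=2 * n)
    x_a = rng.choice(locs, size=2 * n)
    keep = x_v != x_a
    x_v, x_a = x_v[keep][:n], x_a[keep][:n]
    mu = (1 - w_p) * (w_v * x_v + (1 - w_v) * x_a) + 0.5 * w_p
    r = mu + rng.normal(0.0, sigma_n, size=x_v.size)
    return x_v, x_a, r


def make_switching_data(n, w_p, w_v, sigma_n, p_switch, seed,
                        locations=(0.37, 0.43, 0.5, 0.57, 0.63)):
    """Conflict trials from the averaging/switching mixture."""
    rng = np.random.default_rng(seed)
    locs = np.asarray(locations)
    x_v = rng.choice(locs, size=2 * n)
    x_a = rng.choice(locs, size=2 * n)
    keep = x_v != x_a
    x_v, x_a = x_v[keep][:n], x_a[keep][:n]
    ct = 0.5 * w_p
    mu_avg = (1 - w_p) * (w_v * x_v + (1 - w_v) * x_a) + ct
    mu_v = (1 - w_p) * x_v + ct
    mu_a = (1 - w_p) * x_a + ct
    switch = rng.random(x_v.size) < p_switch
    pick_v = rng.random(x_v.size) < w_v
    mu = np.where(switch, np.where(pick_v, mu_v, mu_a), mu_avg)
    return x_v, x_a, mu + rng.normal(0.0, sigma_n, size=x_v.size)
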