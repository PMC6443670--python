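import numpy as np
import pytest

from dvscale.synthetic import SyntheticConfig, generate_population


@pytest.fixture(scope="session")
def noise_free_config():
    """Generator config with every stochastic intensity component off."""
    return SyntheticConfig(
        n_embryos_per_group=4,
        noise_sd=0.0,
        a_cv=0.0,
        background_mean=0.0,
        background_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noise_free_population(noise_free_config):
    return generate_population(noise_free_config, "WT")


@pytest.fixture(scope="session")
def default_population():
    """Small population under the default (calibrated-noise) conditions."""
    cfg = SyntheticConfig(n_embryos_per_group=6, seed=7)
    return generate_population(cfg, "WT")


def make_ring(
    radius: float = 200.0,
    n: int = 360,
    jitter: float = 0.0,
    seed: int = 0,
    intensity=None,
):
    """A circle of points in the xy-plane with optional positional jitter."""
    rng = np.random.default_rng(seed)
    theta = np.linspace(-np.pi, np.pi, n, endpoint=False)
    xyz = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)]
    )
    if jitter > 0:
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        r = jitter * rng.uniform(0, 1, n) ** (1 / 3)
        xyz = xyz + d * r[:, None]
    if intensity is None:
        inten = np.ones(n)
    else:
        inten = intensity(np.degrees(theta))
    return xyz, inten
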