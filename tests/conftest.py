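import numpy as np
import pytest

from kgp.synthetic_data import SimConfig, TraitConfig, simulate_dataset


def small_config(**overrides) -> SimConfig:
    """A reduced population: 12 families, 180 offspring, 300 markers."""
    base = dict(
        n_sires=6,
        n_dams=10,
        n_families=12,
        n_offspring=180,
        family_size_range=(3, 60),
        n_markers=300,
        missing_rate=0.148,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def single_trait_config(h2: float, **overrides) -> SimConfig:
    """Small population carrying one marker-mode trait of given h²."""
    cfg = small_config(**overrides)
    cfg.traits = {"weight": TraitConfig(mean=3.0, sd=0.35, h2=h2, stock_effect=0.1)}
    cfg.binary_traits = {}
    return cfg
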