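import numpy as np
import pytest

from mmnet import (
    GeneratorConfig,
    build_classifications,
    simulate_population,
    simulate_response_mmmc,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small structured population with a response under the full model."""
    cfg = GeneratorConfig(n=300, seed=42)
    ds = simulate_population(cfg)
    menu = build_classifications(ds, ("school", "area", "egonet"))
    simulate_response_mmmc(
        ds,
        [(k, menu[k]) for k in ("school", "area", "egonet")],
        beta=cfg.beta,
        variance_components={
            "school": cfg.sigma2_school,
            "area": cfg.sigma2_area,
            "egonet": cfg.sigma2_net,
        },
        sigma2_e=cfg.sigma2_e,
        seed=43,
    )
    ds._menu = menu
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(20260301)
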