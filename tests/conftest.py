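"""Shared fixtures: hand-built miniature webs and one generated community."""

import numpy as np
import pytest

from multiweb import (
    ModelConfig,
    MultiplexNetwork,
    SpeciesTraits,
    TrophicWeb,
    assign_traits,
    build_model_params,
    build_nti_state,
    generate_niche_web,
)


def make_web(adjacency, niche=None) -> TrophicWeb:
    A = np.asarray(adjacency, dtype=bool)
    S = A.shape[0]
    is_plant = ~A.any(axis=1)
    niche = np.linspace(0.1, 0.9, S) if niche is None else np.asarray(niche)
    return TrophicWeb(S=S, adjacency=A, is_plant=is_plant, niche_values=niche)


def make_traits(web, sessile=None, TL=None, mass=None, TL_shortest=None):
    S = web.S
    sessile = np.zeros(S, bool) if sessile is None else np.asarray(sessile, bool)
    TL = np.ones(S) if TL is None else np.asarray(TL, float)
    mass = np.ones(S) if mass is None else np.asarray(mass, float)
    return SpeciesTraits(is_sessile=sessile, TL=TL, mass=mass,
                         TL_shortest=TL_shortest)


@pytest.fixture
def config():
    return ModelConfig()


@pytest.fixture
def isolated_plant(config):
    """One plant, no links: logistic growth minus mortality."""
    web = make_web([[0]])
    traits = make_traits(web)
    params = build_model_params(web, traits, config)
    nti = build_nti_state(params, None, config)
    return web, traits, params, nti


@pytest.fixture
def chain_network(config):
    """Plant -> herbivore -> carnivore chain with allometric masses."""
    web = make_web([[0, 0, 0],
                    [1, 0, 0],
                    [0, 1, 0]])
    traits = make_traits(web, TL=[1.0, 2.0, 3.0],
                         mass=[1.0, 50.0, 2500.0],
                         TL_shortest=np.array([1.0, 2.0, 3.0]))
    params = build_model_params(web, traits, config)
    return web, traits, params


@pytest.fixture(scope="session")
def std_network():
    """One generated 100-species community (fixed seed)."""
    cfg = ModelConfig()
    rng = np.random.default_rng(20240901)
    web = generate_niche_web(cfg.S, cfg.connectance, cfg.n_plants, rng)
    traits = assign_traits(web, cfg, rng)
    return MultiplexNetwork(web=web, traits=traits, layers={})


@pytest.fixture(scope="session")
def std_params(std_network):
    cfg = ModelConfig()
    params = build_model_params(std_network.web, std_network.traits, cfg)
    nti0 = build_nti_state(params, None, cfg)
    return params, nti0
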