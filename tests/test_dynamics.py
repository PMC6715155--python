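"""Rate assembly and the NTI-modified right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multiweb import (
    ModelConfig,
    NTIState,
    build_model_params,
    build_nti_state,
    competition_factor,
    effective_attack,
    effective_growth,
    effective_mortality,
    functional_response,
    net_growth,
    rhs,
)
from multiweb.generation import draw_nti_layer

from .conftest import make_traits, make_web


class TestParamAssembly:
    def test_plant_scalings_at_unit_mass(self, isolated_plant):
        _, _, params, _ = isolated_plant
        assert params.r[0] == pytest.approx(1.0)
        assert params.K[0] == pytest.approx(1.0)
        assert params.x[0] == 0.0
        assert params.d[0] == pytest.approx(0.0138)

    def test_consumer_scalings(self, chain_network):
        _, _, params = chain_network
        m = 50.0
        assert params.r[1] == 0.0
        assert params.x[1] == pytest.approx(0.314 * m ** -0.25)
        assert params.d[1] == pytest.approx(0.1 * 0.314 * m ** -0.25)
        # mobile herbivore on mobile plant
        assert params.a_base[1, 0] == pytest.approx(50.0 * m ** 0.45)
        assert params.a_base[1, 0] == pytest.approx(290.7, abs=0.1)
        assert params.h[1, 0] == pytest.approx(0.3 * m ** -0.48)
        assert params.h[1, 0] == pytest.approx(0.0459, abs=1e-4)

    def test_relative_consumption_is_inverse_diet_size(self, config):
        web = make_web([[0] * 5,
                        [0] * 5,
                        [0] * 5,
                        [0] * 5,
                        [1, 1, 1, 1, 0]])
        params = build_model_params(web, make_traits(web), config)
        assert params.w[4] == pytest.approx(0.25)

    def test_efficiency_depends_on_resource_type(self, config):
        # consumer 2 eats plant 0 and consumer 1
        web = make_web([[0, 0, 0],
                        [1, 0, 0],
                        [1, 1, 0]])
        params = build_model_params(web, make_traits(web), config)
        assert params.eps[2, 0] == 0.45
        assert params.eps[2, 1] == 0.85
        assert params.eps[0, 2] == 0.0

    def test_sessile_species_drop_their_mass_factor(self, config):
        web = make_web([[0, 0], [1, 0]])
        masses = [2.0, 80.0]
        for cons_sess, res_sess, expected in [
            (False, False, 50.0 * 80.0 ** 0.45 * 2.0 ** 0.15),
            (True, False, 50.0 * 2.0 ** 0.15),
            (False, True, 50.0 * 80.0 ** 0.45),
            (True, True, 50.0),
        ]:
            traits = make_traits(web, sessile=[res_sess, cons_sess], mass=masses)
            params = build_model_params(web, traits, config)
            assert params.a_base[1, 0] == pytest.approx(expected)

    def test_unit_expo_collapses_allometries(self, config):
        web = make_web([[0, 0], [1, 0]])
        traits = make_traits(web, TL=[1.0, 2.0], mass=[1.0, 1.0])
        params = build_model_params(web, traits, config)
        assert params.r[0] == config.r0
        assert params.K[1] == config.K0
        assert params.a_base[1, 0] == config.a0
        assert params.h[1, 0] == config.h0


class TestNTIRates:
    def test_refuge_scales_attack_towards_zero(self, chain_network):
        web, traits, params = chain_network
        cfg = ModelConfig()
        phi = np.zeros((3, 3))
        phi[0, 1] = 1.0    # plant shelters the herbivore
        nti = NTIState.empty(3)
        nti.phi = phi
        nti.r0_refuge = 1.75
        B = np.array([1.0, 1.0, 1.0])
        a = effective_attack(params, nti, B)
        assert a[2, 1] == pytest.approx(params.a_base[2, 1] / 2.75)
        assert a[2, 1] / params.a_base[2, 1] == pytest.approx(0.3636, abs=1e-4)
        # unprotected link unchanged
        assert a[1, 0] == params.a_base[1, 0]
        # facilitator biomass -> infinity drives the attack to zero
        a_inf = effective_attack(params, nti, np.array([1e12, 1.0, 1.0]))
        assert a_inf[2, 1] < 1e-9 * params.a_base[2, 1]

    def test_mortality_modifiers(self, chain_network):
        _, _, params = chain_network
        nti = NTIState.empty(3)
        B = np.ones(3)
        assert np.allclose(effective_mortality(params, nti, B), params.d)
        nti.n_mat = np.zeros((3, 3)); nti.n_mat[0, 1] = 1.0
        nti.n0 = 3.0
        assert effective_mortality(params, nti, B)[1] == pytest.approx(4 * params.d[1])
        nti.n0 = 0.0
        nti.p_mat = np.zeros((3, 3)); nti.p_mat[0, 1] = 1.0
        nti.p0 = 20.0
        assert effective_mortality(params, nti, B)[1] == pytest.approx(params.d[1] / 21)

    def test_recruitment_multiplies_plant_growth_only(self, chain_network):
        _, _, params = chain_network
        nti = NTIState.empty(3)
        nti.eta = np.zeros((3, 3)); nti.eta[1, 0] = 1.0
        nti.e0 = 1.8
        r_new = effective_growth(params, nti, np.ones(3))
        assert r_new[0] == pytest.approx(2.8 * params.r[0])
        assert r_new[1] == 0.0 and r_new[2] == 0.0


class TestFunctionalResponse:
    def test_zero_prey_biomass_means_zero_feeding(self, chain_network):
        _, _, params = chain_network
        nti = NTIState.empty(3)
        F = functional_response(params, nti, np.array([0.0, 0.0, 1.0]))
        assert np.all(F[2] == 0.0)

    def test_single_prey_matches_scalar_formula(self, chain_network):
        """Independent scalar evaluation of the one-prey response."""
        _, _, params = chain_network
        nti = NTIState.empty(3, i0_intra=0.0)
        B = np.array([0.7, 0.4, 0.2])
        F = functional_response(params, nti, B)
        a, h, m, q = params.a_base[1, 0], params.h[1, 0], params.m[1], params.q
        expected = a * B[0] ** (1 + q) / (m * (1 + a * h * B[0] ** (1 + q)))
        assert F[1, 0] == pytest.approx(expected, rel=1e-12)

    def test_zero_off_the_adjacency(self, std_params):
        params, nti = std_params
        rng = np.random.default_rng(0)
        F = functional_response(params, nti, rng.uniform(0, 1, params.S))
        assert np.all(F >= 0.0)
        assert not F[~params.adjacency].any()

    def test_interference_reduces_feeding(self, config):
        # two equal-mass predators (1, 2) share prey 0
        web = make_web([[0, 0, 0],
                        [1, 0, 0],
                        [1, 0, 0]])
        traits = make_traits(web, TL=[1, 2, 2], mass=[1.0, 50.0, 50.0])
        params = build_model_params(web, traits, config)
        layer_presence = np.zeros((3, 3), bool)
        layer_presence[1, 2] = layer_presence[2, 1] = True
        nti = NTIState.empty(3)
        nti.delta = layer_presence.astype(float)   # equal masses: delta = 1
        nti.i0 = 3.0
        B = np.array([0.8, 0.3, 0.3])
        F1 = functional_response(params, nti, B)[1, 0]
        B2 = np.array([0.8, 0.3, 0.6])             # competitor doubled
        F2 = functional_response(params, nti, B2)[1, 0]
        assert F2 < F1

    def test_monotone_in_interference_intensity(self, std_network, std_params):
        params, _ = std_params
        cfg = ModelConfig()
        layer = draw_nti_layer(std_network.web, std_network.traits,
                               "interference", 0.15, 0.0,
                               np.random.default_rng(8))
        B = np.random.default_rng(1).uniform(0.1, 1.0, params.S)
        last = None
        for i0 in (0.0, 1.0, 3.0):
            nti = build_nti_state(params, {"interference": layer}, cfg,
                                  {"interference": i0})
            F = functional_response(params, nti, B)
            if last is not None:
                assert np.all(F <= last + 1e-15)
            last = F


class TestCompetitionFactor:
    def test_factor_value_and_growth_switch(self, config):
        web = make_web([[0, 0], [0, 0]])
        traits = make_traits(web, sessile=[1, 1], mass=[1.0, 50.0])
        params = build_model_params(web, traits, config)
        nti = NTIState.empty(2)
        gamma = np.zeros((2, 2))
        gamma[1, 0] = 50.0 ** (2.0 / 3.0)   # heavy competitor affects plant 0
        nti.gamma = gamma
        nti.c0 = 0.012
        B = np.ones(2)
        g = competition_factor(params, nti, B, net_growth_rate=np.array([1.0, 1.0]))
        assert g[0] == pytest.approx(1 - 0.012 * 50 ** (2 / 3))
        assert g[0] == pytest.approx(0.8371, abs=2e-4)
        assert g[1] == 1.0
        # competition switches off when net growth is negative
        g_neg = competition_factor(params, nti, B, net_growth_rate=np.array([-0.1, 1.0]))
        assert g_neg[0] == 1.0


class TestRHS:
    def test_isolated_plant_at_carrying_capacity(self, isolated_plant):
        _, _, params, nti = isolated_plant
        dB = rhs(params, nti, np.array([1.0]))
        assert dB[0] == pytest.approx(-0.0138)

    def test_isolated_plant_equilibrium_is_stationary(self, isolated_plant):
        _, _, params, nti = isolated_plant
        Bstar = params.K[0] * (1 - params.d[0] / params.r[0])
        assert Bstar == pytest.approx(0.9862)
        assert rhs(params, nti, np.array([Bstar]))[0] == pytest.approx(0.0, abs=1e-14)

    def test_zero_intensities_reduce_to_trophic_model(self, std_network, std_params):
        """With all six intensities zero the multiplex RHS is bitwise equal
        to the purely trophic one, even with layers present."""
        params, nti0 = std_params
        cfg = ModelConfig()
        rng = np.random.default_rng(4)
        layers = {t: draw_nti_layer(std_network.web, std_network.traits, t,
                                    0.1, 0.0, rng)
                  for t in ("competition", "interference", "refuge",
                            "recruitment", "mortality_increase",
                            "mortality_decrease")}
        nti_z = build_nti_state(params, layers, cfg)   # intensities all 0
        B = rng.uniform(0.05, 1.0, params.S)
        assert np.array_equal(rhs(params, nti_z, B), rhs(params, nti0, B))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_extinct_species_stay_extinct(self, seed):
        """B = 0 is absorbing: the derivative of any extinct species is 0."""
        cfg = ModelConfig()
        web = make_web([[0, 0, 0],
                        [1, 0, 0],
                        [1, 1, 0]])
        traits = make_traits(web, TL=[1, 2, 2.5], mass=[1.0, 50.0, 353.6])
        params = build_model_params(web, traits, cfg)
        nti = NTIState.empty(3)
        rng = np.random.default_rng(seed)
        B = rng.uniform(0, 1, 3)
        dead = rng.uniform(size=3) < 0.5
        B[dead] = 0.0
        dB = rhs(params, nti, B)
        assert np.all(dB[dead] == 0.0)

    def test_non_finite_biomass_rejected(self, isolated_plant):
        _, _, params, nti = isolated_plant
        with pytest.raises(ValueError):
            rhs(params, nti, np.array([np.nan]))
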