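"""Niche-model webs, traits and NTI layer drawing."""

import networkx as nx
import numpy as np
import pytest

from multiweb import (
    ModelConfig,
    assign_body_masses,
    assign_mobility,
    assign_traits,
    compute_shortest_trophic_levels,
    compute_trophic_levels,
    draw_nti_layer,
    eligible_pairs,
    eligibility_matrix,
    generate_multiplex,
    generate_niche_web,
    validate_connected_plants,
)
from multiweb.config import DEFAULT_NTI_PROBABILITIES, NTI_TYPES

from .conftest import make_traits, make_web


class TestNicheWeb:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_constraints_hold_on_accepted_webs(self, seed):
        rng = np.random.default_rng(seed)
        web = generate_niche_web(100, 0.06, 20, rng)
        assert web.S == 100
        assert web.n_plants == 20
        # plants have no resources at all
        assert not web.adjacency[web.is_plant].any()
        # every consumer has a non-self resource
        A = web.adjacency.copy()
        np.fill_diagonal(A, False)
        assert A[~web.is_plant].any(axis=1).all()
        # no species is isolated
        assert (A.any(axis=0) | A.any(axis=1)).all()
        # acyclic apart from self-loops (independent check via networkx)
        G = nx.DiGraph(A)
        assert nx.is_directed_acyclic_graph(G)

    def test_realized_connectance_near_target(self):
        rng = np.random.default_rng(7)
        links = [generate_niche_web(100, 0.06, 20, rng).n_links
                 for _ in range(200)]
        assert abs(np.mean(links) / 600.0 - 1.0) < 0.05

    def test_minimal_two_species_web(self):
        rng = np.random.default_rng(0)
        web = generate_niche_web(2, 0.26, 1, rng)
        assert web.n_plants == 1
        plant = int(np.flatnonzero(web.is_plant)[0])
        consumer = 1 - plant
        assert web.adjacency[consumer, plant]

    def test_seeded_generation_is_reproducible(self):
        cfg = ModelConfig()
        nets = [generate_multiplex(cfg, np.random.default_rng(99))
                for _ in range(2)]
        assert np.array_equal(nets[0].web.adjacency, nets[1].web.adjacency)
        assert np.array_equal(nets[0].traits.is_sessile, nets[1].traits.is_sessile)
        for t in NTI_TYPES:
            assert np.array_equal(nets[0].layers[t].presence,
                                  nets[1].layers[t].presence)

    def test_invalid_arguments_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            generate_niche_web(1, 0.1, 1, rng)
        with pytest.raises(ValueError):
            generate_niche_web(10, 0.0, 2, rng)
        with pytest.raises(ValueError):
            generate_niche_web(10, 0.1, 10, rng)


class TestTrophicLevels:
    def test_known_small_webs(self):
        # consumer 2 eats both plants -> TL 2; consumer 3 eats plant 0 and
        # consumer 2 -> TL 2.5
        web = make_web([[0, 0, 0, 0],
                        [0, 0, 0, 0],
                        [1, 1, 0, 0],
                        [1, 0, 1, 0]])
        TL = compute_trophic_levels(web)
        assert TL == pytest.approx([1.0, 1.0, 2.0, 2.5])
        sTL = compute_shortest_trophic_levels(web)
        assert sTL == pytest.approx([1.0, 1.0, 2.0, 2.0])

    def test_self_loop_excluded_from_diet_mean(self):
        web = make_web([[0, 0], [1, 1]])   # cannibal herbivore
        assert compute_trophic_levels(web) == pytest.approx([1.0, 2.0])

    def test_plants_are_level_one_in_generated_webs(self, std_network):
        TL = std_network.traits.TL
        plants = std_network.web.is_plant
        assert np.all(TL[plants] == 1.0)
        assert np.all(TL[~plants] >= 2.0)

    def test_consumer_without_resources_is_an_error(self):
        web = make_web([[0, 0], [0, 0]])
        web.is_plant[1] = False   # declare species 1 a consumer
        with pytest.raises(ValueError):
            compute_trophic_levels(web)


class TestTraits:
    def test_body_mass_scaling(self):
        m = assign_body_masses(np.array([1.0, 2.0, 2.5]), 50.0)
        assert m == pytest.approx([1.0, 50.0, 50.0 ** 1.5])
        assert m[2] == pytest.approx(353.553, abs=1e-3)

    def test_mobility_rejection_hits_exact_count(self, std_network):
        web = std_network.web
        for seed in range(5):
            sessile = assign_mobility(web, 33, 0.8, 0.2,
                                      np.random.default_rng(seed))
            assert int(sessile.sum()) == 33

    def test_deterministic_mobility_first_try(self, std_network):
        web = std_network.web
        sessile = assign_mobility(web, web.n_plants, 1.0, 0.0,
                                  np.random.default_rng(0))
        assert np.array_equal(sessile, web.is_plant)

    def test_assign_traits_masses_follow_shortest_levels(self, std_network):
        tr = std_network.traits
        assert np.allclose(tr.mass, 50.0 ** (tr.TL_shortest - 1.0))


class TestEligibility:
    def test_competition_pairs_are_ordered_sessile_pairs(self, std_network):
        pairs = eligible_pairs(std_network.web, std_network.traits, "competition")
        assert len(pairs) == 33 * 32
        sess = np.flatnonzero(std_network.traits.is_sessile)
        assert all(s in sess and t in sess and s != t for s, t in pairs)

    def test_interference_requires_shared_prey(self):
        # two mobile consumers with disjoint diets: no eligible pair
        web = make_web([[0, 0, 0, 0],
                        [0, 0, 0, 0],
                        [1, 0, 0, 0],
                        [0, 1, 0, 0]])
        traits = make_traits(web, sessile=[1, 1, 0, 0])
        assert eligible_pairs(web, traits, "interference") == set()
        # give them a common prey
        web2 = make_web([[0, 0, 0, 0],
                         [0, 0, 0, 0],
                         [1, 1, 0, 0],
                         [0, 1, 0, 0]])
        assert eligible_pairs(web2, traits, "interference") == {(2, 3)}

    def test_recruitment_targets_are_exactly_the_plants(self, std_network):
        elig = eligibility_matrix(std_network.web, std_network.traits,
                                  "recruitment")
        targets = np.flatnonzero(elig.any(axis=0))
        assert np.array_equal(targets, np.flatnonzero(std_network.web.is_plant))
        # plants do not facilitate recruitment
        assert not elig[std_network.web.is_plant].any()

    def test_mortality_covers_all_ordered_pairs(self, std_network):
        elig = eligibility_matrix(std_network.web, std_network.traits,
                                  "mortality_increase")
        assert elig.sum() == 100 * 99
        assert not np.diag(elig).any()

    def test_refuge_sources_sessile_targets_have_consumers(self, std_network):
        web, tr = std_network.web, std_network.traits
        A = web.adjacency.copy()
        np.fill_diagonal(A, False)
        for s, t in eligible_pairs(web, tr, "refuge"):
            assert tr.is_sessile[s]
            assert A[:, t].any()

    def test_unknown_type_rejected(self, std_network):
        with pytest.raises(ValueError):
            eligibility_matrix(std_network.web, std_network.traits, "parasitism")


class TestLayerDraws:
    def test_zero_probability_gives_empty_layer(self, std_network):
        layer = draw_nti_layer(std_network.web, std_network.traits,
                               "competition", 0.0, 1.0, np.random.default_rng(0))
        assert layer.n_links == 0

    def test_presence_respects_eligibility(self, std_network):
        rng = np.random.default_rng(3)
        for t in NTI_TYPES:
            layer = draw_nti_layer(std_network.web, std_network.traits, t,
                                   DEFAULT_NTI_PROBABILITIES[t], 1.0, rng)
            elig = eligibility_matrix(std_network.web, std_network.traits, t)
            assert not (layer.presence & ~elig).any()
            assert not np.diag(layer.presence).any()

    def test_interference_layer_is_symmetric(self, std_network):
        layer = draw_nti_layer(std_network.web, std_network.traits,
                               "interference", 0.15, 1.0,
                               np.random.default_rng(5))
        assert np.array_equal(layer.presence, layer.presence.T)

    def test_link_counts_are_binomial(self, std_network):
        """Element counts over repeated draws match Binomial(n_elig, p)."""
        rng = np.random.default_rng(11)
        p = 0.098
        n_elig = eligibility_matrix(std_network.web, std_network.traits,
                                    "competition").sum()
        counts = np.array([
            draw_nti_layer(std_network.web, std_network.traits, "competition",
                           p, 1.0, rng).n_links
            for _ in range(300)
        ])
        mean, var = n_elig * p, n_elig * p * (1 - p)
        assert abs(counts.mean() - mean) < 4 * np.sqrt(var / 300)
        assert 0.7 * var < counts.var() < 1.3 * var


class TestPlantConnectivity:
    def test_all_alive_with_consumed_plants_passes(self, std_network):
        alive = np.ones(100, dtype=bool)
        assert validate_connected_plants(std_network.web, alive)

    def test_surviving_plant_without_consumer_fails(self):
        web = make_web([[0, 0], [1, 0]])
        assert validate_connected_plants(web, np.array([True, True]))
        assert not validate_connected_plants(web, np.array([True, False]))

    def test_extinct_plants_are_not_checked(self):
        web = make_web([[0, 0], [1, 0]])
        assert validate_connected_plants(web, np.array([False, False]))
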