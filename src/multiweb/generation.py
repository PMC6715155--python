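"""Generation of multiplex ecological networks.

The trophic skeleton is sampled from the Williams–Martinez niche model and
rejection-sampled until it has an exact number of basal species (plants), no
directed cycle of length >= 2 (cannibalistic self-loops are allowed), and no
isolated species.  Species then receive a binary mobility trait (sessile vs
mobile), a prey-averaged trophic level and an allometric body mass.  On top
of the feeding layer, six non-trophic interaction (NTI) layers are drawn as
independent Bernoulli links restricted to type-specific eligibility rules
inspired by rocky-intertidal multiplex data:

- competition for space: between two sessile species (directed, asymmetric);
- predator interference: between two mobile consumers sharing >= 1 prey
  (symmetric);
- refuge provisioning: from a sessile species to any species that has a
  consumer;
- recruitment facilitation: from a consumer species to a plant;
- mortality increase / decrease: between any pair of species.

Intraspecific NTI links are never drawn (the diagonal is always empty).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import NTI_TYPES, ModelConfig

__all__ = [
    "TrophicWeb",
    "SpeciesTraits",
    "NTILayer",
    "MultiplexNetwork",
    "generate_niche_web",
    "compute_trophic_levels",
    "compute_shortest_trophic_levels",
    "assign_body_masses",
    "assign_mobility",
    "assign_traits",
    "eligible_pairs",
    "eligibility_matrix",
    "draw_nti_layer",
    "validate_connected_plants",
    "generate_multiplex",
]


@dataclass
class TrophicWeb:
    """Directed feeding network: ``adjacency[i, j]`` is True iff consumer
    ``i`` eats resource ``j``.  Plants have an empty diet."""

    S: int
    adjacency: np.ndarray          # (S, S) bool
    is_plant: np.ndarray           # (S,) bool
    niche_values: np.ndarray       # (S,) float, generator bookkeeping

    @property
    def n_links(self) -> int:
        """Number of directed trophic links (self-loops included)."""
        return int(self.adjacency.sum())

    @property
    def n_plants(self) -> int:
        return int(self.is_plant.sum())

    def consumers_of(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[:, j])

    def resources_of(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[i, :])


@dataclass
class SpeciesTraits:
    """Per-species mobility flag, trophic levels and body mass.

    Two trophic-level variants are carried: the prey-averaged level
    (``TL``, fractional; used to classify species into trophic-level
    bands) and the shortest-chain level (``TL_shortest``, integer-valued;
    one plus the length of the shortest food chain to a plant).  Body mass
    scales with the shortest-chain level, ``mass = expo**(TL_shortest-1)``
    — the shortest energy path is what bounds how large a consumer the web
    can sustain, and it is the scaling under which multi-level communities
    persist in this model.
    """

    is_sessile: np.ndarray         # (S,) bool
    TL: np.ndarray                 # (S,) float, >= 1, 1 iff plant
    mass: np.ndarray               # (S,) float, expo**(TL_shortest-1)
    TL_shortest: np.ndarray | None = None


@dataclass
class NTILayer:
    """One NTI type's presence matrix.

    ``presence[k, i]`` is True iff species ``k`` exerts the effect on
    species ``i``.  Interference layers are symmetric; all layers have an
    empty diagonal.
    """

    nti_type: str
    presence: np.ndarray           # (S, S) bool
    probability: float
    intensity: float = 0.0

    @property
    def n_links(self) -> int:
        """Realized link count = number of non-zero matrix elements.

        Each element is non-zero with probability ``probability``; a
        symmetric interference pair therefore contributes two links.
        """
        return int(self.presence.sum())


@dataclass
class MultiplexNetwork:
    """A trophic web plus traits and up to one NTI layer per type."""

    web: TrophicWeb
    traits: SpeciesTraits
    layers: dict = field(default_factory=dict)   # nti_type -> NTILayer

    @property
    def S(self) -> int:
        return self.web.S


class GenerationError(RuntimeError):
    """Raised when rejection sampling exhausts its attempt budget."""


# ---------------------------------------------------------------------------
# niche model
# ---------------------------------------------------------------------------

def _raw_niche_web(S: int, C: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One unconstrained niche-model draw: (adjacency, niche values)."""
    n = rng.uniform(0.0, 1.0, size=S)
    # feeding range fraction ~ Beta(1, beta) with mean 2C, so that the
    # expected connectance of the raw web is C
    beta = 1.0 / (2.0 * C) - 1.0
    x = rng.beta(1.0, beta, size=S)
    r = x * n
    centre = rng.uniform(r / 2.0, n)
    low = centre - r / 2.0
    high = centre + r / 2.0
    adjacency = (n[None, :] >= low[:, None]) & (n[None, :] <= high[:, None])
    return adjacency, n


def _has_cycle(adjacency: np.ndarray) -> bool:
    """True iff the digraph (self-loops ignored) has a directed cycle."""
    A = adjacency.copy()
    np.fill_diagonal(A, False)
    active = np.ones(A.shape[0], dtype=bool)
    while active.any():
        # species with no remaining prey cannot be on a cycle
        sinks = active & ~(A[:, active].any(axis=1))
        if not sinks.any():
            return True
        active &= ~sinks
    return False


def _web_ok(adjacency: np.ndarray, n_plants: int) -> bool:
    A = adjacency.copy()
    np.fill_diagonal(A, False)
    diet_sizes = A.sum(axis=1)
    basal = ~adjacency.any(axis=1)          # empty diet, self-loops included
    if int(basal.sum()) != n_plants:
        return False
    # a non-basal species whose only resource is itself has an undefined
    # trophic level; treat like an invalid web
    if ((~basal) & (diet_sizes == 0)).any():
        return False
    # no isolated species (no links to any other species)
    degree = A.any(axis=1) | A.any(axis=0)
    if not degree.all():
        return False
    return not _has_cycle(adjacency)


def generate_niche_web(
    S: int,
    C: float,
    n_plants: int,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> TrophicWeb:
    """Sample a niche-model web with exactly ``n_plants`` basal species.

    Each candidate draws niche values uniformly on [0, 1], a feeding-range
    fraction from Beta(1, 1/(2C) - 1) (expected connectance ``C``), and a
    range centre uniform on [range/2, niche value]; a species eats every
    species whose niche value falls in its range.  Candidates are rejected
    until the web has exactly ``n_plants`` species with an empty diet, no
    directed cycle of length >= 2, and no isolated species.
    """
    if S < 2:
        raise ValueError("S must be >= 2")
    if not 0.0 < C < 1.0:
        raise ValueError("C must lie in (0, 1)")
    if not 1 <= n_plants < S:
        raise ValueError("n_plants must satisfy 1 <= n_plants < S")
    for attempt in range(1, max_attempts + 1):
        adjacency, n = _raw_niche_web(S, C, rng)
        if _web_ok(adjacency, n_plants):
            basal = ~adjacency.any(axis=1)
            return TrophicWeb(S=S, adjacency=adjacency, is_plant=basal, niche_values=n)
    raise GenerationError(
        f"no admissible niche web (S={S}, C={C}, n_plants={n_plants}) "
        f"after {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def compute_trophic_levels(web: TrophicWeb) -> np.ndarray:
    """Prey-averaged trophic levels: 1 for plants, else one plus the mean
    trophic level of the species' resources (self-loops excluded)."""
    A = web.adjacency.astype(float).copy()
    np.fill_diagonal(A, 0.0)
    diet = A.sum(axis=1)
    if ((~web.is_plant) & (diet == 0)).any():
        bad = np.flatnonzero((~web.is_plant) & (diet == 0))
        raise ValueError(f"non-plant species without non-self resources: {bad.tolist()}")
    W = np.zeros_like(A)
    nz = diet > 0
    W[nz] = A[nz] / diet[nz, None]
    # TL = 1 + W @ TL  (W is nilpotent on an acyclic web, so this is exact)
    TL = np.linalg.solve(np.eye(web.S) - W, np.ones(web.S))
    return TL


def compute_shortest_trophic_levels(web: TrophicWeb) -> np.ndarray:
    """Shortest-chain trophic levels: 1 for plants, else one plus the
    minimum level among the species' resources (self-loops excluded)."""
    A = web.adjacency.copy()
    np.fill_diagonal(A, False)
    if ((~web.is_plant) & ~A.any(axis=1)).any():
        bad = np.flatnonzero((~web.is_plant) & ~A.any(axis=1))
        raise ValueError(f"non-plant species without non-self resources: {bad.tolist()}")
    sTL = np.where(web.is_plant, 1.0, np.inf)
    for _ in range(web.S):
        candidate = 1.0 + np.where(A, sTL[None, :], np.inf).min(axis=1)
        new = np.where(web.is_plant, 1.0, candidate)
        if np.array_equal(new, sTL):
            break
        sTL = new
    if not np.isfinite(sTL).all():
        raise ValueError("web has species unreachable from any plant")
    return sTL


def assign_body_masses(TL: np.ndarray, expo: float) -> np.ndarray:
    """Allometric body masses ``m_i = expo**(TL_i - 1)``."""
    TL = np.asarray(TL, dtype=float)
    if (TL < 1.0 - 1e-9).any():
        raise ValueError("trophic levels must be >= 1")
    return expo ** (TL - 1.0)


def assign_mobility(
    web: TrophicWeb,
    n_sessile: int,
    p_sessile_plant: float,
    p_sessile_other: float,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> np.ndarray:
    """Draw a sessile/mobile trait per species, redrawing the whole vector
    until exactly ``n_sessile`` species are sessile."""
    if n_sessile > web.S:
        raise ValueError("n_sessile cannot exceed the species count")
    p = np.where(web.is_plant, p_sessile_plant, p_sessile_other)
    for attempt in range(1, max_attempts + 1):
        sessile = rng.uniform(size=web.S) < p
        if int(sessile.sum()) == n_sessile:
            return sessile
    raise GenerationError(
        f"no trait vector with exactly {n_sessile} sessile species "
        f"after {max_attempts} attempts"
    )


def assign_traits(web: TrophicWeb, config: ModelConfig, rng: np.random.Generator) -> SpeciesTraits:
    """Mobility, both trophic-level variants and body mass in one call."""
    sessile = assign_mobility(
        web, config.n_sessile, config.p_sessile_plant, config.p_sessile_other,
        rng, config.max_attempts,
    )
    TL = compute_trophic_levels(web)
    sTL = compute_shortest_trophic_levels(web)
    mass = assign_body_masses(sTL, config.expo)
    return SpeciesTraits(is_sessile=sessile, TL=TL, mass=mass, TL_shortest=sTL)


# ---------------------------------------------------------------------------
# NTI layers
# ---------------------------------------------------------------------------

def eligibility_matrix(web: TrophicWeb, traits: SpeciesTraits, nti_type: str) -> np.ndarray:
    """Boolean matrix of candidate links ``[source, target]`` for one NTI type.

    For interference the matrix is symmetric (the pair is unordered); for
    every other type entry ``[k, i]`` means "k may affect i".  The diagonal
    is always False.
    """
    S = web.S
    sessile = traits.is_sessile
    mobile = ~sessile
    elig = np.zeros((S, S), dtype=bool)
    if nti_type == "competition":
        elig = sessile[:, None] & sessile[None, :]
    elif nti_type == "interference":
        A = web.adjacency.copy()
        np.fill_diagonal(A, False)
        consumer = A.any(axis=1)
        shares_prey = (A.astype(np.uint8) @ A.astype(np.uint8).T) > 0
        ok = mobile & consumer
        elig = ok[:, None] & ok[None, :] & shares_prey
    elif nti_type in ("mortality_increase", "mortality_decrease"):
        elig = np.ones((S, S), dtype=bool)
    elif nti_type == "refuge":
        A = web.adjacency.copy()
        np.fill_diagonal(A, False)
        has_consumer = A.any(axis=0)
        elig = sessile[:, None] & has_consumer[None, :]
    elif nti_type == "recruitment":
        elig = (~web.is_plant)[:, None] & web.is_plant[None, :]
    else:
        raise ValueError(f"unknown NTI type: {nti_type!r}")
    np.fill_diagonal(elig, False)
    return elig


def eligible_pairs(web: TrophicWeb, traits: SpeciesTraits, nti_type: str) -> set:
    """Eligible (source, target) pairs; interference pairs are returned once,
    with source < target."""
    elig = eligibility_matrix(web, traits, nti_type)
    if nti_type == "interference":
        elig = np.triu(elig)
    src, tgt = np.nonzero(elig)
    return set(zip(src.tolist(), tgt.tolist()))


def draw_nti_layer(
    web: TrophicWeb,
    traits: SpeciesTraits,
    nti_type: str,
    probability: float,
    intensity: float,
    rng: np.random.Generator,
) -> NTILayer:
    """Bernoulli-sample one NTI layer over its eligible pairs.

    Interference draws one coin per unordered pair and stores the link
    symmetrically; all other types draw per ordered pair.
    """
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    elig = eligibility_matrix(web, traits, nti_type)
    draws = rng.uniform(size=elig.shape) < probability
    if nti_type == "interference":
        upper = np.triu(elig & draws)
        presence = upper | upper.T
    else:
        presence = elig & draws
    return NTILayer(nti_type=nti_type, presence=presence,
                    probability=probability, intensity=intensity)


def validate_connected_plants(web: TrophicWeb, alive: np.ndarray) -> bool:
    """True iff every surviving plant retains at least one surviving consumer."""
    alive = np.asarray(alive, dtype=bool)
    if alive.shape != (web.S,):
        raise ValueError("alive mask must have length S")
    A = web.adjacency.copy()
    np.fill_diagonal(A, False)
    has_live_consumer = (A & alive[:, None]).any(axis=0)
    return bool(np.all(~(web.is_plant & alive) | has_live_consumer))


def generate_multiplex(
    config: ModelConfig,
    rng: np.random.Generator,
    nti_types: tuple = NTI_TYPES,
    probabilities: dict | None = None,
    intensities: dict | None = None,
) -> MultiplexNetwork:
    """Generate a full multiplex network under one config.

    ``probabilities`` / ``intensities`` override the config defaults per NTI
    type; a probability of 0 still yields an (empty) layer.
    """
    web = generate_niche_web(config.S, config.connectance, config.n_plants,
                             rng, config.max_attempts)
    traits = assign_traits(web, config, rng)
    probs = dict(config.nti_probabilities)
    if probabilities:
        probs.update(probabilities)
    intens = {t: config.intensity_of(t) for t in NTI_TYPES}
    if intensities:
        intens.update(intensities)
    layers = {
        t: draw_nti_layer(web, traits, t, probs[t], intens[t], rng)
        for t in nti_types
    }
    return MultiplexNetwork(web=web, traits=traits, layers=layers)
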