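"""Allometric bioenergetic dynamics on a multiplex network.

The trophic core is a standard allometric food-web model: plants grow
logistically, consumers feed through a multi-prey Holling functional
response with Hill exponent ``1 + q``, and all rates scale with body mass
``m`` as quarter-power laws.  The biomass density ``B_i`` of species ``i``
obeys

    dB_i/dt = g_i (r_i G_i + sum_j eps_ij F_ij - x_i) B_i
              - sum_k B_k F_ki - d_i B_i

with ``G_i = 1 - B_i / K_i`` the logistic term (plants only), ``F_ij`` the
feeding rate of ``i`` on ``j``, ``x_i`` the metabolic demand and ``d_i``
the background mortality.

Six non-trophic interaction (NTI) mechanisms modify the trophic rates as
linear functions of the biomass of the species exerting the effect:

- competition for space rescales the net growth term by
  ``g_i = 1 - c0 sum_l gamma_il B_l`` (only while net growth is positive);
- predator interference adds a Beddington–DeAngelis term
  ``i0_intra B_i + i0 sum_s delta_si B_s`` to the functional-response
  denominator, summed over the other predators ``s`` of the focal prey;
- refuge provisioning divides capture coefficients on the protected prey
  by ``1 + r0_refuge sum_k phi_kj B_k``;
- recruitment facilitation multiplies plant growth by
  ``1 + e0 sum_k eta_ki B_k``;
- mortality modification rescales ``d_i`` by
  ``(1 + n0 sum_k n_ki B_k) / (1 + p0 sum_k p_ki B_k)``.

With all intensities at zero the equations reduce exactly (term by term,
same evaluation order) to the purely trophic model.  This module is the
plain-NumPy reference implementation; :mod:`multiweb.simulate` integrates a
numerically identical compiled kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .generation import MultiplexNetwork, NTILayer, SpeciesTraits, TrophicWeb

__all__ = [
    "ModelParams",
    "NTIState",
    "build_model_params",
    "build_nti_state",
    "effective_attack",
    "effective_mortality",
    "effective_growth",
    "functional_response",
    "competition_factor",
    "net_growth",
    "rhs",
]


@dataclass
class ModelParams:
    """Fully assembled rate constants for the trophic core.

    All per-link matrices are zero off the trophic adjacency.
    """

    S: int
    is_plant: np.ndarray       # (S,) bool
    is_sessile: np.ndarray     # (S,) bool
    adjacency: np.ndarray      # (S, S) bool, consumer -> resource
    m: np.ndarray              # (S,) body masses
    r: np.ndarray              # (S,) intrinsic growth, >0 iff plant
    K: np.ndarray              # (S,) carrying capacities
    x: np.ndarray              # (S,) metabolic demand, 0 for plants
    d: np.ndarray              # (S,) background mortality
    eps: np.ndarray            # (S, S) assimilation efficiency on links
    w: np.ndarray              # (S,) relative consumption rate, 1/diet size
    a_base: np.ndarray         # (S, S) capture coefficients on links
    h: np.ndarray              # (S, S) handling times on links
    q: float                   # Hill coefficient; exponent is 1 + q


@dataclass
class NTIState:
    """Weighted NTI matrices plus intensity constants.

    ``[source, target]`` indexing throughout; weights are zero wherever the
    corresponding layer has no link.
    """

    gamma: np.ndarray          # (S, S) competition weights gamma0 * m_source^(2/3)
    delta: np.ndarray          # (S, S) interference weights, symmetric
    phi: np.ndarray            # (S, S) refuge presence (facilitator -> prey)
    eta: np.ndarray            # (S, S) recruitment presence (facilitator -> plant)
    n_mat: np.ndarray          # (S, S) mortality-increase presence
    p_mat: np.ndarray          # (S, S) mortality-decrease presence
    c0: float = 0.0
    i0: float = 0.0
    i0_intra: float = 0.8
    n0: float = 0.0
    p0: float = 0.0
    r0_refuge: float = 0.0
    e0: float = 0.0

    @classmethod
    def empty(cls, S: int, i0_intra: float = 0.8) -> "NTIState":
        """State with no NTI links (the purely trophic model)."""
        z = np.zeros((S, S))
        return cls(gamma=z, delta=z, phi=z, eta=z, n_mat=z, p_mat=z,
                   i0_intra=i0_intra)


def build_model_params(
    web: TrophicWeb,
    traits: SpeciesTraits,
    config: ModelConfig,
) -> ModelParams:
    """Assemble every allometric rate from body masses and the config.

    Scalings (mass ``m``, exponents fixed):

    - plants: ``r = r0 m^-0.25``, ``K = K0 m^0.25``, ``x = 0``,
      ``d = d0 * 0.138 * m^-0.25``;
    - consumers: ``r = 0``, ``x = 0.314 m^-0.25``,
      ``d = d0 * 0.314 * m^-0.25``;
    - capture ``a_ij = a0 m_i^exp1 m_j^exp2`` with the consumer (resource)
      mass factor dropped when the consumer (resource) is sessile;
    - handling ``h_ij = h0 m_i^-0.48 m_j^-0.66``;
    - assimilation efficiency 0.45 on plant resources, 0.85 otherwise;
    - ``w_i = 1 /`` (initial diet size), fixed for the whole run.
    """
    m = np.asarray(traits.mass, dtype=float)
    if m.shape != (web.S,):
        raise ValueError("traits.mass must have length S")
    if (m <= 0).any() or not np.isfinite(m).all():
        raise ValueError("body masses must be finite and positive")
    plant = web.is_plant
    sessile = traits.is_sessile
    m_q = m ** -0.25

    r = np.where(plant, config.r0 * m_q, 0.0)
    K = config.K0 * m ** 0.25
    x = np.where(plant, 0.0, config.x_species_other * m_q)
    x_sp = np.where(plant, config.x_species_plant, config.x_species_other)
    d = config.d0 * x_sp * m_q

    A = web.adjacency
    eps = np.where(A, np.where(plant[None, :], config.eps_plant, config.eps_other), 0.0)

    diet = A.sum(axis=1)
    w = np.zeros(web.S)
    w[diet > 0] = 1.0 / diet[diet > 0]

    # capture coefficients: a mobile species contributes its mass factor,
    # a sessile one does not; when both ends are sessile no mass factor
    # remains and the sessile-consumer coefficient applies
    cons_sess = sessile[:, None]
    res_sess = sessile[None, :]
    cons_fac = np.broadcast_to(m[:, None] ** config.exp1, (web.S, web.S))
    res_fac = np.broadcast_to(m[None, :] ** config.exp2, (web.S, web.S))
    a_full = np.where(
        cons_sess,
        config.a0_sesscons * np.where(res_sess, 1.0, res_fac),
        np.where(res_sess, config.a0_sessres * cons_fac,
                 config.a0 * cons_fac * res_fac),
    )
    a_base = np.where(A, a_full, 0.0)

    h = np.where(A, config.h0 * (m[:, None] ** -0.48) * (m[None, :] ** -0.66), 0.0)

    return ModelParams(
        S=web.S, is_plant=plant, is_sessile=sessile, adjacency=A,
        m=m, r=r, K=K, x=x, d=d, eps=eps, w=w, a_base=a_base, h=h,
        q=config.q,
    )


def build_nti_state(
    params: ModelParams,
    layers: dict | None,
    config: ModelConfig,
    intensities: dict | None = None,
) -> NTIState:
    """Turn NTI layers into weighted matrices plus intensity constants.

    ``layers`` maps NTI type names to :class:`~multiweb.generation.NTILayer`;
    absent types contribute empty matrices.  Intensities default to the
    config fields and can be overridden per type.
    """
    S = params.S
    m = params.m

    def presence(t: str) -> np.ndarray:
        if layers and t in layers:
            return layers[t].presence.astype(float)
        return np.zeros((S, S))

    intens = {t: config.intensity_of(t) for t in (
        "competition", "interference", "mortality_increase",
        "mortality_decrease", "refuge", "recruitment")}
    if intensities:
        intens.update(intensities)

    # competition weight of source l on target i grows with the space an
    # individual of l occupies: gamma0 * m_l^(2/3)
    gamma = presence("competition") * (config.gamma0 * m[:, None] ** (2.0 / 3.0))
    # interference is strongest between predators of similar body mass
    with np.errstate(divide="ignore"):
        logm = np.log(m)
    delta = presence("interference") / (1.0 + np.abs(logm[:, None] - logm[None, :]))

    return NTIState(
        gamma=gamma, delta=delta,
        phi=presence("refuge"), eta=presence("recruitment"),
        n_mat=presence("mortality_increase"), p_mat=presence("mortality_decrease"),
        c0=intens["competition"], i0=intens["interference"],
        i0_intra=config.i0_intra,
        n0=intens["mortality_increase"], p0=intens["mortality_decrease"],
        r0_refuge=intens["refuge"], e0=intens["recruitment"],
    )


# ---------------------------------------------------------------------------
# NTI-modified rates
# ---------------------------------------------------------------------------

def effective_attack(params: ModelParams, nti: NTIState, B: np.ndarray) -> np.ndarray:
    """Refuge-modified capture coefficients.

    ``a_ij -> a_ij / (1 + r0_refuge * sum_k phi_kj B_k)``: every predator of
    a protected prey sees the same reduction, vanishing as facilitator
    biomass grows.
    """
    shelter = 1.0 + nti.r0_refuge * (nti.phi.T @ B)
    return params.a_base / shelter[None, :]


def effective_mortality(params: ModelParams, nti: NTIState, B: np.ndarray) -> np.ndarray:
    """Mortality rescaled by negative and positive effectors:
    ``d_i (1 + n0 sum n_ki B_k) / (1 + p0 sum p_ki B_k)``."""
    up = 1.0 + nti.n0 * (nti.n_mat.T @ B)
    down = 1.0 + nti.p0 * (nti.p_mat.T @ B)
    return params.d * up / down


def effective_growth(params: ModelParams, nti: NTIState, B: np.ndarray) -> np.ndarray:
    """Recruitment-facilitated plant growth ``r_i (1 + e0 sum eta_ki B_k)``.

    Eligibility restricts eta to plant targets, so consumers keep r = 0.
    """
    return params.r * (1.0 + nti.e0 * (nti.eta.T @ B))


def functional_response(params: ModelParams, nti: NTIState, B: np.ndarray) -> np.ndarray:
    """Feeding rate ``F_ij`` of every consumer on every resource.

    Multi-prey Holling response with Hill exponent ``1 + q``, capture
    coefficients already refuge-modified, and a Beddington–DeAngelis
    interference term per focal prey:

        F_ij = w_i a_ij B_j^(1+q) /
               [ m_i (1 + I_ij + w_i sum_k a_ik h_ik B_k^(1+q)) ]

    with ``I_ij = i0_intra B_i + i0 sum_{s in pred(j), s != i} delta_si B_s``.
    """
    B = np.asarray(B, dtype=float)
    Bq = np.where(B > 0.0, B, 0.0) ** (1.0 + params.q)
    a_new = effective_attack(params, nti, B)
    wa = params.w[:, None] * a_new
    saturation = (wa * params.h) @ Bq                      # (S,)
    # interference of the other predators s of prey j with consumer i:
    # delta is symmetric and has an empty diagonal, so s = i drops out
    inter = nti.delta @ (np.where(params.adjacency, B[:, None], 0.0)) \
        if nti.i0 != 0.0 else 0.0
    I = nti.i0_intra * B[:, None] + nti.i0 * inter
    denom = params.m[:, None] * (1.0 + I + saturation[:, None])
    F = wa * Bq[None, :] / denom
    return np.where(params.adjacency, F, 0.0)


def net_growth(params: ModelParams, nti: NTIState, B: np.ndarray,
               F: np.ndarray | None = None) -> np.ndarray:
    """Per-capita net growth ``r_i^new G_i + sum_j eps_ij F_ij - x_i``
    (the bracketed term of the balance equation, before space competition)."""
    B = np.asarray(B, dtype=float)
    if F is None:
        F = functional_response(params, nti, B)
    G = 1.0 - B / params.K
    r_new = effective_growth(params, nti, B)
    return r_new * G + (params.eps * F).sum(axis=1) - params.x


def competition_factor(params: ModelParams, nti: NTIState, B: np.ndarray,
                       net_growth_rate: np.ndarray) -> np.ndarray:
    """Space-competition factor ``g_i = 1 - c0 sum_l gamma_il B_l``.

    Competition only operates while the target's net growth rate is
    positive; otherwise ``g_i = 1``.  ``g`` is not clamped below at zero
    (within the calibrated c0 range it stays positive).
    """
    g = 1.0 - nti.c0 * (nti.gamma.T @ B)
    return np.where(net_growth_rate > 0.0, g, 1.0)


def rhs(params: ModelParams, nti: NTIState, B: np.ndarray) -> np.ndarray:
    """Time derivative of all biomass densities.

    Extinct species (``B_i = 0``) get exactly zero: every gain term carries
    a factor ``B_i`` and predation loss scales with ``B_i^(1+q)``.
    """
    B = np.asarray(B, dtype=float)
    if not np.isfinite(B).all():
        raise ValueError("non-finite biomass passed to rhs")
    F = functional_response(params, nti, B)
    growth = net_growth(params, nti, B, F=F)
    g = competition_factor(params, nti, B, growth)
    d_new = effective_mortality(params, nti, B)
    predation = F.T @ B                      # sum_k B_k F_ki
    return g * growth * B - predation - d_new * B


def production_rate(params: ModelParams, nti: NTIState, B: np.ndarray) -> np.ndarray:
    """Per-species production ``g_i (r_i^new G_i + sum eps F - x_i) B_i``:
    intrinsic growth of plants plus food uptake minus respiration."""
    B = np.asarray(B, dtype=float)
    growth = net_growth(params, nti, B)
    g = competition_factor(params, nti, B, growth)
    return g * growth * B


def assemble(network: MultiplexNetwork, config: ModelConfig,
             intensities: dict | None = None) -> tuple[ModelParams, NTIState]:
    """Convenience: parameters and NTI state for a generated network."""
    params = build_model_params(network.web, network.traits, config)
    nti = build_nti_state(params, network.layers, config, intensities)
    return params, nti
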