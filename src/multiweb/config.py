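"""Model configuration: every rate constant and structural setting in one place.

All constants of the bioenergetic model and of the network generator are
collected in :class:`ModelConfig`, with defaults set to the values used for
the main simulation study (allometric scalings anchored at body mass 1, time
scale set by the plant growth scaling ``r0 = 1``).  Any field can be
overridden through :func:`load_config` for sensitivity analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

#: The six non-trophic interaction (NTI) types, in canonical order.
NTI_TYPES = (
    "competition",
    "interference",
    "mortality_increase",
    "mortality_decrease",
    "refuge",
    "recruitment",
)

#: Per-pair link probabilities calibrated to yield ~100 links of each type
#: on a 100-species web with 20 plants and 33 sessile species.
DEFAULT_NTI_PROBABILITIES = {
    "competition": 0.098,
    "interference": 0.15,
    "mortality_increase": 0.01,
    "mortality_decrease": 0.01,
    "refuge": 0.033,
    "recruitment": 0.063,
}

#: Intensity ranges spanning a ~2.5% (min) to ~10% (max) effect on species
#: diversity when each NTI acts alone.
DEFAULT_INTENSITY_RANGES = {
    "competition": (0.0045, 0.012),
    "interference": (0.75, 3.0),
    "mortality_increase": (0.75, 3.0),
    "mortality_decrease": (5.0, 20.0),
    "refuge": (0.25, 1.75),
    "recruitment": (0.15, 1.8),
}

#: NTI types with a detrimental effect on diversity; in the mixed ensemble
#: their link probabilities are quartered so positive and negative link
#: numbers balance.
NEGATIVE_NTI_TYPES = ("competition", "interference", "refuge", "mortality_increase")


@dataclass
class ModelConfig:
    """All tunable constants of the generator and the dynamical model.

    Rates are per unit time on the scale set by ``r0 = 1``; masses are in
    units of the smallest (plant) body mass.
    """

    # --- network generation ---
    S: int = 100                      # species richness of the regional pool
    connectance: float = 0.06         # target L / S^2 of the niche model
    n_plants: int = 20                # exact basal-species count (rejection)
    n_sessile: int = 33               # exact sessile count (rejection)
    p_sessile_plant: float = 0.8      # P(sessile) for plants
    p_sessile_other: float = 0.2      # P(sessile) for consumers
    max_attempts: int = 10_000        # rejection-sampling cap (webs and traits)

    # --- allometry ---
    expo: float = 50.0                # body mass m_i = expo**(TL_i - 1)
    r0: float = 1.0                   # plant growth scaling, r_i = r0 m^-0.25
    K0: float = 1.0                   # carrying capacity scaling, K_i = K0 m^0.25
    x_species_plant: float = 0.138    # metabolic constant entering plant mortality
    x_species_other: float = 0.314    # consumer metabolic constant
    d0: float = 0.1                   # mortality d_i = d0 x_species m^-0.25
    eps_plant: float = 0.45           # assimilation efficiency on plant resources
    eps_other: float = 0.85           # assimilation efficiency on animal resources
    a0: float = 50.0                  # capture coefficient, both species mobile
    a0_sesscons: float = 50.0         # capture coefficient, sessile consumer
    a0_sessres: float = 50.0          # capture coefficient, sessile resource
    exp1: float = 0.45                # consumer-mass exponent of the capture rate
    exp2: float = 0.15                # resource-mass exponent of the capture rate
    h0: float = 0.3                   # handling time h_ij = h0 m_i^-0.48 m_j^-0.66
    q: float = 0.5                    # Hill coefficient; 1+q is the Hill exponent
    gamma0: float = 1.0               # space-competition weight gamma = gamma0 m^(2/3)
    i0_intra: float = 0.8             # intraspecific predator interference (always on)

    # --- NTI intensities (0 = mechanism absent) ---
    c0: float = 0.0                   # competition for space
    i0: float = 0.0                   # interspecific predator interference
    n0: float = 0.0                   # mortality increase
    p0: float = 0.0                   # mortality decrease
    r0_refuge: float = 0.0            # refuge provisioning
    e0: float = 0.0                   # recruitment facilitation

    # --- simulation ---
    t_max: float = 5000.0             # integration horizon; final state = steady state
    extinction_threshold: float = 1e-6
    rtol: float = 1e-8
    atol: float = 1e-10
    b0_min: float = 0.05              # initial biomass ~ U[b0_min, b0_max]
    b0_max: float = 1.0

    nti_probabilities: dict = field(
        default_factory=lambda: dict(DEFAULT_NTI_PROBABILITIES)
    )
    intensity_ranges: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_INTENSITY_RANGES.items()}
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.S < 2:
            raise ValueError("S: need at least 2 species")
        if not 0.0 < self.connectance < 1.0:
            raise ValueError("connectance: must lie in (0, 1)")
        if not 1 <= self.n_plants < self.S:
            raise ValueError("n_plants: must satisfy 1 <= n_plants < S")
        if not 0 <= self.n_sessile <= self.S:
            raise ValueError("n_sessile: must satisfy 0 <= n_sessile <= S")
        for key in ("a0", "a0_sesscons", "a0_sessres", "h0", "expo", "r0", "K0"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key}: must be strictly positive")
        for key in ("c0", "i0", "n0", "p0", "r0_refuge", "e0", "i0_intra",
                    "d0", "q", "extinction_threshold"):
            if getattr(self, key) < 0:
                raise ValueError(f"{key}: must be nonnegative")
        unknown = set(self.nti_probabilities) - set(NTI_TYPES)
        if unknown:
            raise ValueError(f"nti_probabilities: unknown NTI types {sorted(unknown)}")
        for k, p in self.nti_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"nti_probabilities.{k}: probability outside [0, 1]")

    def intensity_of(self, nti_type: str) -> float:
        """Current intensity constant for one NTI type."""
        return getattr(self, INTENSITY_FIELD[nti_type])

    def with_intensities(self, **intensities: float) -> "ModelConfig":
        """Copy of this config with NTI intensities replaced by type name."""
        fields = {INTENSITY_FIELD[k]: v for k, v in intensities.items()}
        return dataclasses.replace(self, **fields)

    def replace(self, **kwargs: Any) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: Map from NTI type name to its intensity field on :class:`ModelConfig`.
INTENSITY_FIELD = {
    "competition": "c0",
    "interference": "i0",
    "mortality_increase": "n0",
    "mortality_decrease": "p0",
    "refuge": "r0_refuge",
    "recruitment": "e0",
}

_VALID_KEYS = {f.name for f in dataclasses.fields(ModelConfig)}


def config_from_mapping(mapping: Mapping[str, Any] | None) -> ModelConfig:
    """Build a config from a plain mapping, rejecting unknown keys."""
    mapping = dict(mapping or {})
    unknown = set(mapping) - _VALID_KEYS
    if unknown:
        raise ValueError(
            f"unknown configuration keys: {sorted(unknown)}; "
            f"valid keys are {sorted(_VALID_KEYS)}"
        )
    ranges = mapping.get("intensity_ranges")
    if ranges is not None:
        mapping["intensity_ranges"] = {k: tuple(v) for k, v in ranges.items()}
    return ModelConfig(**mapping)


def load_config(path: str) -> ModelConfig:
    """Load a YAML config file; an empty file yields the full defaults.

    Raises ``ValueError`` naming the offending key on unknown keys or
    out-of-range values.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: top level must be a mapping, got {type(data).__name__}")
    return config_from_mapping(data)
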