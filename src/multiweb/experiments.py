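"""Ensemble experiments: paired with/without-NTI simulations.

Every design follows the same protocol.  A trophic web is accepted once its
trophic-only run leaves no disconnected plant (a surviving plant without a
surviving consumer) at the end of the dynamics; that run doubles as the
"without" arm.  NTI layers are then drawn on the accepted web and the
paired "with" run — same web, same initial biomasses, same parameters
except the NTI terms — yields normalized ratios
``(with - without) / without`` for diversity, biomass and production.
Runs whose final state leaves a disconnected plant are themselves rejected
(and the layer draw resampled up to a cap).

Designs
-------
- :func:`run_single_nti_sweep`: one NTI type, intensity swept linearly over
  its range (intensity–response panels and their regression slopes);
- :func:`run_mixed_ensemble`: the five retained types together, quartered
  link probabilities for the four detrimental ones (balanced ~100 positive
  vs ~100 negative links), intensities uniform over their ranges;
- :func:`run_link_count_ensemble`: fixed maximal intensities, varied
  positive/negative link numbers;
- :func:`run_sensitivity_suite`: the mixed ensemble repeated over
  alternative values of q, a0 and expo, reporting BEF slopes;
- :func:`calibrate_intensity`: bisection for the intensity producing a
  target mean diversity change.

Randomness derives from a single seed through named spawn keys, so every
web, trait draw and layer draw is reproducible independently of execution
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_INTENSITY_RANGES,
    NEGATIVE_NTI_TYPES,
    NTI_TYPES,
    ModelConfig,
)
from .dynamics import NTIState, build_model_params, build_nti_state
from .generation import (
    GenerationError,
    MultiplexNetwork,
    assign_traits,
    draw_nti_layer,
    generate_niche_web,
    validate_connected_plants,
)
from .simulate import compute_metrics, draw_initial_biomasses, integrate
from .stats import TL_CLASS_SUFFIX, ancova_slopes, fit_linear

__all__ = [
    "ExperimentConfig",
    "run_single_nti_sweep",
    "run_mixed_ensemble",
    "run_link_count_ensemble",
    "run_sensitivity_suite",
    "calibrate_intensity",
    "CalibrationResult",
    "bef_slopes",
]

#: Fixed intensities (the ~10% single-type diversity effect) used by the
#: link-count ensemble.
MAX_INTENSITIES = {
    "interference": 3.0,
    "refuge": 1.75,
    "competition": 0.012,
    "recruitment": 1.8,
    "mortality_increase": 3.0,
}

#: Sensitivity-analysis settings, varied one at a time around the defaults.
#: The low capture coefficient requires a shorter handling time to avoid
#: community collapse.
SENSITIVITY_SETTINGS = (
    {"label": "default"},
    {"label": "q=0.3", "q": 0.3},
    {"label": "q=0.7", "q": 0.7},
    {"label": "a0=10", "a0": 10.0, "a0_sesscons": 10.0, "a0_sessres": 10.0,
     "h0": 0.1},
    {"label": "a0=250", "a0": 250.0, "a0_sesscons": 250.0, "a0_sessres": 250.0},
    {"label": "expo=25", "expo": 25.0},
    {"label": "expo=75", "expo": 75.0},
)


@dataclass
class ExperimentConfig:
    """Sizes, seed and solver settings of an ensemble experiment.

    ``scale_factor`` shrinks ``n_webs`` and ``n_nti_draws`` proportionally
    (floor, minimum 1) for desk-scale execution; statistical power shrinks
    with it but the sign structure of the effects is preserved.
    """

    n_webs: int = 20
    n_nti_draws: int = 10
    grid_size: int = 8                    # intensity grid points per sweep
    seed: int = 0
    scale_factor: float = 1.0
    model: ModelConfig = field(default_factory=ModelConfig)
    intensity_ranges: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_INTENSITY_RANGES.items()})
    max_web_attempts: int = 200           # web rejections per accepted web
    max_draw_attempts: int = 20           # layer-draw rejections per kept draw
    rtol: float = 1e-6                    # ensemble solver tolerances
    atol: float = 1e-9                    # (see docs/methods.md)
    backend: str = "numba"

    def __post_init__(self) -> None:
        if not 0.0 < self.scale_factor <= 1.0:
            raise ValueError("scale_factor must lie in (0, 1]")
        for k, (lo, hi) in self.intensity_ranges.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"intensity_ranges[{k!r}]: need 0 <= lo <= hi")

    @property
    def webs(self) -> int:
        return max(1, int(self.n_webs * self.scale_factor))

    @property
    def draws(self) -> int:
        return max(1, int(self.n_nti_draws * self.scale_factor))


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class _WebContext:
    """An accepted web with its trophic-only (without-NTI) baseline run."""

    web_id: int
    attempt: int
    network: MultiplexNetwork            # layers empty
    params: object
    nti0: NTIState
    B0: np.ndarray
    metrics_without: object


def _prepare_webs(cfg: ExperimentConfig, n_webs: int, tally: dict) -> list[_WebContext]:
    """Generate webs until ``n_webs`` pass the trophic-only plant filter."""
    model = cfg.model
    out: list[_WebContext] = []
    attempt = 0
    while len(out) < n_webs:
        if attempt >= cfg.max_web_attempts * n_webs:
            raise GenerationError(
                f"only {len(out)}/{n_webs} webs accepted after {attempt} attempts")
        rng = _rng(cfg.seed, 0, attempt)
        attempt += 1
        web = generate_niche_web(model.S, model.connectance, model.n_plants,
                                 rng, model.max_attempts)
        traits = assign_traits(web, model, rng)
        params = build_model_params(web, traits, model)
        nti0 = build_nti_state(params, None, model)
        B0 = draw_initial_biomasses(model.S, rng, model.b0_min, model.b0_max)
        res = integrate(params, nti0, B0, t_max=model.t_max,
                        threshold=model.extinction_threshold,
                        rtol=cfg.rtol, atol=cfg.atol, backend=cfg.backend)
        if not validate_connected_plants(web, res.alive):
            tally["webs_rejected"] += 1
            continue
        tally["webs_accepted"] += 1
        metrics = compute_metrics(res, params, nti0, traits.TL)
        out.append(_WebContext(
            web_id=len(out), attempt=attempt - 1,
            network=MultiplexNetwork(web=web, traits=traits, layers={}),
            params=params, nti0=nti0, B0=B0, metrics_without=metrics))
    return out


def _metric_columns(prefix: str, metrics) -> dict:
    row = {
        f"{prefix}_diversity": metrics.diversity,
        f"{prefix}_biomass": metrics.biomass,
        f"{prefix}_production": metrics.production,
    }
    for label, suffix in TL_CLASS_SUFFIX.items():
        for var in ("diversity", "biomass", "production"):
            row[f"{prefix}_{var}_{suffix}"] = metrics.per_tl[label][var]
    return row


def _ratio_columns(m_with, m_without) -> dict:
    def ratio(a, b):
        return (a - b) / b if b != 0 else np.nan
    row = {}
    for var in ("diversity", "biomass", "production"):
        row[f"{var}_ratio"] = ratio(getattr(m_with, var), getattr(m_without, var))
    for label, suffix in TL_CLASS_SUFFIX.items():
        for var in ("diversity", "biomass", "production"):
            row[f"{var}_ratio_{suffix}"] = ratio(
                m_with.per_tl[label][var], m_without.per_tl[label][var])
    return row


def _paired_run(cfg, ctx, layers, intensities) -> tuple[dict | None, object]:
    """Run the with-NTI arm; None if it fails the plant filter."""
    model = cfg.model
    nti = build_nti_state(ctx.params, layers, model, intensities)
    res = integrate(ctx.params, nti, ctx.B0, t_max=model.t_max,
                    threshold=model.extinction_threshold,
                    rtol=cfg.rtol, atol=cfg.atol, backend=cfg.backend)
    if not validate_connected_plants(ctx.network.web, res.alive):
        return None, None
    metrics = compute_metrics(res, ctx.params, nti, ctx.network.traits.TL)
    row = {**_metric_columns("with", metrics),
           **_metric_columns("without", ctx.metrics_without),
           **_ratio_columns(metrics, ctx.metrics_without)}
    return row, metrics


def _new_tally() -> dict:
    return {"webs_accepted": 0, "webs_rejected": 0,
            "draws_accepted": 0, "draws_rejected": 0}


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

def run_single_nti_sweep(
    cfg: ExperimentConfig,
    nti_type: str,
    intensities: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sweep one NTI type's intensity over a linear grid.

    One layer per (web, draw) is reused across the whole grid, so the
    intensity axis is the only thing that changes within a draw.  Returns
    one row per accepted (web, draw, intensity) run; rejection tallies and
    the diversity-ratio-vs-intensity regression slope are in ``.attrs``.
    """
    if nti_type not in NTI_TYPES:
        raise ValueError(f"unknown NTI type {nti_type!r}")
    if intensities is None:
        lo, hi = cfg.intensity_ranges[nti_type]
        intensities = np.linspace(lo, hi, cfg.grid_size)
    tally = _new_tally()
    webs = _prepare_webs(cfg, cfg.webs, tally)
    prob = cfg.model.nti_probabilities[nti_type]
    rows = []
    for ctx in webs:
        for draw in range(cfg.draws):
            for redraw in range(cfg.max_draw_attempts):
                rng = _rng(cfg.seed, 1, ctx.attempt, draw, redraw)
                layer = draw_nti_layer(ctx.network.web, ctx.network.traits,
                                       nti_type, prob, 0.0, rng)
                draw_rows = []
                ok = True
                for x in intensities:
                    row, _ = _paired_run(cfg, ctx, {nti_type: layer},
                                         {nti_type: float(x)})
                    if row is None:
                        ok = False
                        break
                    row.update(web_id=ctx.web_id, draw_id=draw,
                               nti_type=nti_type, intensity=float(x),
                               n_links=layer.n_links)
                    draw_rows.append(row)
                if ok:
                    tally["draws_accepted"] += 1
                    rows.extend(draw_rows)
                    break
                tally["draws_rejected"] += 1
            else:
                pass  # draw dropped; tallied above
    if not rows:
        raise GenerationError("no accepted runs in sweep (all draws rejected)")
    df = pd.DataFrame(rows)
    df.attrs["tally"] = tally
    if df["intensity"].nunique() > 1:
        fit = fit_linear(df["intensity"], df["diversity_ratio"])
        df.attrs["slope"] = fit.slope
        df.attrs["slope_p_value"] = fit.p_value
    df.attrs["mean_ratio_per_intensity"] = (
        df.groupby("intensity")["diversity_ratio"].mean().to_dict())
    return df


def _mixed_layers(cfg, ctx, rng, negative_types, positive_scale=1.0,
                  negative_scale=0.25):
    """Draw one layer per retained type with scaled probabilities."""
    layers = {}
    probs = cfg.model.nti_probabilities
    for t in negative_types:
        layers[t] = draw_nti_layer(ctx.network.web, ctx.network.traits, t,
                                   probs[t] * negative_scale, 0.0, rng)
    layers["recruitment"] = draw_nti_layer(
        ctx.network.web, ctx.network.traits, "recruitment",
        probs["recruitment"] * positive_scale, 0.0, rng)
    return layers


def run_mixed_ensemble(
    cfg: ExperimentConfig,
    negative_types: tuple = NEGATIVE_NTI_TYPES,
) -> pd.DataFrame:
    """All retained NTI types together with random intensities.

    The four detrimental types get one quarter of their single-type link
    probabilities, balancing ~100 beneficial (recruitment) against ~100
    detrimental links per network; mortality decrease is excluded for its
    negligible effect.  Intensities are uniform over the per-type ranges.
    """
    tally = _new_tally()
    webs = _prepare_webs(cfg, cfg.webs, tally)
    rows = []
    types = tuple(negative_types) + ("recruitment",)
    for ctx in webs:
        for draw in range(cfg.draws):
            for redraw in range(cfg.max_draw_attempts):
                rng = _rng(cfg.seed, 1, ctx.attempt, draw, redraw)
                layers = _mixed_layers(cfg, ctx, rng, negative_types)
                intensities = {
                    t: float(rng.uniform(*cfg.intensity_ranges[t])) for t in types}
                row, _ = _paired_run(cfg, ctx, layers, intensities)
                if row is not None:
                    break
                tally["draws_rejected"] += 1
            else:
                continue   # draw dropped after max redraws
            tally["draws_accepted"] += 1
            row.update(web_id=ctx.web_id, draw_id=draw)
            for t in types:
                row[f"intensity_{t}"] = intensities[t]
                row[f"links_{t}"] = layers[t].n_links
            rows.append(row)
    if not rows:
        raise GenerationError("no accepted runs in mixed ensemble")
    df = pd.DataFrame(rows)
    df.attrs["tally"] = tally
    return df


def run_link_count_ensemble(
    cfg: ExperimentConfig,
    setups: tuple = ((100, 100), (50, 100), (100, 50)),
    negative_types: tuple = NEGATIVE_NTI_TYPES,
) -> pd.DataFrame:
    """Vary the positive/negative link balance at fixed maximal intensities.

    Each setup targets ``n_pos`` recruitment links and ``n_neg`` detrimental
    links split equally over ``negative_types`` (100 of a type corresponds
    to its full single-type probability).  Intensities are the fixed
    ~10%-effect values.
    """
    tally = _new_tally()
    webs = _prepare_webs(cfg, cfg.webs, tally)
    intensities = {t: MAX_INTENSITIES[t] for t in
                   tuple(negative_types) + ("recruitment",)}
    rows = []
    for n_pos, n_neg in setups:
        pos_scale = n_pos / 100.0
        neg_scale = n_neg / 100.0 / len(negative_types)
        for ctx in webs:
            for draw in range(cfg.draws):
                for redraw in range(cfg.max_draw_attempts):
                    rng = _rng(cfg.seed, 2, n_pos, n_neg, ctx.attempt, draw, redraw)
                    layers = _mixed_layers(cfg, ctx, rng, negative_types,
                                           pos_scale, neg_scale)
                    row, _ = _paired_run(cfg, ctx, layers, intensities)
                    if row is not None:
                        break
                    tally["draws_rejected"] += 1
                else:
                    continue
                tally["draws_accepted"] += 1
                row.update(web_id=ctx.web_id, draw_id=draw,
                           n_pos_target=n_pos, n_neg_target=n_neg,
                           links_positive=layers["recruitment"].n_links,
                           links_negative=sum(layers[t].n_links
                                              for t in negative_types))
                rows.append(row)
    if not rows:
        raise GenerationError("no accepted runs in link-count ensemble")
    df = pd.DataFrame(rows)
    df.attrs["tally"] = tally
    return df


def bef_slopes(ensemble: pd.DataFrame, response: str = "biomass"):
    """Diversity–functioning slopes with and without NTIs.

    The "with" points are every accepted paired run; the "without" points
    are the unique trophic-only baselines — one per web, since every draw
    on a web shares the same baseline run.  Returns the slope-homogeneity
    ANCOVA (group 1 = without, group 2 = with).
    """
    without = ensemble.drop_duplicates("web_id")
    return ancova_slopes(
        without["without_diversity"], without[f"without_{response}"],
        ensemble["with_diversity"], ensemble[f"with_{response}"],
    )


def run_sensitivity_suite(
    cfg: ExperimentConfig,
    settings: tuple = SENSITIVITY_SETTINGS,
) -> pd.DataFrame:
    """Mixed ensemble repeated under alternative model parameters.

    Each setting overrides one influential constant (Hill coefficient q,
    capture coefficient a0, mass scaling expo) and reports the BEF slope
    with and without NTIs plus the slope-difference p-value.
    """
    rows = []
    for setting in settings:
        overrides = {k: v for k, v in setting.items() if k != "label"}
        sub = replace(cfg, model=cfg.model.replace(**overrides))
        ens = run_mixed_ensemble(sub)
        bef = bef_slopes(ens)
        rows.append({
            "label": setting["label"], **overrides,
            "slope_without": bef.slope1, "slope_with": bef.slope2,
            "interaction": bef.interaction, "p_value": bef.p_value,
            "n_runs": len(ens),
        })
    return pd.DataFrame(rows)


@dataclass
class CalibrationResult:
    nti_type: str
    target_effect: float
    intensity: float
    achieved_effect: float
    converged: bool
    n_evaluations: int


def mean_diversity_effect(cfg: ExperimentConfig, nti_type: str,
                          intensity: float) -> float:
    """Mean diversity ratio of one NTI type at one intensity over the
    calibration ensemble (single-type layers at full probability)."""
    if intensity == 0.0:
        return 0.0
    df = run_single_nti_sweep(cfg, nti_type, intensities=np.array([intensity]))
    return float(df["diversity_ratio"].mean())


def calibrate_intensity(
    cfg: ExperimentConfig,
    nti_type: str,
    target_effect: float,
    bounds: tuple | None = None,
    tol: float = 0.005,
    max_iter: int = 12,
) -> CalibrationResult:
    """Bisection for the intensity whose mean diversity effect matches a
    signed target (e.g. -0.10 for a 10% diversity loss).

    If even the upper intensity bound cannot reach the target (as happens
    for mortality decrease), returns ``converged=False`` with the maximum
    achieved effect.
    """
    if target_effect == 0:
        return CalibrationResult(nti_type, 0.0, 0.0, 0.0, True, 0)
    if not abs(target_effect) < 0.5:
        raise ValueError("target_effect magnitude must lie in [0, 0.5)")
    if bounds is None:
        lo, hi = 0.0, cfg.intensity_ranges[nti_type][1] * 2.0
    else:
        lo, hi = bounds
    n_eval = 0
    effect_hi = mean_diversity_effect(cfg, nti_type, hi)
    n_eval += 1
    sign = 1.0 if target_effect > 0 else -1.0
    if sign * effect_hi < abs(target_effect) - tol:
        return CalibrationResult(nti_type, target_effect, hi, effect_hi,
                                 False, n_eval)
    mid = 0.5 * (lo + hi)
    effect_mid = effect_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        effect_mid = mean_diversity_effect(cfg, nti_type, mid)
        n_eval += 1
        if abs(effect_mid - target_effect) <= tol:
            return CalibrationResult(nti_type, target_effect, mid, effect_mid,
                                     True, n_eval)
        if sign * effect_mid < abs(target_effect):
            lo = mid
        else:
            hi = mid
    return CalibrationResult(nti_type, target_effect, mid, effect_mid,
                             False, n_eval)
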