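"""Integration to steady state and community-level metrics.

The system is integrated with an embedded Runge–Kutta–Fehlberg 4(5) pair to
a fixed horizon (default t = 5000, observed sufficient for the dynamics to
settle); whenever a species' biomass falls below the extinction threshold
(default 1e-6) at an accepted step it is clamped to zero and — zero being
an exact fixed point — stays extinct.  The state at the horizon is treated
as the steady state; community metrics (diversity, total biomass, total
production) are evaluated there, overall and per trophic-level class.

Two backends produce the same trajectories: a compiled RKF45 loop
(``backend="numba"``, default) and a SciPy ``RK45`` stepper with the pure
NumPy right-hand side (``backend="scipy"``), which also supports trajectory
recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import RK45

from . import _kernel
from .dynamics import ModelParams, NTIState, production_rate, rhs

__all__ = [
    "SimulationResult",
    "CommunityMetrics",
    "draw_initial_biomasses",
    "integrate",
    "compute_metrics",
    "normalized_ratio",
    "TL_CLASSES",
]

#: Trophic-level classes used in per-class summaries: plants, intermediate
#: consumers, top consumers.  Prey-averaged TL is 1 for plants and >= 2 for
#: consumers, so the three classes partition any community.
TL_CLASSES = ("TL=1", "2<=TL<=3", "TL>3")


class IntegrationError(RuntimeError):
    pass


@dataclass
class SimulationResult:
    B_final: np.ndarray            # (S,) biomass at the horizon, 0 if extinct
    alive: np.ndarray              # (S,) bool
    t_final: float
    extinction_times: np.ndarray   # (S,) NaN for survivors
    n_steps: int = 0
    trajectory_t: np.ndarray | None = None
    trajectory_B: np.ndarray | None = None   # (n_times, S)


@dataclass
class CommunityMetrics:
    """Steady-state summary: survivor count, summed biomass and production,
    plus the same three numbers per trophic-level class."""

    diversity: int
    biomass: float
    production: float
    per_tl: dict = field(default_factory=dict)   # class label -> dict


def draw_initial_biomasses(
    S: int,
    rng: np.random.Generator,
    low: float = 0.05,
    high: float = 1.0,
) -> np.ndarray:
    """I.i.d. uniform initial biomasses on [low, high].

    Paired with/without-NTI runs must reuse the same draw.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    return rng.uniform(low, high, size=S)


def _kernel_args(params: ModelParams, nti: NTIState) -> tuple:
    f = np.ascontiguousarray
    WA = params.w[:, None] * params.a_base
    # trophic links as an edge list (row-major, ~600 entries)
    t_cons, t_res = np.nonzero(params.adjacency)
    # interference layer as an edge list (it is sparse: ~100 links)
    d_src, d_tgt = np.nonzero(nti.delta)
    d_val = nti.delta[d_src, d_tgt].astype(np.float64)
    return (
        t_cons.astype(np.int64), t_res.astype(np.int64),
        f(WA[t_cons, t_res]), f((WA * params.h)[t_cons, t_res]),
        f(params.eps[t_cons, t_res]),
        f(params.m), f(params.K), f(params.r), f(params.x), f(params.d),
        f(params.adjacency.astype(np.float64)),
        f(nti.gamma.T.astype(np.float64)),
        d_src.astype(np.int64), d_tgt.astype(np.int64), d_val,
        f(nti.phi.T.astype(np.float64)), f(nti.eta.T.astype(np.float64)),
        f(nti.n_mat.T.astype(np.float64)), f(nti.p_mat.T.astype(np.float64)),
        float(nti.c0), float(nti.i0), float(nti.i0_intra),
        float(nti.n0), float(nti.p0), float(nti.r0_refuge), float(nti.e0),
        float(params.q),
    )


def _integrate_scipy(params, nti, B0, t_max, threshold, rtol, atol,
                     record_trajectory):
    y = B0.copy()
    ext_time = np.full(params.S, np.nan)
    below = y < threshold
    y[below] = 0.0
    ext_time[below] = 0.0
    ts, Bs = [0.0], [y.copy()]
    t = 0.0
    n_steps = 0
    fun = lambda _t, B: rhs(params, nti, B)
    while t < t_max:
        solver = RK45(fun, t, y, t_max, rtol=rtol, atol=atol)
        while solver.status == "running":
            solver.step()
            n_steps += 1
            t, y = solver.t, solver.y.copy()
            newly = (y != 0.0) & (y < threshold)
            if record_trajectory:
                ts.append(t)
                Bs.append(np.where(newly, 0.0, y))
            if newly.any():
                y[newly] = 0.0
                ext_time[newly] = t
                break   # restart the stepper from the clamped state
        if solver.status == "failed":
            raise IntegrationError(f"solver step failed at t={t:.4g}")
        if solver.status == "finished" and not ((y != 0.0) & (y < threshold)).any():
            t = solver.t
            break
    traj_t = np.array(ts) if record_trajectory else None
    traj_B = np.array(Bs) if record_trajectory else None
    return SimulationResult(
        B_final=y, alive=y >= threshold, t_final=t,
        extinction_times=ext_time, n_steps=n_steps,
        trajectory_t=traj_t, trajectory_B=traj_B,
    )


def integrate(
    params: ModelParams,
    nti: NTIState,
    B0: np.ndarray,
    t_max: float = 5000.0,
    threshold: float = 1e-6,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    backend: str = "numba",
    record_trajectory: bool = False,
    max_steps: int = 20_000_000,
) -> SimulationResult:
    """Integrate the community to ``t_max`` with extinction clamping.

    Raises :class:`IntegrationError` on step-size underflow or non-finite
    states, with the failure time in the message.
    """
    B0 = np.asarray(B0, dtype=float)
    if B0.shape != (params.S,):
        raise ValueError("B0 must have length S")
    if not np.isfinite(B0).all() or (B0 < 0).any():
        raise ValueError("B0 must be finite and nonnegative")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if backend == "scipy" or record_trajectory:
        return _integrate_scipy(params, nti, B0, t_max, threshold, rtol, atol,
                                record_trajectory)
    if backend != "numba":
        raise ValueError(f"unknown backend {backend!r}")
    y, ext_time, status, n_steps = _kernel.integrate_kernel(
        B0, float(t_max), float(threshold), float(rtol), float(atol),
        max_steps, *_kernel_args(params, nti),
    )
    if status == _kernel.STATUS_STEP_UNDERFLOW:
        t_fail = np.nanmax(np.where(np.isnan(ext_time), 0.0, ext_time))
        raise IntegrationError(
            f"step-size underflow after {n_steps} steps (last extinction at "
            f"t={t_fail:.4g})"
        )
    if status == _kernel.STATUS_MAX_STEPS:
        raise IntegrationError(f"step budget exhausted ({max_steps} steps)")
    return SimulationResult(
        B_final=y, alive=y >= threshold, t_final=float(t_max),
        extinction_times=ext_time, n_steps=int(n_steps),
    )


def _tl_class_masks(TL: np.ndarray) -> dict:
    TL = np.asarray(TL, dtype=float)
    return {
        "TL=1": TL <= 1.5,
        "2<=TL<=3": (TL > 1.5) & (TL <= 3.0),
        "TL>3": TL > 3.0,
    }


def compute_metrics(
    result: SimulationResult,
    params: ModelParams,
    nti: NTIState,
    TL: np.ndarray,
) -> CommunityMetrics:
    """Diversity, total biomass and total production at the final state.

    Production is the first term of the balance equation — intrinsic plant
    growth plus food uptake minus consumer respiration — summed over
    survivors (extinct species contribute exactly zero).
    """
    B = result.B_final
    prod = production_rate(params, nti, B)
    masks = _tl_class_masks(TL)
    per_tl = {
        label: {
            "diversity": int((result.alive & mask).sum()),
            "biomass": float(B[mask].sum()),
            "production": float(prod[mask].sum()),
        }
        for label, mask in masks.items()
    }
    return CommunityMetrics(
        diversity=int(result.alive.sum()),
        biomass=float(B.sum()),
        production=float(prod.sum()),
        per_tl=per_tl,
    )


def normalized_ratio(metric_with: float, metric_without: float) -> float:
    """Relative change ``(with - without) / without``; NaN when the baseline
    is zero (recorded as missing)."""
    if metric_without == 0:
        return float("nan")
    return (metric_with - metric_without) / metric_without
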