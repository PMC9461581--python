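"""Limiting cases of the two-agent social foraging model.

Three idealized regimes bracket the finite-coupling models:

* **NC** (no coupling): agents are i.i.d. given the shared depletion
  drift; the group departs at the *max* of the individual
  first-passage times.
* **D_inf** (perfect diffusive coupling): the half-difference
  ``x_- = (x1 - x2)/2`` is an Ornstein--Uhlenbeck process with
  relaxation rate ``2*kappa`` and variance ``B/(4 kappa)
  (1 - e^{-4 kappa t})``, which vanishes as ``kappa -> inf``; both
  beliefs collapse onto the average ``x_+``, whose SDE carries *half*
  the diffusion scale (``sqrt(B) dW`` instead of ``sqrt(2B) dW``).
  The group time is the single first-passage time of that averaged
  process.
* **P_inf** (perfect pulsatile coupling): the first decider instantly
  triggers everyone, so the group time is the *min* of N i.i.d.
  first-passage times, ``f_min = N f S^{N-1}``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal

import numpy as np

from .fpt import FPTDensity, GridSpec, adaptive_grid, depletion_drift, solve_fp_1d
from .model import PatchEnvironment

__all__ = [
    "LimitCase",
    "ou_half_difference_variance",
    "d_infinity_fpt",
    "p_infinity_group_fpt",
    "nc_group_fpt",
]


@dataclasses.dataclass(frozen=True)
class LimitCase:
    """Effective 1D description of a limiting regime."""

    label: Literal["NC", "D_inf", "P_inf"]
    diffusion_scale: float  # D in dx = mu dt + sqrt(2D) dW
    group_rule: Literal["max", "shared", "min"]


def limit_case(label: str, noise_scale: float) -> LimitCase:
    """Build the :class:`LimitCase` for a given group noise scale B."""
    if label == "NC":
        return LimitCase("NC", noise_scale, "max")
    if label == "D_inf":
        # perfect diffusive coupling halves the effective diffusion
        return LimitCase("D_inf", noise_scale / 2.0, "shared")
    if label == "P_inf":
        return LimitCase("P_inf", noise_scale, "min")
    raise ValueError(f"unknown limit case {label!r}")


def ou_half_difference_variance(kappa: float, noise_scale: float, t) -> np.ndarray | float:
    """Variance of the belief half-difference under diffusive coupling.

    For two diffusively coupled agents the half-difference
    ``x_- = (x1 - x2)/2`` obeys ``dx_- = -2 kappa x_- dt + sqrt(B/...)``
    noise of intensity B, giving

        Var[x_-](t) = B / (4 kappa) * (1 - exp(-4 kappa t)),

    monotone in ``t`` with stationary value ``B/(4 kappa)`` that
    vanishes in the strong-coupling limit.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    out = noise_scale / (4.0 * kappa) * -np.expm1(-4.0 * kappa * t)
    return float(out) if out.ndim == 0 else out


def _single_fpt(
    env: PatchEnvironment,
    theta: float,
    diffusion: float,
    n_agents: int,
    horizon: float,
    grid: GridSpec | None,
    min_captured: float,
):
    drift = depletion_drift(env, n_agents)
    if grid is None:
        grid = adaptive_grid(drift, diffusion, theta, horizon)
    return solve_fp_1d(
        drift, diffusion, theta, grid, init=None, t_span=horizon, min_captured=min_captured
    )


def d_infinity_fpt(
    env: PatchEnvironment,
    theta: float,
    noise_scale: float,
    n_agents: int = 2,
    horizon: float = 60.0,
    grid: GridSpec | None = None,
    min_captured: float = 0.999,
) -> FPTDensity:
    """Group departure density under perfect diffusive coupling.

    The shared belief follows ``dx = (rho e^{-N t/tau} - alpha) dt +
    sqrt(B) dW`` (effective diffusion scale ``B/2``); the group time is
    this single first-passage time.
    """
    if theta >= 0:
        raise ValueError("theta must be negative")
    sol = _single_fpt(env, theta, noise_scale / 2.0, n_agents, horizon, grid, min_captured)
    return sol.fpt


def p_infinity_group_fpt(
    env: PatchEnvironment,
    theta: float,
    noise_scale: float,
    n_agents: int = 2,
    horizon: float = 60.0,
    grid: GridSpec | None = None,
    min_captured: float = 0.999,
) -> FPTDensity:
    """Group departure density under perfect pulsatile coupling.

    The first decider triggers everyone: the group time is the minimum
    of ``N`` i.i.d. first-passage times of the full-noise process, with
    order-statistic density ``f_min = N f S^{N-1}``.
    """
    if theta >= 0:
        raise ValueError("theta must be negative")
    sol = _single_fpt(env, theta, noise_scale, n_agents, horizon, grid, min_captured)
    f = sol.fpt.density
    s = np.clip(sol.fpt.survival, 0.0, None)
    f_min = n_agents * f * s ** (n_agents - 1)
    surv_min = s**n_agents
    return FPTDensity(time_grid=sol.fpt.time_grid, density=f_min, survival=surv_min)


def nc_group_fpt(
    env: PatchEnvironment,
    theta: float,
    noise_scale: float,
    n_agents: int = 2,
    horizon: float = 60.0,
    min_captured: float = 0.995,
) -> FPTDensity:
    """Group departure (max) density with no coupling.

    For ``N = 2`` this is computed by exact propagation: the
    first-decider density ``f_1 = 2 f S`` under the two-agent depletion
    drift, then conditional propagation of the survivor's interior
    density under the one-agent drift; the group density is the
    marginal of the second passage time.  Larger groups fall back to
    Monte Carlo (see :func:`patchforage.simulate.simulate_dataset` with
    ``mode='none'``).
    """
    if n_agents != 2:
        raise NotImplementedError("exact propagation implemented for N=2")
    from .likelihood import LikelihoodSettings, pair_density_table

    settings = LikelihoodSettings(horizon=horizon)
    table = pair_density_table("none", theta, 0.0, noise_scale, env, settings)
    return table.second_time_marginal(min_captured=min_captured)
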