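"""Euler--Maruyama Monte Carlo engine for coupled patch-departure bouts.

The stepping loop lives in a numba kernel so that the strategy sweeps
and likelihood banks (thousands of bouts per parameter point) stay
cheap.  One root seed spawns an independent per-trial stream via
``numpy.random.SeedSequence``, so a dataset is reproducible and each
trial's draw sequence does not depend on how trials are batched.

Per step, every agent receives the shared depletion drift
``rho*exp(-Lambda) - alpha`` plus its coupling increment, and
independent Gaussian noise ``sqrt(2 B dt) z``.  Threshold crossings are
detected at step resolution (no sub-step bridge correction); a crossing
is recorded at the end time of the crossing step.  In pulsatile mode
the pulse cascade is resolved before the next step, and cascade-
triggered decisions share the trigger's recorded time with the
``simultaneous`` flag set.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from numba import njit

from .model import (
    DepartureRecord,
    GroupModel,
    SimulationSettings,
    Trajectory,
)

__all__ = [
    "simulate_bout",
    "simulate_dataset",
    "records_from_dataset",
    "dataset_pairs",
    "empirical_departure_distribution",
    "simulate_free_pair",
    "TruncationError",
]

_MODE_CODE = {"none": 0, "diffusive": 1, "pulsatile": 2}


class TruncationError(RuntimeError):
    """Raised when an agent is still undecided at the simulation horizon."""


@njit(cache=True)
def _simulate_trials(
    seeds,
    n_agents,
    thetas,
    kappas,
    mode,
    rho,
    alpha,
    tau,
    noise_b,
    dt,
    n_steps,
    traj_out,
    record_traj,
):
    """Simulate one bout per seed; returns (times, simultaneous, ok).

    ``times[t, i]`` is agent i's decision time in trial t (nan if the
    horizon was hit), ``simultaneous[t, i]`` marks pulse-triggered
    decisions.  ``traj_out`` is filled for trial 0 when requested.
    """
    n_trials = seeds.shape[0]
    times = np.full((n_trials, n_agents), np.nan)
    simflag = np.zeros((n_trials, n_agents), dtype=np.bool_)
    ok = np.ones(n_trials, dtype=np.bool_)
    sqdt = math.sqrt(2.0 * noise_b * dt)

    for trial in range(n_trials):
        np.random.seed(seeds[trial])
        x = np.zeros(n_agents)
        decided = np.zeros(n_agents, dtype=np.bool_)
        n_active = n_agents
        lam = 0.0  # depletion exponent Lambda(t)
        if record_traj and trial == 0:
            for i in range(n_agents):
                traj_out[0, i] = 0.0
            traj_out[0, n_agents] = float(n_agents)

        for step in range(n_steps):
            if n_active == 0:
                break
            mu = rho * math.exp(-lam) - alpha
            # coupling increments (diffusive); decided agents have gap 0
            if mode == 1:
                gap_sum = 0.0
                for i in range(n_agents):
                    if not decided[i]:
                        gap_sum += x[i] - thetas[i]
                for i in range(n_agents):
                    if not decided[i]:
                        gap_i = x[i] - thetas[i]
                        x[i] += kappas[i] * (gap_sum - n_agents * gap_i) * dt
            # drift + noise (noise drawn for every agent to keep the
            # stream identical across modes at matched seeds)
            for i in range(n_agents):
                z = np.random.standard_normal()
                if not decided[i]:
                    x[i] += mu * dt + sqdt * z
            t_end = (step + 1) * dt
            # grid crossings
            n_new = 0
            for i in range(n_agents):
                if not decided[i] and x[i] <= thetas[i]:
                    decided[i] = True
                    x[i] = thetas[i]
                    times[trial, i] = t_end
                    n_new += 1
            # pulsatile cascade: each new decider emits one pulse to all
            # still-undecided agents; repeat until no new crossings
            if mode == 2:
                while n_new > 0:
                    pulses = n_new
                    n_new = 0
                    for i in range(n_agents):
                        if not decided[i]:
                            x[i] -= kappas[i] * pulses
                            if x[i] <= thetas[i]:
                                decided[i] = True
                                x[i] = thetas[i]
                                times[trial, i] = t_end
                                simflag[trial, i] = True
                                n_new += 1
            lam += n_active * dt / tau
            n_active = 0
            for i in range(n_agents):
                if not decided[i]:
                    n_active += 1
            if record_traj and trial == 0:
                for i in range(n_agents):
                    traj_out[step + 1, i] = x[i]
                traj_out[step + 1, n_agents] = float(n_active)
        if n_active > 0:
            ok[trial] = False
    return times, simflag, ok


def _trial_seeds(seed: int, n_trials: int) -> np.ndarray:
    """Independent 32-bit per-trial seeds spawned from one root seed."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n_trials, dtype=np.uint32).astype(np.int64)


def _run(model: GroupModel, settings: SimulationSettings, record_trajectory: bool):
    n_steps = int(math.ceil(settings.t_max / settings.dt))
    n_agents = model.n_agents
    seeds = _trial_seeds(settings.seed, settings.n_trials)
    if record_trajectory:
        traj = np.zeros((n_steps + 1, n_agents + 1))
    else:
        traj = np.zeros((1, n_agents + 1))
    times, simflag, ok = _simulate_trials(
        seeds,
        n_agents,
        model.thetas,
        model.kappas,
        _MODE_CODE[model.mode],
        model.env.rho,
        model.env.alpha,
        model.env.tau,
        model.noise_scale,
        settings.dt,
        n_steps,
        traj,
        record_trajectory,
    )
    if not ok.all():
        bad = int(np.flatnonzero(~ok)[0])
        raise TruncationError(
            f"trial {bad}: agent(s) undecided at t_max={settings.t_max}; "
            "increase t_max (drift eventually approaches -alpha, so a "
            "longer horizon always suffices)"
        )
    return times, simflag, traj, n_steps


def _record_from_times(times_row: np.ndarray, sim_row: np.ndarray) -> DepartureRecord:
    # at tied times the pulse trigger (simultaneous=False) precedes the
    # cascade-triggered decisions it caused
    order = np.lexsort((np.arange(len(times_row)), sim_row, times_row))
    return DepartureRecord(
        ordered_times=times_row[order],
        decider_order=order,
        simultaneous=sim_row[order],
    )


def simulate_bout(
    model: GroupModel,
    settings: SimulationSettings,
    record_trajectory: bool = False,
) -> DepartureRecord | tuple[DepartureRecord, Trajectory]:
    """Simulate a single bout (the first trial of ``settings``).

    Returns the :class:`DepartureRecord`, plus the belief
    :class:`Trajectory` when ``record_trajectory`` is set.
    """
    one = SimulationSettings(
        dt=settings.dt, t_max=settings.t_max, n_trials=1, seed=settings.seed
    )
    times, simflag, traj, n_steps = _run(model, one, record_trajectory)
    record = _record_from_times(times[0], simflag[0])
    if not record_trajectory:
        return record
    grid = np.arange(n_steps + 1) * settings.dt
    last = min(int(round(record.group_time / settings.dt)), n_steps)
    trajectory = Trajectory(
        times=grid[: last + 1],
        states=traj[: last + 1, : model.n_agents].copy(),
        n_active=traj[: last + 1, model.n_agents].astype(int),
    )
    return record, trajectory


def simulate_dataset(model: GroupModel, settings: SimulationSettings) -> pd.DataFrame:
    """Simulate ``settings.n_trials`` bouts into a long-format table.

    Columns: ``trial, agent, decision_time, decision_rank,
    simultaneous`` — one row per (trial, agent), ranks 1..N in decision
    order within each trial.
    """
    times, simflag, _, _ = _run(model, settings, False)
    n_trials, n_agents = times.shape
    trial_idx = np.repeat(np.arange(n_trials), n_agents)
    agent_idx = np.tile(np.arange(n_agents), n_trials)
    order = np.lexsort((agent_idx, simflag.ravel(), times.ravel(), trial_idx))
    ranks_flat = np.empty(n_trials * n_agents, dtype=int)
    ranks_flat[order] = np.tile(np.arange(1, n_agents + 1), n_trials)
    ranks = ranks_flat.reshape(n_trials, n_agents)
    return pd.DataFrame(
        {
            "trial": np.repeat(np.arange(n_trials), n_agents),
            "agent": np.tile(np.arange(n_agents), n_trials),
            "decision_time": times.ravel(),
            "decision_rank": ranks.ravel(),
            "simultaneous": simflag.ravel(),
        }
    )


def records_from_dataset(dataset: pd.DataFrame) -> list[DepartureRecord]:
    """Rebuild per-bout :class:`DepartureRecord` objects from the table."""
    records = []
    for _, grp in dataset.groupby("trial", sort=True):
        grp = grp.sort_values("decision_rank")
        records.append(
            DepartureRecord(
                ordered_times=grp["decision_time"].to_numpy(),
                decider_order=grp["agent"].to_numpy(),
                simultaneous=grp["simultaneous"].to_numpy(),
            )
        )
    return records


def dataset_pairs(dataset: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (T_first, T_second, tie_flag) arrays from a two-agent table."""
    n_agents = dataset["agent"].nunique()
    if n_agents != 2:
        raise ValueError(f"pair extraction requires 2 agents, found {n_agents}")
    piv = dataset.pivot_table(
        index="trial", columns="decision_rank", values="decision_time", sort=True
    )
    t1 = piv[1].to_numpy(float)
    t2 = piv[2].to_numpy(float)
    tie = (
        dataset[dataset["decision_rank"] == 2]
        .sort_values("trial")["simultaneous"]
        .to_numpy(bool)
    )
    return t1, t2, tie


def empirical_departure_distribution(
    dataset: pd.DataFrame | np.ndarray, bin_width: float = 0.25
) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalized histogram of group departure times.

    Accepts a long-format dataset (group time = last decision per
    trial) or a raw array of group times.  Returns ``(bin_edges,
    density, mean_time)`` with the density integrating to 1.
    """
    if isinstance(dataset, pd.DataFrame):
        if len(dataset) == 0:
            raise ValueError("empty dataset")
        group_times = dataset.groupby("trial")["decision_time"].max().to_numpy()
    else:
        group_times = np.asarray(dataset, dtype=float)
        if group_times.size == 0:
            raise ValueError("empty dataset")
    lo = 0.0
    hi = max(group_times.max() + bin_width, bin_width)
    edges = np.arange(lo, hi + bin_width, bin_width)
    density, edges = np.histogram(group_times, bins=edges, density=True)
    return edges, density, float(group_times.mean())


@njit(cache=True)
def _free_pair_kernel(seeds, kappa, noise_b, dt, n_steps, out_idx, out):
    sqdt = math.sqrt(2.0 * noise_b * dt)
    for trial in range(seeds.shape[0]):
        np.random.seed(seeds[trial])
        x1 = 0.0
        x2 = 0.0
        k = 0
        for step in range(n_steps):
            # diffusive coupling with equal thresholds: gap difference
            c = kappa * (x2 - x1)
            x1 += c * dt + sqdt * np.random.standard_normal()
            x2 += -c * dt + sqdt * np.random.standard_normal()
            if k < out_idx.shape[0] and step + 1 == out_idx[k]:
                out[trial, k, 0] = x1
                out[trial, k, 1] = x2
                k += 1


def simulate_free_pair(
    kappa: float,
    noise_scale: float,
    sample_times: np.ndarray,
    dt: float,
    n_trials: int,
    seed: int,
) -> np.ndarray:
    """Two diffusively coupled beliefs with zero net drift and no absorption.

    Used to probe the Ornstein--Uhlenbeck half-difference analytics:
    with ``rho = alpha = 0`` the half-difference ``x_- = (x1 - x2)/2``
    relaxes at rate ``2*kappa`` toward zero with stationary variance
    ``B/(4*kappa)``.  Returns states of shape ``(n_trials,
    len(sample_times), 2)``.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    out_idx = np.rint(sample_times / dt).astype(np.int64)
    if np.any(out_idx < 1):
        raise ValueError("sample times must be >= dt")
    n_steps = int(out_idx.max())
    out = np.zeros((n_trials, len(sample_times), 2))
    seeds = _trial_seeds(seed, n_trials)
    _free_pair_kernel(seeds, kappa, noise_scale, dt, n_steps, out_idx, out)
    return out
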