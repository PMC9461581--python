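"""Core domain types and shared dynamics for social patch-foraging models.

A group of ``N`` foragers exploits a depleting patch. Each agent ``i``
carries a scalar belief ``x_i(t)`` (its motivation to stay) that drifts
with the net energy intake rate and diffuses with sensory/encounter
noise; the agent commits to leaving when ``x_i`` first reaches its
negative threshold ``theta_i``.  Because the group is cohesive, it
departs at ``T_N = max_i T_i``.

The patch resource starts at density ``rho`` and depletes with timescale
``tau`` per still-foraging agent, so the drift shared by all agents is

    mu(t) = rho * exp(-Lambda(t)) - alpha,
    Lambda(t) = (1/tau) * integral_0^t  N_active(s) ds,

where ``N_active`` is the non-increasing counting function of agents
still foraging and ``alpha`` is the constant cost of foraging/travel.
The integrated (continuous) form of the depletion exponent is used
throughout: it keeps the resource density continuous across individual
decision times and is the form consistent with the group reward
accounting in :mod:`patchforage.reward`.

Two information-sharing modes couple the agents' beliefs:

* *diffusive* — each agent is continuously attracted to the others'
  distance-to-threshold:  ``sum_{j != i} kappa_i ((x_j - theta_j) -
  (x_i - theta_i))``;
* *pulsatile* — at the instant an agent decides, every undecided agent
  receives an instantaneous decrement ``kappa_i`` toward its own
  threshold, possibly triggering an immediate cascade of decisions.

Decided agents' beliefs are clamped at their thresholds and keep
participating in diffusive coupling with zero distance-to-threshold.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "PatchEnvironment",
    "AgentStrategy",
    "GroupModel",
    "SimulationSettings",
    "Trajectory",
    "DepartureRecord",
    "counting_function",
    "depletion_exponent",
    "drift",
    "coupling_drift_diffusive",
    "apply_pulse",
]

CouplingMode = Literal["none", "diffusive", "pulsatile"]


@dataclasses.dataclass(frozen=True)
class PatchEnvironment:
    """Resource and cost parameters of a single patch visit.

    Parameters
    ----------
    rho : float
        Initial resource density (energy per unit time). Must exceed
        ``alpha`` so foraging is initially profitable.
    tau : float
        Patch depletion timescale per foraging agent (time units).
    alpha : float
        Constant energy cost rate of foraging and travel.
    travel_time : float
        Inter-patch travel time ``T_I`` entering the reward rate.
    """

    rho: float = 2.0
    tau: float = 5.0
    alpha: float = 1.0
    travel_time: float = 5.0

    def __post_init__(self) -> None:
        if not self.rho > self.alpha:
            raise ValueError(
                f"require rho > alpha (initial gain must exceed cost); "
                f"got rho={self.rho}, alpha={self.alpha}"
            )
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.travel_time < 0:
            raise ValueError(f"travel_time must be >= 0, got {self.travel_time}")


@dataclasses.dataclass(frozen=True)
class AgentStrategy:
    """Per-agent decision threshold and received coupling strength.

    ``theta`` is strictly negative (increment--decrement strategy: food
    encounters push the belief up, away from the threshold).  ``kappa``
    is the strength with which this agent weights social information:
    units 1/time in diffusive mode, belief units (jump size) in
    pulsatile mode.
    """

    theta: float
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if not self.theta < 0:
            raise ValueError(f"theta must be strictly negative, got {self.theta}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be nonnegative, got {self.kappa}")


@dataclasses.dataclass(frozen=True)
class GroupModel:
    """A foraging group: coupling mode, strategies, noise scale, patch."""

    mode: CouplingMode
    agents: tuple[AgentStrategy, ...]
    noise_scale: float  # diffusion scale B: dx gets sqrt(2 B dt) noise
    env: PatchEnvironment = dataclasses.field(default_factory=PatchEnvironment)

    def __post_init__(self) -> None:
        if self.mode not in ("none", "diffusive", "pulsatile"):
            raise ValueError(f"unknown coupling mode {self.mode!r}")
        if len(self.agents) < 1:
            raise ValueError("group needs at least one agent")
        if not self.noise_scale > 0:
            raise ValueError(f"noise_scale B must be positive, got {self.noise_scale}")
        object.__setattr__(self, "agents", tuple(self.agents))

    @property
    def n_agents(self) -> int:
        return len(self.agents)

    @property
    def thetas(self) -> np.ndarray:
        return np.array([a.theta for a in self.agents])

    @property
    def kappas(self) -> np.ndarray:
        # mode "none" ignores kappa entirely
        if self.mode == "none":
            return np.zeros(len(self.agents))
        return np.array([a.kappa for a in self.agents])

    @classmethod
    def symmetric(
        cls,
        mode: CouplingMode,
        n_agents: int,
        theta: float,
        kappa: float,
        noise_scale: float,
        env: PatchEnvironment | None = None,
    ) -> "GroupModel":
        """Homogeneous group: every agent shares (theta, kappa)."""
        env = env if env is not None else PatchEnvironment()
        agents = tuple(AgentStrategy(theta, kappa) for _ in range(n_agents))
        return cls(mode=mode, agents=agents, noise_scale=noise_scale, env=env)


@dataclasses.dataclass(frozen=True)
class SimulationSettings:
    """Euler--Maruyama discretization and trial bookkeeping."""

    dt: float = 0.005
    t_max: float = 200.0
    n_trials: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.t_max > 0:
            raise ValueError("t_max must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclasses.dataclass
class Trajectory:
    """One bout's belief paths on the simulation grid.

    ``states[k, i]`` is agent ``i``'s belief at ``times[k]``; decided
    agents are clamped at their thresholds.  ``n_active[k]`` samples the
    counting function on the same grid (right-continuous).
    """

    times: np.ndarray
    states: np.ndarray
    n_active: np.ndarray


@dataclasses.dataclass
class DepartureRecord:
    """Ordered individual decision times of one foraging bout.

    ``ordered_times`` is sorted ascending; ``decider_order`` holds the
    agent index of each successive decision; ``simultaneous[k]`` is True
    when decision ``k`` was triggered instantaneously by a pulse
    cascade (and therefore shares its recorded time with the trigger).
    """

    ordered_times: np.ndarray
    decider_order: np.ndarray
    simultaneous: np.ndarray

    def __post_init__(self) -> None:
        self.ordered_times = np.asarray(self.ordered_times, dtype=float)
        self.decider_order = np.asarray(self.decider_order, dtype=int)
        self.simultaneous = np.asarray(self.simultaneous, dtype=bool)
        if np.any(np.diff(self.ordered_times) < 0):
            raise ValueError("ordered_times must be sorted ascending")

    @property
    def group_time(self) -> float:
        """Group departure time T_N = max of individual decision times."""
        return float(self.ordered_times[-1])

    @property
    def n_agents(self) -> int:
        return len(self.ordered_times)


# ---------------------------------------------------------------------------
# Shared dynamics
# ---------------------------------------------------------------------------


def counting_function(ordered_times: Sequence[float], t: float, n_agents: int) -> int:
    """Number of agents still foraging at time ``t``.

    Right-continuous: at exactly a decision time the post-decision count
    is returned.  Piecewise constant and non-increasing, starting at
    ``n_agents`` and reaching 0 after the last decision.
    """
    if t < 0:
        raise ValueError(f"t must be nonnegative, got {t}")
    times = np.asarray(ordered_times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("ordered_times must be sorted ascending")
    return int(n_agents - np.searchsorted(times, t, side="right"))


def depletion_exponent(
    ordered_times: Sequence[float], t: float, tau: float, n_agents: int
) -> float:
    """Cumulative depletion Lambda(t) = (1/tau) * int_0^t N_active(s) ds.

    Continuous, non-decreasing, piecewise linear with slope
    ``N_active(t)/tau``; the patch density ``rho*exp(-Lambda)`` stays
    continuous across decision times.
    """
    if t < 0:
        raise ValueError(f"t must be nonnegative, got {t}")
    if tau <= 0:
        raise ValueError("tau must be positive")
    times = np.asarray(ordered_times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("ordered_times must be sorted ascending")
    # integral of the step function: sum over inter-decision segments
    integral = 0.0
    prev = 0.0
    active = n_agents
    for t_dec in times:
        if t_dec >= t:
            break
        integral += active * (t_dec - prev)
        prev = t_dec
        active -= 1
    integral += active * (t - prev)
    return integral / tau


def drift(
    ordered_times: Sequence[float], t: float, env: PatchEnvironment, n_agents: int
) -> float:
    """Belief drift rate rho*exp(-Lambda(t)) - alpha shared by all agents."""
    lam = depletion_exponent(ordered_times, t, env.tau, n_agents)
    return env.rho * np.exp(-lam) - env.alpha


def coupling_drift_diffusive(
    states: np.ndarray,
    strategies: Sequence[AgentStrategy],
    active_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-agent diffusive coupling increments.

    Agent ``i`` receives ``kappa_i * sum_{j != i} (g_j - g_i)`` where
    ``g = x - theta`` is the distance-to-threshold (zero for decided
    agents, whose clamped states pull everyone toward threshold).
    """
    states = np.asarray(states, dtype=float)
    thetas = np.array([s.theta for s in strategies])
    kappas = np.array([s.kappa for s in strategies])
    if states.shape != thetas.shape:
        raise ValueError("states and strategies must have the same length")
    gaps = states - thetas
    if active_mask is not None:
        gaps = np.where(np.asarray(active_mask, dtype=bool), gaps, 0.0)
    n = len(gaps)
    return kappas * (gaps.sum() - n * gaps)


def apply_pulse(
    states: np.ndarray,
    strategies: Sequence[AgentStrategy],
    decider_index: int,
    decided: np.ndarray | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Deliver a decision pulse and resolve the resulting cascade.

    Agent ``decider_index`` has just reached its threshold.  Every
    still-undecided agent ``i`` jumps down by its own coupling strength
    (``x_i -= kappa_i``).  Any agent pushed to or past its threshold is
    clamped there, marked decided at the same instant, and recursively
    emits its own pulse.  Returns the updated states and the cascade of
    newly decided agent indices in trigger order.
    """
    states = np.asarray(states, dtype=float).copy()
    thetas = np.array([s.theta for s in strategies])
    kappas = np.array([s.kappa for s in strategies])
    n = len(states)
    if decided is None:
        decided = states <= thetas
        decided[decider_index] = True
    else:
        decided = np.asarray(decided, dtype=bool).copy()
        if decided[decider_index]:
            raise ValueError(
                f"agent {decider_index} is already decided; cannot emit a new pulse"
            )
        decided[decider_index] = True
    states[decider_index] = thetas[decider_index]

    cascade: list[int] = []
    queue = [decider_index]
    while queue:
        queue.pop(0)
        undecided = np.flatnonzero(~decided)
        if undecided.size == 0:
            break
        states[undecided] -= kappas[undecided]
        crossed = [int(i) for i in undecided if states[i] <= thetas[i]]
        for i in crossed:
            decided[i] = True
            states[i] = thetas[i]
            cascade.append(i)
            queue.append(i)
    return states, cascade
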