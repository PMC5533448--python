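"""PSO and bat-algorithm search over a bounded 2-D integer grid (S, K).

Both swarms fly in continuous space; positions are decoded (rounded half-up,
clamped) to integer grid points before every objective call.  Fitness values
are opaque to this module: a pluggable ``comparator(best, candidate) -> bool``
decides whether a candidate replaces an incumbent, which is how the
kappa-floor acceptance rule is injected without this module knowing about
kappa at all.

PSO velocity/position update (per agent i, dimension d, iteration k):

    v_id <- w*v_id + c1*r1*(pbest_id - x_id) + c2*r2*(gbest_d - x_id)
    x_id <- x_id + v_id

Bat algorithm update (x* the current global best):

    f_i <- Q_min + (Q_max - Q_min)*beta,  beta ~ U[0,1]
    v_i <- v_i + (x_i - x*) * f_i
    x_i <- x_i + v_i

with a loudness-gated acceptance step and a pulse-rate-gated local walk
around the global best.  The inertia weight w defaults to 0.729 (a standard
stable constriction-equivalent setting) and is exposed in the config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SwarmConfig",
    "AgentState",
    "TraceEntry",
    "pso_step",
    "ba_step",
    "optimize",
    "brute_force_grid",
]

Bounds = tuple[tuple[int, int], tuple[int, int]]
Comparator = Callable[[object, object], bool]
Objective = Callable[[int, int], object]


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters (population 20, 1000 iterations, c1=c2=1.5,
    loudness 0.5, pulse rate 1, frequency range [0, 2] by default)."""

    population: int = 20
    iterations: int = 1000
    c1: float = 1.5
    c2: float = 1.5
    inertia: float = 0.729
    loudness_A: float = 0.5
    pulse_rate_r: float = 1.0
    Q_min: float = 0.0
    Q_max: float = 2.0
    alpha: float = 0.9
    gamma: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1, c2 must be non-negative")
        if self.Q_min > self.Q_max:
            raise ValueError("Q_min must not exceed Q_max")
        if not 0 <= self.loudness_A <= 1:
            raise ValueError("loudness must lie in [0, 1]")
        if not 0 <= self.pulse_rate_r <= 1:
            raise ValueError("pulse rate must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SwarmConfig":
        """Accepts the conventional config-file names (A, r, Qmin, Qmax...)."""
        alias = {"A": "loudness_A", "r": "pulse_rate_r",
                 "Qmin": "Q_min", "Qmax": "Q_max", "w": "inertia"}
        kw = {alias.get(k, k): v for k, v in d.items()}
        return cls(**kw)


@dataclass
class AgentState:
    position: np.ndarray
    velocity: np.ndarray
    personal_best_position: np.ndarray
    personal_best_fitness: object
    loudness: float = 0.5
    pulse_rate: float = 1.0
    frequency: float = 0.0


@dataclass(frozen=True)
class TraceEntry:
    iteration: int
    agent: int
    S: int
    K: int
    fitness: object
    accepted: bool


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def decode(position: Sequence[float], bounds: Bounds) -> tuple[int, int]:
    """Continuous position -> in-bounds integer grid point."""
    out = []
    for x, (lo, hi) in zip(position, bounds):
        out.append(min(max(_round_half_up(float(x)), lo), hi))
    return tuple(out)


def _clamp_position(pos: np.ndarray, bounds: Bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    return np.clip(pos, lo, hi)


def _vmax(bounds: Bounds) -> np.ndarray:
    # half the range per dimension, floor 0.5 so degenerate axes still move
    return np.array([max((hi - lo) / 2.0, 0.5) for lo, hi in bounds])


def pso_step(
    agents: list[AgentState],
    global_best: np.ndarray,
    cfg: SwarmConfig,
    bounds: Bounds,
    rng: np.random.Generator,
) -> None:
    """One synchronous PSO velocity/position update, in place."""
    vmax = _vmax(bounds)
    for a in agents:
        r1 = rng.uniform(size=2)
        r2 = rng.uniform(size=2)
        a.velocity = (
            cfg.inertia * a.velocity
            + cfg.c1 * r1 * (a.personal_best_position - a.position)
            + cfg.c2 * r2 * (global_best - a.position)
        )
        a.velocity = np.clip(a.velocity, -vmax, vmax)
        a.position = _clamp_position(a.position + a.velocity, bounds)


def ba_step(
    agents: list[AgentState],
    global_best: np.ndarray,
    cfg: SwarmConfig,
    bounds: Bounds,
    rng: np.random.Generator,
    t: int,
) -> list[np.ndarray]:
    """One bat flight; returns each bat's candidate position to evaluate.

    The flight (frequency-tuned velocity) always moves the bat; when
    rand > pulse_rate the candidate is instead a local walk around the global
    best scaled by the swarm's mean loudness.  Whether the candidate is
    *accepted* (loudness gate + comparator) is decided by the caller after
    evaluation.
    """
    vmax = _vmax(bounds)
    mean_loudness = float(np.mean([a.loudness for a in agents]))
    candidates = []
    for a in agents:
        beta = rng.uniform()
        a.frequency = cfg.Q_min + (cfg.Q_max - cfg.Q_min) * beta
        a.velocity = a.velocity + (a.position - global_best) * a.frequency
        a.velocity = np.clip(a.velocity, -vmax, vmax)
        a.position = _clamp_position(a.position + a.velocity, bounds)
        cand = a.position
        if rng.uniform() > a.pulse_rate:
            eps = rng.uniform(-1.0, 1.0, size=2)
            cand = _clamp_position(global_best + eps * mean_loudness, bounds)
        candidates.append(cand)
    return candidates


def _init_agents(
    cfg: SwarmConfig,
    bounds: Bounds,
    rng: np.random.Generator,
    warm_start: tuple[int, int] | None,
) -> list[AgentState]:
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    agents = []
    for i in range(cfg.population):
        if i == 0 and warm_start is not None:
            pos = np.array(warm_start, dtype=float)
        else:
            pos = rng.uniform(lo, hi)
        agents.append(
            AgentState(
                position=pos,
                velocity=np.zeros(2),
                personal_best_position=pos.copy(),
                personal_best_fitness=None,
                loudness=cfg.loudness_A,
                pulse_rate=cfg.pulse_rate_r,
            )
        )
    return agents


def optimize(
    objective: Objective,
    bounds: Bounds,
    algorithm: str,
    cfg: SwarmConfig,
    comparator: Comparator,
    warm_start: tuple[int, int] | None = None,
) -> tuple[tuple[int, int], object, list[TraceEntry]]:
    """Run a swarm over the integer grid; returns (best point, fitness, trace).

    The incumbent starts as the first evaluated agent's fitness and only ever
    changes when the comparator accepts a candidate, so the returned point was
    actually evaluated and the best fitness is monotone under the comparator.
    Deterministic given ``cfg.seed``.
    """
    if algorithm not in ("pso", "ba"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    for lo, hi in bounds:
        if hi < lo:
            raise ValueError(f"empty bound ({lo}, {hi})")
    rng = np.random.default_rng(cfg.seed)
    agents = _init_agents(cfg, bounds, rng, warm_start)
    trace: list[TraceEntry] = []

    best_point = None
    best_fit = None

    def consider(i, it, point, fit, agent=None):
        nonlocal best_point, best_fit
        if agent is not None:
            if agent.personal_best_fitness is None or comparator(
                agent.personal_best_fitness, fit
            ):
                agent.personal_best_fitness = fit
                agent.personal_best_position = np.array(point, dtype=float)
        if best_fit is None:
            accepted = True
        else:
            accepted = comparator(best_fit, fit)
        if accepted:
            best_fit = fit
            best_point = point
        trace.append(TraceEntry(it, i, point[0], point[1], fit, accepted))
        return accepted

    # initial evaluation (iteration 0)
    for i, a in enumerate(agents):
        pt = decode(a.position, bounds)
        consider(i, 0, pt, objective(*pt), agent=a)

    for t in range(1, cfg.iterations + 1):
        gbest = np.array(best_point, dtype=float)
        if algorithm == "pso":
            pso_step(agents, gbest, cfg, bounds, rng)
            for i, a in enumerate(agents):
                pt = decode(a.position, bounds)
                consider(i, t, pt, objective(*pt), agent=a)
        else:
            candidates = ba_step(agents, gbest, cfg, bounds, rng, t)
            for i, (a, cand) in enumerate(zip(agents, candidates)):
                pt = decode(cand, bounds)
                fit = objective(*pt)
                loud_ok = rng.uniform() < a.loudness
                better = (
                    a.personal_best_fitness is None
                    or comparator(a.personal_best_fitness, fit)
                )
                if loud_ok and better:
                    a.position = np.array(cand, dtype=float)
                    a.personal_best_fitness = fit
                    a.personal_best_position = np.array(pt, dtype=float)
                    a.loudness *= cfg.alpha
                    a.pulse_rate = cfg.pulse_rate_r * (
                        1.0 - math.exp(-cfg.gamma * t)
                    )
                # global incumbent considers every evaluated point
                consider(i, t, pt, fit)
    return best_point, best_fit, trace


def brute_force_grid(
    objective: Objective,
    bounds: Bounds,
    comparator: Comparator,
) -> tuple[tuple[int, int], object, int]:
    """Exhaustive sweep of every integer (S, K) pair; the search oracle.

    Returns (best point, best fitness, evaluation count); the count is
    |S range| x |K range|.
    """
    (s_lo, s_hi), (k_lo, k_hi) = bounds
    best_point = None
    best_fit = None
    count = 0
    for S in range(s_lo, s_hi + 1):
        for K in range(k_lo, k_hi + 1):
            fit = objective(S, K)
            count += 1
            if best_fit is None or comparator(best_fit, fit):
                best_fit = fit
                best_point = (S, K)
    return best_point, best_fit, count
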