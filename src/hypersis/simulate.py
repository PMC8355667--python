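"""Exact individual-level SIS dynamics on (partitioned) hypergraphs.

A susceptible node ``i`` becomes infectious with rate

    beta * sum_h I[i, h] * f(sum_j X_j * I[j, h])

(the inner count includes ``j = i``, which never adds self-infection because
``X_i = 0`` for a susceptible node), and an infected node recovers with rate
``delta``.  On a partitioned hypergraph the sum runs over categories, each
with its own response ``f_k``.

Two simulators are provided: a synchronous discrete-time scheme (one uniform
draw per node per step, flip probabilities ``1 - exp(-rate * dt)``) and a
statistically exact event-driven continuous-time simulator.  Two auxiliary
chains used as analysis oracles are also implemented: the integer-valued
severity process that stochastically dominates the infection process for
concave responses, and the scalar birth-death chain that bounds it from
below in the non-extinction argument.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .hypergraph import Hypergraph, PartitionedHypergraph, build_incidence, comembership

__all__ = [
    "ModelParams",
    "Trajectory",
    "EnsembleSummary",
    "infection_rates",
    "step_discrete",
    "simulate_discrete",
    "simulate_exact",
    "run_ensemble",
    "simulate_severity_chain",
    "simulate_bounding_birth_death",
]


@dataclass(frozen=True)
class ModelParams:
    """Infection strength ``beta``, recovery rate ``delta`` and the
    independent per-node initial infection probability ``i0``."""

    beta: float
    delta: float
    i0: float

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not (0.0 <= self.i0 <= 1.0):
            raise ValueError("i0 must be a probability")


@dataclass
class Trajectory:
    """Recorded path of the infected-count process.

    ``extinction_time`` is the first recorded time with zero infections, or
    ``None`` if the run was censored at the horizon while still active.
    """

    times: np.ndarray
    infected_count: np.ndarray
    extinction_time: float | None = None
    states: np.ndarray | None = None
    seed: object = None

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time", "infected_count"])
            for t, c in zip(self.times, self.infected_count):
                w.writerow([f"{t:.10g}", int(c)])


@dataclass
class EnsembleSummary:
    """Aligned ensemble statistics over runs on a shared hypergraph."""

    times: np.ndarray
    mean_infected_fraction: np.ndarray
    survival_probability: np.ndarray
    run_count: int
    seeds: list
    counts: np.ndarray | None = field(default=None, repr=False)

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time", "mean_infected_fraction", "survival_probability"])
            for t, m, s in zip(self.times, self.mean_infected_fraction, self.survival_probability):
                w.writerow([f"{t:.10g}", f"{m:.10g}", f"{s:.10g}"])

    def to_json(self, path: str, metadata: dict | None = None) -> None:
        doc = {
            "times": self.times.tolist(),
            "mean_infected_fraction": self.mean_infected_fraction.tolist(),
            "survival_probability": self.survival_probability.tolist(),
            "run_count": self.run_count,
            "seeds": [str(s) for s in self.seeds],
        }
        if metadata:
            doc["metadata"] = metadata
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


class _RateEngine:
    """Pre-built incidence matrices and responses for fast rate evaluation."""

    def __init__(self, H, rf):
        if isinstance(H, PartitionedHypergraph):
            if not isinstance(rf, (list, tuple)):
                raise ValueError("a partitioned hypergraph needs one rate function per category")
            if len(rf) != H.K:
                raise ValueError(f"{len(rf)} rate functions for K={H.K} categories")
            self.n = H.n
            self.parts = [
                (build_incidence(H.subhypergraph(k + 1)), rf[k]) for k in range(H.K)
            ]
        else:
            if isinstance(rf, (list, tuple)):
                if len(rf) != 1:
                    raise ValueError("an unpartitioned hypergraph takes a single rate function")
                rf = rf[0]
            self.n = H.n
            self.parts = [(build_incidence(H), rf)]
        self.parts = [(I.tocsr(), I.T.tocsr(), f) for I, f in self.parts]

    def rates(self, x: np.ndarray, beta: float) -> np.ndarray:
        """beta * sum_k I^(k) f_k(I^(k)T x) for every node (caller masks)."""
        out = np.zeros(self.n)
        for I, IT, f in self.parts:
            counts = IT @ x
            out += I @ f.evaluate(counts)
        return beta * out


def infection_rates(H, state: np.ndarray, rf, beta: float) -> np.ndarray:
    """Per-node infection rate vector for the given binary state.

    The value is computed for every node; for an infected node it is the
    same formula evaluated at the current state (the caller masks by
    state).
    """
    x = np.asarray(state, dtype=float)
    engine = _RateEngine(H, rf)
    if x.shape != (engine.n,):
        raise ValueError(f"state has shape {x.shape}, expected ({engine.n},)")
    return engine.rates(x, beta)


def step_discrete(H, state, rf, params: ModelParams, dt: float, rng: np.random.Generator,
                  _engine: _RateEngine | None = None) -> np.ndarray:
    """One synchronous update of the discrete-time scheme.

    A single uniform draw ``r_i`` per node decides both flip types:
    susceptible ``i`` infects if ``r_i < 1 - exp(-rate_i*dt)``; infected
    ``i`` recovers if ``r_i < 1 - exp(-delta*dt)``.  Transitions use the
    pre-step state only.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(state, dtype=float)
    engine = _engine if _engine is not None else _RateEngine(H, rf)
    rates = engine.rates(x, params.beta)
    r = rng.random(engine.n)
    p_inf = -np.expm1(-rates * dt)
    p_rec = -math.expm1(-params.delta * dt)
    new = x.copy()
    sus = x == 0
    new[sus & (r < p_inf)] = 1.0
    new[~sus & (r < p_rec)] = 0.0
    return new


def _resolve_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _initial_state(n, i0, rng):
    return (rng.random(n) < i0).astype(float)


def simulate_discrete(H, params: ModelParams, rf, T: float, dt: float, seed,
                      *, x0: np.ndarray | None = None,
                      record_states: bool = False) -> Trajectory:
    """Iterate the synchronous scheme to time ``T`` on a fixed grid.

    The initial state is i.i.d. Bernoulli(i0) unless ``x0`` is supplied.
    Zero infection is absorbing, so iteration stops early at extinction and
    the remaining grid is filled with zeros.
    """
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be positive")
    rng = _resolve_rng(seed)
    engine = _RateEngine(H, rf)
    n_steps = int(round(T / dt))
    times = np.arange(n_steps + 1) * dt
    x = _initial_state(engine.n, params.i0, rng) if x0 is None else np.asarray(x0, dtype=float).copy()
    counts = np.zeros(n_steps + 1, dtype=np.int64)
    counts[0] = int(x.sum())
    history = [x.copy()] if record_states else None
    extinct_at = 0.0 if counts[0] == 0 else None
    for k in range(1, n_steps + 1):
        if extinct_at is None:
            x = step_discrete(H, x, rf, params, dt, rng, _engine=engine)
            counts[k] = int(x.sum())
            if counts[k] == 0:
                extinct_at = times[k]
        if record_states:
            history.append(x.copy())
    states = np.array(history) if record_states else None
    return Trajectory(times=times, infected_count=counts, extinction_time=extinct_at,
                      states=states, seed=seed)


def simulate_exact(H, params: ModelParams, rf, T: float, seed,
                   *, x0: np.ndarray | None = None) -> Trajectory:
    """Statistically exact event-driven simulation of the continuous-time
    Markov chain.

    Waiting times are exponential with the current total rate (sum of
    susceptible infection rates plus ``delta`` times the infected count);
    the event node is chosen proportionally to its rate.  Event times and
    counts are recorded; censoring at ``T`` leaves ``extinction_time`` None.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    rng = _resolve_rng(seed)
    engine = _RateEngine(H, rf)
    x = _initial_state(engine.n, params.i0, rng) if x0 is None else np.asarray(x0, dtype=float).copy()
    t = 0.0
    times = [0.0]
    counts = [int(x.sum())]
    extinct_at = 0.0 if counts[0] == 0 else None
    while extinct_at is None:
        inf_rates = engine.rates(x, params.beta)
        inf_rates[x == 1] = 0.0
        rec_rates = params.delta * x
        total = inf_rates.sum() + rec_rates.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > T:
            break
        cum = np.cumsum(inf_rates + rec_rates)
        node = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        x[node] = 1.0 - x[node]
        times.append(t)
        counts.append(int(x.sum()))
        if counts[-1] == 0:
            extinct_at = t
    return Trajectory(times=np.array(times), infected_count=np.array(counts, dtype=np.int64),
                      extinction_time=extinct_at, seed=seed)


def sample_trajectory(traj: Trajectory, grid: np.ndarray) -> np.ndarray:
    """Piecewise-constant (right-continuous) sampling of a trajectory's
    infected count on a time grid; zero after extinction."""
    idx = np.searchsorted(traj.times, grid, side="right") - 1
    vals = traj.infected_count[np.clip(idx, 0, len(traj.times) - 1)]
    vals = vals.astype(float)
    if traj.extinction_time is not None:
        vals[grid >= traj.extinction_time] = 0.0
    elif traj.times[-1] < grid[-1]:
        # censored run: hold the last observed count
        vals[grid > traj.times[-1]] = traj.infected_count[-1]
    return vals


def run_seed(base_seed: int, run_index: int) -> np.random.SeedSequence:
    """Deterministic per-run seed: ``SeedSequence((base_seed, run_index))``.

    Counter-style derivation keeps ensembles reproducible and trivially
    parallelizable without shared RNG state.
    """
    return np.random.SeedSequence((int(base_seed), int(run_index)))


def run_ensemble(H, params: ModelParams, rf, T: float, n_runs: int, base_seed: int,
                 *, dt: float | None = None, exact: bool = False,
                 record_dt: float = 0.5, share_initial_state: bool = True) -> EnsembleSummary:
    """Independent trajectories on the SAME hypergraph, aligned on a grid.

    ``share_initial_state=True`` draws one Bernoulli(i0) state and reuses it
    across runs (the documented default for figure reproduction);
    ``False`` redraws per run.  Discrete runs use ``dt``; ``exact=True``
    runs the event-driven simulator and samples it on a grid of spacing
    ``record_dt``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not exact and dt is None:
        raise ValueError("dt is required for the discrete simulator (or pass exact=True)")
    engine = _RateEngine(H, rf)
    x0 = None
    if share_initial_state:
        x0 = _initial_state(engine.n, params.i0, np.random.default_rng(run_seed(base_seed, 0)))
    grid = np.arange(int(round(T / (dt if not exact else record_dt))) + 1) * (dt if not exact else record_dt)
    all_counts = np.zeros((n_runs, len(grid)))
    seeds = []
    for r in range(n_runs):
        ss = run_seed(base_seed, r + 1)
        seeds.append(ss)
        rng = np.random.default_rng(ss)
        if exact:
            traj = simulate_exact(H, params, rf, T, rng, x0=x0)
            all_counts[r] = sample_trajectory(traj, grid)
        else:
            traj = simulate_discrete(H, params, rf, T, dt, rng, x0=x0)
            all_counts[r] = traj.infected_count
    return EnsembleSummary(
        times=grid,
        mean_infected_fraction=all_counts.mean(axis=0) / engine.n,
        survival_probability=(all_counts > 0).mean(axis=0),
        run_count=n_runs,
        seeds=seeds,
        counts=all_counts,
    )


def simulate_severity_chain(H: Hypergraph, params: ModelParams, rf, T: float, seed,
                            *, y0: np.ndarray | None = None,
                            severity_cap: int = 100_000) -> Trajectory:
    """Event-driven simulation of the dominating integer severity process.

    Component ``i`` jumps up with rate ``beta * f'(0) * (W @ Y)_i`` and down
    with rate ``delta * Y_i``.  Requires a concave response (the domination
    argument uses ``f(x) <= f'(0) x``).  Total severity is capped at
    ``severity_cap`` with a warning, since the process is unbounded.
    """
    if not rf.is_concave:
        raise ValueError("severity-chain domination requires a concave rate function")
    rng = _resolve_rng(seed)
    W = comembership(H)
    n = H.n
    y = (_initial_state(n, params.i0, rng) if y0 is None else np.asarray(y0, dtype=float)).copy()
    c0 = params.beta * rf.derivative_at_zero
    t = 0.0
    times = [0.0]
    totals = [int(y.sum())]
    extinct_at = 0.0 if totals[0] == 0 else None
    capped = False
    while extinct_at is None:
        up = c0 * (W @ y)
        down = params.delta * y
        if y.sum() >= severity_cap:
            if not capped:
                warnings.warn(f"severity cap {severity_cap} hit; upward jumps suppressed")
                capped = True
            up = np.zeros_like(up)
        total = up.sum() + down.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > T:
            break
        r = rng.random() * total
        cum = np.cumsum(np.concatenate([up, down]))
        k = int(np.searchsorted(cum, r, side="right"))
        if k < n:
            y[k] += 1
        else:
            y[k - n] -= 1
        times.append(t)
        totals.append(int(y.sum()))
        if totals[-1] == 0:
            extinct_at = t
    return Trajectory(times=np.array(times), infected_count=np.array(totals, dtype=np.int64),
                      extinction_time=extinct_at, seed=seed)


def simulate_bounding_birth_death(m_cap: int, up_rate_coeff: float, delta: float,
                                  z0: int, T: float, seed) -> Trajectory:
    """Scalar birth-death chain on ``{0, ..., m_cap}`` with up rate
    ``k * up_rate_coeff`` (suppressed at the cap) and down rate ``k * delta``.

    The infection count stochastically dominates this chain in the
    non-extinction argument; it serves as the Monte-Carlo oracle for the
    persistence bound.
    """
    if z0 > m_cap:
        raise ValueError("z0 must not exceed m_cap")
    rng = _resolve_rng(seed)
    k = int(z0)
    t = 0.0
    times = [0.0]
    vals = [k]
    extinct_at = 0.0 if k == 0 else None
    while extinct_at is None:
        up = k * up_rate_coeff if k < m_cap else 0.0
        down = k * delta
        total = up + down
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > T:
            break
        k += 1 if rng.random() * total < up else -1
        times.append(t)
        vals.append(k)
        if k == 0:
            extinct_at = t
    return Trajectory(times=np.array(times), infected_count=np.array(vals, dtype=np.int64),
                      extinction_time=extinct_at, seed=seed)
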