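"""Deterministic mean-field approximation of the hypergraph SIS process.

The node infection probabilities ``p_i(t)`` evolve under

    dp_i/dt = g_i(P) = beta * sum_h I[i,h] * f(sum_j p_j I[j,h]) * (1 - p_i)
                       - delta * p_i

with the category-summed analogue on a partitioned hypergraph.  The inner
sum deliberately includes the node's own ``p_i``: the self-term is part of
the approximation, and no correction is applied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .hypergraph import PartitionedHypergraph, build_incidence
from .simulate import ModelParams

__all__ = [
    "MeanFieldTrajectory",
    "meanfield_rhs",
    "integrate_euler",
    "integrate_adaptive",
    "jacobian",
    "equilibrium_norm_decay",
]


@dataclass
class MeanFieldTrajectory:
    """Times, probability states and the count of boundary projections
    applied by the Euler integrator."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n)
    clamp_events: int = 0

    @property
    def mean_fraction(self) -> np.ndarray:
        return self.states.mean(axis=1)

    def to_csv(self, path: str, summary_only: bool = True) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            if summary_only:
                w.writerow(["time", "mean_fraction"])
                for t, m in zip(self.times, self.mean_fraction):
                    w.writerow([f"{t:.10g}", f"{m:.10g}"])
            else:
                n = self.states.shape[1]
                w.writerow(["time"] + [f"p_{i}" for i in range(n)])
                for t, row in zip(self.times, self.states):
                    w.writerow([f"{t:.10g}"] + [f"{v:.10g}" for v in row])


def _parts(H, rf):
    """(I, I.T, rate-fn) triples, one per category."""
    if isinstance(H, PartitionedHypergraph):
        if not isinstance(rf, (list, tuple)) or len(rf) != H.K:
            raise ValueError(f"need {H.K} rate functions for the partitioned hypergraph")
        triples = []
        for k in range(H.K):
            I = build_incidence(H.subhypergraph(k + 1))
            triples.append((I.tocsr(), I.T.tocsr(), rf[k]))
        return H.n, triples
    if isinstance(rf, (list, tuple)):
        if len(rf) != 1:
            raise ValueError("an unpartitioned hypergraph takes a single rate function")
        rf = rf[0]
    I = build_incidence(H)
    return H.n, [(I.tocsr(), I.T.tocsr(), rf)]


def meanfield_rhs(P: np.ndarray, H, params: ModelParams, rf) -> np.ndarray:
    """The vector field ``g(P)``."""
    n, triples = _parts(H, rf)
    p = np.asarray(P, dtype=float)
    if p.shape != (n,):
        raise ValueError(f"state has shape {p.shape}, expected ({n},)")
    pressure = np.zeros(n)
    for I, IT, f in triples:
        pressure += I @ f.evaluate(IT @ p)
    return params.beta * pressure * (1.0 - p) - params.delta * p


def integrate_euler(P0, H, params: ModelParams, rf, dt: float, T: float) -> MeanFieldTrajectory:
    """Explicit Euler with post-step projection onto ``[0, 1]^n``.

    Projections are counted in ``clamp_events`` rather than silently
    applied: they are discretization artefacts of large steps.
    """
    if dt <= 0 or T <= 0:
        raise ValueError("dt and T must be positive")
    n, triples = _parts(H, rf)
    p = np.asarray(P0, dtype=float).copy()
    n_steps = int(round(T / dt))
    times = np.arange(n_steps + 1) * dt
    states = np.zeros((n_steps + 1, n))
    states[0] = p
    clamps = 0
    for k in range(1, n_steps + 1):
        pressure = np.zeros(n)
        for I, IT, f in triples:
            pressure += I @ f.evaluate(IT @ p)
        p = p + dt * (params.beta * pressure * (1.0 - p) - params.delta * p)
        if (p < 0).any() or (p > 1).any():
            clamps += int(((p < 0) | (p > 1)).sum())
            p = np.clip(p, 0.0, 1.0)
        states[k] = p
    return MeanFieldTrajectory(times=times, states=states, clamp_events=clamps)


def integrate_adaptive(P0, H, params: ModelParams, rf, T: float, tol: float = 1e-8,
                       t_eval: np.ndarray | None = None) -> MeanFieldTrajectory:
    """Adaptive error-controlled reference integration (RK45)."""
    if tol <= 0 or T <= 0:
        raise ValueError("T and tol must be positive")
    n, triples = _parts(H, rf)

    def rhs(_t, p):
        pressure = np.zeros(n)
        for I, IT, f in triples:
            pressure += I @ f.evaluate(IT @ p)
        return params.beta * pressure * (1.0 - p) - params.delta * p

    sol = solve_ivp(rhs, (0.0, T), np.asarray(P0, dtype=float), method="RK45",
                    rtol=tol, atol=tol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return MeanFieldTrajectory(times=sol.t, states=sol.y.T, clamp_events=0)


def jacobian(P, H, params: ModelParams, rf) -> np.ndarray:
    """Analytic Jacobian of ``g`` at ``P``.

    Entry (i, j): ``beta * (1 - p_i) * sum_k sum_h I_ih I_jh f_k'(s_h)``
    where ``s_h`` is the hyperedge probability mass, with the extra diagonal
    terms ``-beta * sum_h I_ih f(s_h) - delta``.  Kinked responses use the
    one-sided derivative from below.

    At ``P = 0`` this reduces to ``beta * f'(0) * W - delta * I`` (and the
    category-weighted analogue).
    """
    n, triples = _parts(H, rf)
    p = np.asarray(P, dtype=float)
    if p.shape != (n,):
        raise ValueError(f"state has shape {p.shape}, expected ({n},)")
    J = np.zeros((n, n))
    pressure = np.zeros(n)
    for I, IT, f in triples:
        s = IT @ p
        fp = f.derivative(s)
        J += (I.multiply(fp[np.newaxis, :]) @ I.T).toarray()
        pressure += I @ f.evaluate(s)
    J *= params.beta * (1.0 - p)[:, np.newaxis]
    J -= np.diag(params.beta * pressure + params.delta)
    return J


def equilibrium_norm_decay(traj: MeanFieldTrajectory, tail_fraction: float = 0.5):
    """Check eventual monotone decay of the Euclidean norm and fit an
    exponential rate over the trajectory tail.

    Returns ``(decaying, rate)`` where ``rate`` is the fitted d(log||P||)/dt
    (None when the tail reaches numerical zero).
    """
    if len(traj.times) < 3:
        raise ValueError("trajectory too short")
    norms = np.linalg.norm(traj.states, axis=1)
    k0 = int(len(norms) * (1.0 - tail_fraction))
    tail = norms[k0:]
    t_tail = traj.times[k0:]
    if np.all(tail < 1e-300):
        return True, None
    decaying = bool(np.all(np.diff(tail) <= 1e-12 * max(tail[0], 1.0)))
    pos = tail > 0
    if pos.sum() < 2:
        return decaying, None
    rate = float(np.polyfit(t_tail[pos], np.log(tail[pos]), 1)[0])
    return decaying, rate
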