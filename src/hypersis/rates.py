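"""Infection-response functions.

Each hyperedge contributes ``f(#infected members)`` to the infection rate of
its susceptible members.  All functions satisfy ``f(0) = 0``.  Concave
families (identity, capped linear, scaled log, arctan) model collective
suppression; the step and hinge families model collective contagion, where
spread inside a hyperedge needs a threshold number of infectious members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "RateFunction",
    "RateFamily",
    "make_rate_function",
    "parse_rate_spec",
    "concave_majorant_slope",
    "check_concavity",
]


@dataclass(frozen=True)
class RateFunction:
    """A named infection response with analytic metadata.

    ``derivative_at_zero`` is stored analytically per family (thresholds must
    be exact, so no numerical differentiation).  ``derivative`` evaluates
    f' elementwise, using the one-sided derivative from below at kinks.
    """

    name: str
    params: dict = field(default_factory=dict)
    evaluate: Callable[[np.ndarray], np.ndarray] = None
    derivative: Callable[[np.ndarray], np.ndarray] = None
    derivative_at_zero: float = 0.0
    is_concave: bool = False
    is_nondecreasing: bool = True

    def __call__(self, x):
        return self.evaluate(np.asarray(x, dtype=float))

    def spec_string(self) -> str:
        if not self.params:
            return self.name
        inner = ",".join(f"{k}={v:g}" for k, v in self.params.items())
        return f"{self.name}:{inner}"


# Family of RateFunctions for a partitioned hypergraph: functions[k-1]
# applies to category k.
RateFamily = list


def _require_positive(params: dict, keys: list[str]) -> None:
    for k in keys:
        if params[k] <= 0:
            raise ValueError(f"parameter {k} must be positive, got {params[k]}")


def make_rate_function(name: str, **params) -> RateFunction:
    """Build a rate function by family name.

    Families: ``identity``; ``capped_linear`` (min(x, c)); ``log1p``
    (a*log(1+x)); ``arctan``; ``step`` (c2*1{x >= c1}); ``hinge``
    (max(0, x-c)).
    """
    if name == "identity":
        return RateFunction(
            name="identity",
            evaluate=lambda x: x.astype(float),
            derivative=lambda x: np.ones_like(x, dtype=float),
            derivative_at_zero=1.0,
            is_concave=True,
        )
    if name == "capped_linear":
        _require_positive(params, ["c"])
        c = float(params["c"])
        return RateFunction(
            name="capped_linear",
            params={"c": c},
            evaluate=lambda x: np.minimum(x, c),
            # one-sided derivative from below at the kink x = c
            derivative=lambda x: np.where(x <= c, 1.0, 0.0),
            derivative_at_zero=1.0,
            is_concave=True,
        )
    if name == "log1p":
        a = float(params.get("a", 1.0))
        if a <= 0:
            raise ValueError(f"parameter a must be positive, got {a}")
        return RateFunction(
            name="log1p",
            params={"a": a},
            evaluate=lambda x: a * np.log1p(x),
            derivative=lambda x: a / (1.0 + x),
            derivative_at_zero=a,
            is_concave=True,
        )
    if name == "arctan":
        return RateFunction(
            name="arctan",
            evaluate=np.arctan,
            derivative=lambda x: 1.0 / (1.0 + x**2),
            derivative_at_zero=1.0,
            is_concave=True,
        )
    if name == "step":
        _require_positive(params, ["c1", "c2"])
        c1, c2 = float(params["c1"]), float(params["c2"])
        return RateFunction(
            name="step",
            params={"c1": c1, "c2": c2},
            evaluate=lambda x: np.where(x >= c1, c2, 0.0),
            derivative=lambda x: np.zeros_like(x, dtype=float),
            derivative_at_zero=0.0,
            is_concave=False,
        )
    if name == "hinge":
        _require_positive(params, ["c"])
        c = float(params["c"])
        return RateFunction(
            name="hinge",
            params={"c": c},
            evaluate=lambda x: np.maximum(0.0, x - c),
            derivative=lambda x: np.where(x <= c, 0.0, 1.0),
            derivative_at_zero=0.0,
            is_concave=False,  # convex, and not dominated by f'(0)*x
        )
    raise ValueError(f"unknown rate function {name!r}")


def parse_rate_spec(spec: str) -> RateFunction:
    """Parse config-file syntax like ``"step:c1=2,c2=1"`` or ``"identity"``."""
    if ":" in spec:
        name, rest = spec.split(":", 1)
        params = {}
        for item in rest.split(","):
            k, v = item.split("=")
            params[k.strip()] = float(v)
        return make_rate_function(name.strip(), **params)
    return make_rate_function(spec.strip())


def concave_majorant_slope(rf: RateFunction, e_max: int) -> float:
    """Slope ``c_f`` of the smallest implemented linear majorant of ``rf`` on
    ``[0, e_max - 1]`` (so ``c_f * x >= f(x)`` there).

    Concave families use f'(0); the step family uses ``c2/c1``; the hinge
    family uses ``(e_max-1-c)/(e_max-1)``.  Anything else falls back to
    ``max f(x)/x`` over integer x — an extension beyond the named families,
    flagged in reports.
    """
    if e_max < 2:
        raise ValueError("e_max must be >= 2")
    if rf.is_concave:
        return rf.derivative_at_zero
    if rf.name == "step":
        return rf.params["c2"] / rf.params["c1"]
    if rf.name == "hinge":
        c = rf.params["c"]
        if c >= e_max - 1:
            return 0.0
        return (e_max - 1 - c) / (e_max - 1)
    xs = np.arange(1, e_max, dtype=float)
    return float(np.max(rf(xs) / xs))


def check_concavity(rf: RateFunction, e_max: int, n_grid: int = 257) -> bool:
    """Midpoint-concavity check of ``rf`` on a grid over ``[0, e_max - 1]``.

    Gates the concave-only stability and extinction theorems; returns False
    on any violation beyond a small numerical slack.
    """
    if e_max < 2:
        raise ValueError("e_max must be >= 2")
    xs = np.linspace(0.0, float(e_max - 1), n_grid)
    a, b = np.meshgrid(xs, xs)
    mid = rf((a + b) / 2.0)
    avg = (rf(a) + rf(b)) / 2.0
    return bool(np.all(mid >= avg - 1e-12))
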