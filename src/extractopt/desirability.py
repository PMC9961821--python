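"""Derringer desirability functions and multi-response optimization.

Each response prediction is mapped to an individual desirability
d in [0, 1] through a one-sided ramp (maximize or minimize) or a
two-sided target ramp, and the overall desirability is the weighted
geometric mean

    D = (d1^w1 * d2^w2 * ... * dn^wn)^(1 / sum(w)).

D is maximized over a coded-unit box by Nelder-Mead restarts seeded on
a fixed coarse grid, which makes the search deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import optimize

from .design import decode_point
from .rsm import QuadraticModel, predict

__all__ = [
    "ResponseGoal",
    "DesirabilitySpec",
    "OptimizationResult",
    "ValidationReport",
    "individual_desirability",
    "overall_desirability",
    "optimize_desirability",
    "validation_rsd",
]


@dataclass(frozen=True)
class ResponseGoal:
    """Goal for one response: maximize, minimize, or target in [L, U]."""

    goal: str  # "maximize" | "minimize" | "target"
    low: float
    high: float
    weight: float = 1.0
    target: float | None = None  # required for goal="target"

    def __post_init__(self) -> None:
        if self.goal not in ("maximize", "minimize", "target"):
            raise ValueError(f"unknown goal {self.goal!r}")
        if not self.low < self.high:
            raise ValueError("require L < U")
        if not self.weight > 0:
            raise ValueError("weights must be > 0")
        if self.goal == "target":
            if self.target is None or not (self.low < self.target < self.high):
                raise ValueError("target goal needs L < target < U")


@dataclass
class DesirabilitySpec:
    """Per-response goals keyed by response name."""

    goals: dict[str, ResponseGoal]

    @classmethod
    def maximize_observed(cls, names, values: np.ndarray, weight: float = 1.0):
        """Maximize every response with limits at its observed min/max.

        This is the usual convention when no external specification
        limits exist: d = 0 at the worst observed value, 1 at the best.
        """
        goals = {
            n: ResponseGoal("maximize", float(values[:, j].min()), float(values[:, j].max()), weight)
            for j, n in enumerate(names)
        }
        return cls(goals)


def individual_desirability(value: float, goal: ResponseGoal) -> float:
    """Ramp desirability of one predicted value under one goal."""
    L, U, w = goal.low, goal.high, goal.weight
    if goal.goal == "maximize":
        if value <= L:
            return 0.0
        if value >= U:
            return 1.0
        return ((value - L) / (U - L)) ** w
    if goal.goal == "minimize":
        if value >= U:
            return 0.0
        if value <= L:
            return 1.0
        return ((U - value) / (U - L)) ** w
    # two-sided target ramp
    T = goal.target
    if value <= L or value >= U:
        return 0.0
    if value <= T:
        return ((value - L) / (T - L)) ** w
    return ((U - value) / (U - T)) ** w


def overall_desirability(d: np.ndarray | list, w: np.ndarray | list | None = None) -> float:
    """Weighted geometric mean of individual desirabilities."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError("individual desirabilities must lie in [0, 1]")
    w = np.ones_like(d) if w is None else np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    if np.any(d == 0):
        return 0.0
    return float(np.exp(np.sum(w * np.log(d)) / np.sum(w)))


@dataclass
class OptimizationResult:
    point_coded: np.ndarray
    point_natural: np.ndarray
    predicted: dict[str, float]
    individual: dict[str, float]
    D: float
    all_zero: bool = field(default=False)  # no point with D > 0 was found

    def to_dict(self) -> dict:
        return {
            "point_coded": [float(v) for v in self.point_coded],
            "point_natural": [float(v) for v in self.point_natural],
            "predicted": self.predicted,
            "individual": self.individual,
            "D": self.D,
            "all_zero": self.all_zero,
        }


def _evaluate(models, spec, x):
    preds, ds, ws = {}, {}, []
    for m in models:
        g = spec.goals[m.response]
        v = predict(m, x, coded=True)
        preds[m.response] = float(v)
        ds[m.response] = individual_desirability(float(v), g)
        ws.append(g.weight)
    D = overall_desirability(list(ds.values()), ws)
    return preds, ds, D


def optimize_desirability(
    models: list[QuadraticModel],
    spec: DesirabilitySpec,
    region: tuple[float, float] | list[tuple[float, float]] = (-1.0, 1.0),
    n_grid: int = 5,
    tol: float = 1e-8,
) -> OptimizationResult:
    """Maximize overall desirability over a coded box.

    ``region`` is either one (lo, hi) pair applied to every factor or a
    per-factor list. Nelder-Mead is restarted from every node of an
    ``n_grid``-per-axis lattice; the fixed start list makes the result
    deterministic. If D = 0 everywhere the best grid point is returned
    with ``all_zero=True``.
    """
    if not models:
        raise ValueError("need at least one model")
    k = models[0].k
    bounds = [tuple(region)] * k if np.ndim(region) == 1 else [tuple(r) for r in region]
    if len(bounds) != k:
        raise ValueError("region does not match factor count")

    def neg_d(x):
        return -_evaluate(models, spec, x)[2]

    axes = [np.linspace(lo, hi, n_grid) for lo, hi in bounds]
    best_x, best_d = None, -1.0
    for start in product(*axes):
        res = optimize.minimize(
            neg_d,
            np.asarray(start),
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-6, "fatol": tol, "maxiter": 2000},
        )
        if -res.fun > best_d:
            best_d, best_x = -res.fun, res.x
    best_x = np.clip(best_x, [b[0] for b in bounds], [b[1] for b in bounds])
    preds, ds, D = _evaluate(models, spec, best_x)
    return OptimizationResult(
        point_coded=best_x,
        point_natural=decode_point(best_x, models[0].factors),
        predicted=preds,
        individual=ds,
        D=D,
        all_zero=(D == 0.0),
    )


@dataclass
class ValidationReport:
    response: str
    experimental: float
    predicted: float
    std: float
    rsd_fraction: float
    rsd_percent: float


def validation_rsd(experimental: float, predicted: float, response: str = "y") -> ValidationReport:
    """Agreement between one experimental and one predicted value.

    ``std`` is the two-value sample standard deviation |e - p| / sqrt(2)
    and RSD divides it by the pair mean — reported both as a fraction
    and as a percentage.
    """
    mean = (experimental + predicted) / 2.0
    if np.isclose(mean, 0.0):
        raise ValueError("RSD undefined: mean of the pair is zero")
    std = abs(experimental - predicted) / np.sqrt(2.0)
    return ValidationReport(
        response=response,
        experimental=experimental,
        predicted=predicted,
        std=float(std),
        rsd_fraction=float(std / mean),
        rsd_percent=float(100.0 * std / mean),
    )
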