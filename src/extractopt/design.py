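"""Rotatable central composite designs and design/response tables.

A central composite design (CCD) for ``k`` factors consists of a full
2^k factorial block at coded levels ±1, ``2k`` axial (star) points at
coded ±alpha on one axis, and ``n_center`` replicated center runs. The
replicated centers supply the pure-error estimate that the lack-of-fit
test needs; the axial points make the pure quadratic terms estimable.

Factors are handled in two unit systems: *natural* units (e.g. percent
ethanol) and dimensionless *coded* units ``(natural - center) / step``.
All model coefficients downstream live in coded units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignMatrix",
    "ResponseTable",
    "build_ccd",
    "code_point",
    "decode_point",
    "load_table",
    "write_table",
]


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor and its coding convention.

    ``step`` is the natural-unit change corresponding to one coded unit,
    and ``axial_alpha`` the coded distance of the star points.
    """

    name: str
    center: float
    step: float
    axial_alpha: float = 2.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.center):
            raise ValueError(f"factor {self.name!r}: center must be finite")
        if not (self.step > 0):
            raise ValueError(f"factor {self.name!r}: step must be > 0")
        if not (self.axial_alpha > 0):
            raise ValueError(f"factor {self.name!r}: axial_alpha must be > 0")

    def code(self, x: float | np.ndarray) -> float | np.ndarray:
        return (x - self.center) / self.step

    def decode(self, z: float | np.ndarray) -> float | np.ndarray:
        return z * self.step + self.center


# Factors of the packaged 20-run hot-extraction study: five equally spaced
# levels per factor (e.g. ethanol 0/25/50/75/100 %) force these centers,
# steps and axial distance alpha = 2.
DEFAULT_FACTORS = (
    FactorSpec("ethanol_pct", center=50.0, step=25.0, axial_alpha=2.0),
    FactorSpec("time_h", center=3.0, step=1.0, axial_alpha=2.0),
    FactorSpec("temp_C", center=60.0, step=10.0, axial_alpha=2.0),
)

RUN_FACTORIAL = "factorial"
RUN_AXIAL = "axial"
RUN_CENTER = "center"


@dataclass
class DesignMatrix:
    """Runs of a CCD in natural and coded units with per-run type labels."""

    factors: tuple[FactorSpec, ...]
    natural: np.ndarray  # (n_runs, k)
    coded: np.ndarray  # (n_runs, k)
    run_type: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return self.natural.shape[0]

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def center_mask(self) -> np.ndarray:
        return np.array([t == RUN_CENTER for t in self.run_type])

    def replicate_groups(self) -> list[np.ndarray]:
        """Indices of runs sharing identical coded coordinates (any group size)."""
        seen: dict[tuple, list[int]] = {}
        for i, row in enumerate(np.round(self.coded, 10)):
            seen.setdefault(tuple(row), []).append(i)
        return [np.asarray(ix) for ix in seen.values()]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.natural, columns=self.factor_names)
        df["run_type"] = self.run_type
        return df


@dataclass
class ResponseTable:
    """Observed responses, one column per assay, aligned with a DesignMatrix."""

    names: list[str]
    values: np.ndarray  # (n_runs, n_responses)
    units: dict[str, str] = field(default_factory=dict)
    metadata: pd.DataFrame | None = None  # e.g. reported replicate SDs

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be a runs x responses matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response values must all be finite")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


def build_ccd(
    factors: list[FactorSpec] | tuple[FactorSpec, ...], n_center: int
) -> DesignMatrix:
    """Construct a full CCD: 2^k factorial + 2k axial + n_center center runs.

    Run ordering is deterministic: factorial points in binary order
    (last factor fastest), axial points factor by factor (-alpha then
    +alpha), then the center replicates.
    """
    factors = tuple(factors)
    k = len(factors)
    if k < 2:
        raise ValueError("a CCD needs at least 2 factors")
    if n_center < 1:
        raise ValueError("a CCD needs at least 1 center run")

    rows: list[list[float]] = []
    types: list[str] = []
    for combo in itertools.product((-1.0, 1.0), repeat=k):
        rows.append(list(combo))
        types.append(RUN_FACTORIAL)
    for j, f in enumerate(factors):
        for sign in (-1.0, 1.0):
            point = [0.0] * k
            point[j] = sign * f.axial_alpha
            rows.append(point)
            types.append(RUN_AXIAL)
    for _ in range(n_center):
        rows.append([0.0] * k)
        types.append(RUN_CENTER)

    coded = np.asarray(rows)
    natural = decode_point(coded, factors)
    return DesignMatrix(factors=factors, natural=natural, coded=coded, run_type=types)


def code_point(
    point: np.ndarray | list, factors: tuple[FactorSpec, ...] | list[FactorSpec]
) -> np.ndarray:
    """Natural units -> coded units, componentwise (vectorised over rows)."""
    point = np.asarray(point, dtype=float)
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    return (point - centers) / steps


def decode_point(
    point: np.ndarray | list, factors: tuple[FactorSpec, ...] | list[FactorSpec]
) -> np.ndarray:
    """Coded units -> natural units; exact inverse of :func:`code_point`."""
    point = np.asarray(point, dtype=float)
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    return point * steps + centers


class DesignParseError(ValueError):
    """Raised when a design/response table fails geometric validation."""


def _infer_factor(name: str, column: np.ndarray) -> FactorSpec:
    """Infer center/step/alpha from the distinct levels of one CCD factor.

    A full CCD shows five levels (center, ±1, ±alpha) or three when
    alpha == 1. Levels must be symmetric about the center.
    """
    levels = np.unique(column)
    if len(levels) == 5:
        center = levels[2]
        step = levels[3] - center
        alpha = (levels[4] - center) / step
    elif len(levels) == 3:
        center = levels[1]
        step = levels[2] - center
        alpha = 1.0
    else:
        raise DesignParseError(
            f"column {name!r}: expected 3 or 5 distinct CCD levels, got {len(levels)}"
        )
    if not np.allclose(levels + levels[::-1], 2 * center):
        raise DesignParseError(f"column {name!r}: levels are not symmetric about center")
    return FactorSpec(name, center=float(center), step=float(step), axial_alpha=float(alpha))


def _classify_runs(coded: np.ndarray, alphas: np.ndarray) -> list[str]:
    types = []
    for i, row in enumerate(coded):
        nz = np.nonzero(np.abs(row) > 1e-9)[0]
        if len(nz) == 0:
            types.append(RUN_CENTER)
        elif np.all(np.isclose(np.abs(row), 1.0)):
            types.append(RUN_FACTORIAL)
        elif len(nz) == 1 and np.isclose(abs(row[nz[0]]), alphas[nz[0]]):
            types.append(RUN_AXIAL)
        else:
            raise DesignParseError(f"run {i + 1}: unrecognized CCD geometry {row}")
    return types


def load_table(
    path,
    n_factors: int = 3,
    factors: tuple[FactorSpec, ...] | None = None,
) -> tuple[DesignMatrix, ResponseTable]:
    """Read a CSV design/response table: factor columns first, then responses.

    Columns whose name ends in ``_sd`` are treated as side metadata
    (reported replicate standard deviations) and excluded from the
    response matrix. Run types are inferred from the coded geometry;
    a table that is not a recognizable CCD raises DesignParseError.
    """
    df = pd.read_csv(path)
    if df.shape[1] < n_factors:
        raise DesignParseError(f"table needs at least {n_factors} factor columns")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] + 1 if len(bad) else "?"
            raise DesignParseError(f"non-numeric value in column {col!r}, row {row}")

    fac_cols = list(df.columns[:n_factors])
    rest = list(df.columns[n_factors:])
    resp_cols = [c for c in rest if not c.endswith("_sd")]
    sd_cols = [c for c in rest if c.endswith("_sd")]

    natural = df[fac_cols].to_numpy(dtype=float)
    if factors is None:
        factors = tuple(_infer_factor(c, natural[:, j]) for j, c in enumerate(fac_cols))
    coded = code_point(natural, factors)
    alphas = np.array([f.axial_alpha for f in factors])
    types = _classify_runs(coded, alphas)

    n_center = types.count(RUN_CENTER)
    k = len(factors)
    expected = 2**k + 2 * k + n_center
    if len(types) != expected:
        raise DesignParseError(
            f"run count {len(types)} does not match full CCD size {expected} "
            f"(2^{k} + {2 * k} + {n_center} centers)"
        )

    design = DesignMatrix(factors=factors, natural=natural, coded=coded, run_type=types)
    responses = ResponseTable(
        names=resp_cols,
        values=df[resp_cols].to_numpy(dtype=float),
        metadata=df[sd_cols] if sd_cols else None,
    )
    return design, responses


def write_table(path, design: DesignMatrix, responses: ResponseTable) -> None:
    """Write the CSV read back by :func:`load_table` (values round-trip)."""
    df = pd.DataFrame(design.natural, columns=design.factor_names)
    for j, name in enumerate(responses.names):
        df[name] = responses.values[:, j]
    if responses.metadata is not None:
        for c in responses.metadata.columns:
            df[c] = responses.metadata[c].to_numpy()
    df.to_csv(path, index=False)
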