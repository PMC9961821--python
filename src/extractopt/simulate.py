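"""Synthetic CCD datasets and the packaged study fixtures.

The generator instantiates the statistical model the whole analysis
assumes: responses are a known second-order polynomial in the coded
factors plus i.i.d. Gaussian noise, observed on a full central
composite design with replicated center points. That structure is
exactly what the lack-of-fit test, the pure-error estimate and the
coefficient standard errors presuppose, so every downstream stage can
be validated against known truth without any external data.

Defaults mimic the packaged 20-run hot-extraction study: three factors
(ethanol %, time h, temperature °C), the fitted total-phenolic-content
surface as the true polynomial, noise sigma = 0.08 (about the square
root of that model's residual mean square), and six center replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .design import DEFAULT_FACTORS, DesignMatrix, FactorSpec, ResponseTable, build_ccd
from .msannot import AnnotatedCompound, adduct_mz, monoisotopic_mass
from .rsm import model_matrix

__all__ = ["SurfaceSpec", "generate_dataset", "load_fixture", "TPC_SURFACE"]

# Coefficients of the fitted TPC surface, coded units, ordered as
# [1, x1, x2, x3, x1^2, x2^2, x3^2, x1x2, x1x3, x2x3].
TPC_SURFACE = (4.45, 0.34, 0.02, -0.0575, -0.2089, -0.4001, -0.1676, 0.27, -0.005, 0.1425)


@dataclass
class SurfaceSpec:
    """A known quadratic truth on a CCD: the generator's full description."""

    k: int = 3
    coefficients: tuple[float, ...] = TPC_SURFACE
    sigma: float = 0.08
    n_center: int = 6
    seed: int = 0
    factors: tuple[FactorSpec, ...] = field(default=DEFAULT_FACTORS)
    response_name: str = "y"

    def __post_init__(self) -> None:
        p = 1 + 2 * self.k + self.k * (self.k - 1) // 2
        if len(self.coefficients) != p:
            raise ValueError(
                f"need {p} coefficients for k={self.k}, got {len(self.coefficients)}"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if len(self.factors) != self.k:
            raise ValueError("factors must match k")


def generate_dataset(spec: SurfaceSpec) -> tuple[DesignMatrix, ResponseTable]:
    """Simulate one CCD experiment from a known surface.

    Deterministic for a fixed spec (including seed): identical specs
    yield identical tables.
    """
    design = build_ccd(spec.factors, spec.n_center)
    mean = model_matrix(design.coded) @ np.asarray(spec.coefficients)
    rng = np.random.default_rng(spec.seed)
    y = mean + rng.normal(0.0, spec.sigma, size=len(mean))
    table = ResponseTable(names=[spec.response_name], values=y[:, None])
    return design, table


def _load_table1():
    from .design import load_table  # local import to avoid cycle at module load

    with resources.as_file(resources.files("extractopt.data") / "table1.csv") as p:
        return load_table(p, n_factors=3)


def _load_table5() -> list[AnnotatedCompound]:
    with resources.as_file(resources.files("extractopt.data") / "table5.tsv") as p:
        df = pd.read_csv(p, sep="\t")
    compounds = []
    for _, row in df.iterrows():
        frags = [float(v) for v in str(row["fragments"]).split(";") if v]
        recomputed = adduct_mz(monoisotopic_mass(str(row["formula"])), "[M-H]-")
        compounds.append(
            AnnotatedCompound(
                name=str(row["name"]),
                formula=str(row["formula"]),
                observed_neg=None if pd.isna(row["observed_neg"]) else float(row["observed_neg"]),
                observed_pos=None if pd.isna(row["observed_pos"]) else float(row["observed_pos"]),
                calculated_printed=float(row["calculated"]),
                fragments=frags,
                collision_energy=float(row["ce"]),
                confidence_level=int(row["cl"]),
                first_time=bool(row["first_time"]),
                compound_class=str(row["class"]),
                cm_inconsistent=abs(recomputed - float(row["calculated"])) > 0.001,
            )
        )
    return compounds


def load_fixture(name: str):
    """Load a packaged fixture: "table1" (design+responses) or "table5".

    "table1" returns ``(DesignMatrix, ResponseTable)`` for the 20-run
    extraction study; "table5" returns the list of 71 annotated
    compounds from its ESI-MS/MS profile. Compound rows whose printed
    elemental formula and printed calculated m/z disagree by more than
    1 mDa (printing errors in the source table) carry
    ``cm_inconsistent=True``.
    """
    if name == "table1":
        return _load_table1()
    if name == "table5":
        return _load_table5()
    raise KeyError(f"unknown fixture {name!r} (expected 'table1' or 'table5')")
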