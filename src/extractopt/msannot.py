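"""Monoisotopic masses, ESI adduct m/z and neutral-loss annotation.

Utilities for checking compound tables from ESI-MS/MS metabolite
profiling: parse elemental formulas, compute monoisotopic (lightest-
isotope) masses, derive [M-H]- / [M+H]+ adduct m/z, and annotate
fragment-ion lists with the diagnostic neutral losses of plant
secondary metabolites (sugar residues such as hexose 162 Da, and small
molecules such as CO, CO2, H2O, ketene, SO3).

Two adduct conventions are supported. The default subtracts or adds
the hydrogen-ATOM mass (1.007825 Da), which is what compound tables in
the phytochemistry literature usually print. The physically strict
convention (``convention="proton"``) moves a proton (1.007276 Da) with
correct electron bookkeeping; the two differ by the electron mass,
about 0.00055 Da per charge.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ElementalComposition",
    "AnnotatedCompound",
    "FragmentAnnotation",
    "NEUTRAL_LOSSES",
    "MONOISOTOPIC_MASS",
    "HYDROGEN_MASS",
    "PROTON_MASS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "annotate_losses",
]

# lightest-isotope atomic masses (Da)
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
}

HYDROGEN_MASS = MONOISOTOPIC_MASS["H"]
ELECTRON_MASS = 0.00054857990946
PROTON_MASS = HYDROGEN_MASS - ELECTRON_MASS  # 1.0072764...

#: Diagnostic neutral losses (name -> exact mass, Da). "CO2" and the
#: legacy label "COO" are the same 43.9898 Da loss.
NEUTRAL_LOSSES: dict[str, float] = {
    "hexose": 162.0528,
    "deoxyhexose": 146.0579,
    "pentose": 132.0423,
    "H2O": 18.0106,
    "CO": 27.9949,
    "CO2": 43.9898,
    "CH3": 15.0235,
    "C2H2O": 42.0106,
    "SO3": 79.9568,
    "2CO": 55.9898,
    "3CO": 83.9847,
    "CO+CO2": 71.9847,
}
LOSS_ALIASES = {"COO": "CO2", "CO+COO": "CO+CO2"}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed or unsupported elemental formula."""


ElementalComposition = dict[str, int]


def parse_formula(text: str) -> ElementalComposition:
    """Parse a Hill-style formula ("C15H10O7") into element counts.

    Underscore/subscript decoration is stripped; an omitted count means
    one atom. Unknown element symbols raise FormulaError.
    """
    clean = text.replace("_", "").strip()
    if not clean:
        raise FormulaError("empty formula")
    pos = 0
    comp: ElementalComposition = {}
    for m in _TOKEN.finditer(clean):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} near {clean[pos:]!r}")
        if not m.group(0):
            break
        el, cnt = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unsupported element {el!r} in {text!r}")
        comp[el] = comp.get(el, 0) + (int(cnt) if cnt else 1)
        pos = m.end()
    if pos != len(clean):
        raise FormulaError(f"malformed formula {text!r} near {clean[pos:]!r}")
    return comp


def monoisotopic_mass(composition: ElementalComposition | str) -> float:
    """Sum of lightest-isotope atomic masses, in Da."""
    if isinstance(composition, str):
        composition = parse_formula(composition)
    try:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in composition.items())
    except KeyError as err:
        raise FormulaError(f"unsupported element {err.args[0]!r}") from None


def adduct_mz(neutral_mass: float, adduct: str = "[M-H]-", convention: str = "hydrogen") -> float:
    """m/z of a singly charged adduct of a neutral monoisotopic mass.

    ``convention="hydrogen"`` (default) moves a hydrogen atom;
    ``"proton"`` moves a proton with electron bookkeeping.
    """
    if convention == "hydrogen":
        delta = HYDROGEN_MASS
    elif convention == "proton":
        delta = PROTON_MASS
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if adduct in ("[M-H]-", "[M-H]−"):
        if neutral_mass <= delta:
            raise ValueError("neutral mass must exceed the adduct mass")
        return neutral_mass - delta
    if adduct in ("[M+H]+", "[M+H]⁺"):
        return neutral_mass + delta
    raise ValueError(f"unknown adduct {adduct!r}")


def ppm_error(observed: float, calculated: float) -> float:
    """Signed relative error in parts per million."""
    if calculated <= 0:
        raise ValueError("calculated m/z must be > 0")
    return 1e6 * (observed - calculated) / calculated


@dataclass
class FragmentAnnotation:
    """One explained fragment: parent ion, loss name, mass error, path.

    ``path`` records the chain of losses from the precursor down to
    this fragment, e.g. ("hexose", "H2O").
    """

    fragment_mz: float
    parent_mz: float
    loss: str
    error_da: float
    path: tuple[str, ...]


@dataclass
class AnnotatedCompound:
    """One compound row of a profiling table plus its annotations."""

    name: str
    formula: str
    observed_neg: float | None = None
    observed_pos: float | None = None
    calculated_printed: float | None = None
    fragments: list[float] = field(default_factory=list)
    collision_energy: float | None = None
    confidence_level: int | None = None
    first_time: bool = False
    compound_class: str = ""
    cm_inconsistent: bool = False  # printed formula and CM disagree (> 1 mDa)
    annotations: list[FragmentAnnotation] = field(default_factory=list)
    unannotated: list[float] = field(default_factory=list)

    @property
    def composition(self) -> ElementalComposition:
        return parse_formula(self.formula)

    @property
    def calculated_mz_neg(self) -> float:
        return adduct_mz(monoisotopic_mass(self.composition), "[M-H]-")


def annotate_losses(
    precursor_mz: float,
    fragments: list[float],
    table: dict[str, float] | None = None,
    tolerance_da: float = 0.02,
    max_depth: int = 3,
) -> tuple[list[FragmentAnnotation], list[float]]:
    """Explain fragment ions as neutral losses from the precursor.

    Every fragment is tested against the precursor and against every
    heavier already-annotated fragment; each loss whose mass matches
    the parent-fragment difference within ``tolerance_da`` is reported.
    Sequential losses are tracked as paths, capped at ``max_depth``
    steps to bound combinatorial output. Fragments explained by no
    loss are returned in the second list — that is a valid outcome,
    not an error.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance must be > 0")
    table = NEUTRAL_LOSSES if table is None else table
    table = {LOSS_ALIASES.get(k, k): v for k, v in table.items()}

    annotations: list[FragmentAnnotation] = []
    unannotated: list[float] = []
    # parents: (mz, path-of-losses-so-far); fragments processed heavy -> light
    # so a lighter fragment can chain off a heavier one
    parents: list[tuple[float, tuple[str, ...]]] = [(precursor_mz, ())]
    order = sorted(range(len(fragments)), key=lambda i: -fragments[i])
    for i in order:
        frag = fragments[i]
        hits = []
        for parent_mz, path in parents:
            if frag >= parent_mz or len(path) >= max_depth:
                continue
            diff = parent_mz - frag
            for name, mass in table.items():
                if abs(diff - mass) <= tolerance_da:
                    hits.append(
                        FragmentAnnotation(
                            fragment_mz=frag,
                            parent_mz=parent_mz,
                            loss=name,
                            error_da=float(diff - mass),
                            path=path + (name,),
                        )
                    )
        if hits:
            annotations.extend(hits)
            for h in hits:
                parents.append((frag, h.path))
        else:
            unannotated.append(frag)
    return annotations, unannotated
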