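"""Xanthophyll fatty-acid ester masses and neutral-loss fragment annotation.

Esterified xanthophylls condense a hydroxylated carotenoid backbone
(e.g. zeaxanthin, C40H56O2) with a fatty acid (e.g. myristic acid,
C14:0 = C14H28O2), losing one water.  In negative-mode ESI the intact
ester appears as the deprotonated molecular ion [M−H]⁻, and fragments
arise from neutral losses of acyl-chain pieces plus a characteristic
polyene-backbone fragment near m/z 377.

Masses are computed on two scales: nominal (integer atomic masses, the
scale on which published ester tables are printed) and monoisotopic
(standard isotope masses).  Fragment annotation matches each observed
neutral loss to the nearest library formula within a mass tolerance and
reports the residual in Da rather than silently accepting a label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .exceptions import ChemistryError, ValidationError

__all__ = [
    "MolecularFormula",
    "EsterCandidate",
    "FragmentAnnotation",
    "formula_mass",
    "build_ester",
    "annotate_fragments",
    "ZEAXANTHIN",
    "MYRISTIC_ACID",
    "WATER",
    "DEFAULT_LOSS_LIBRARY",
    "POLYENE_FRAGMENT_MZ",
]

#: Integer (nominal) atomic masses.
NOMINAL_MASS = {"C": 12, "H": 1, "O": 16, "N": 14, "S": 32}

#: Monoisotopic masses of the principal isotopes (Da).
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.99491461956,
    "N": 14.0030740048,
    "S": 31.97207100,
}

#: Characteristic polyene-backbone fragment of carotenoids (m/z).
POLYENE_FRAGMENT_MZ = 377.0

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Immutable element-count composition supporting + and −."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValidationError("formula must contain at least one atom")
        for el, n in self.counts:
            if n < 0 or n != int(n):
                raise ValidationError(f"element {el}: count must be a non-negative integer")
        if sum(n for _, n in self.counts) == 0:
            raise ValidationError("formula must contain at least one atom")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "MolecularFormula":
        items = tuple(sorted((el, int(n)) for el, n in counts.items() if n > 0))
        return cls(counts=items)

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a Hill-style formula string such as ``"C40H56O2"``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValidationError(f"cannot parse formula {text!r} at position {pos}")
            pos = m.end()
            el = m.group(1)
            counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
        if pos != len(text) or not counts:
            raise ValidationError(f"cannot parse formula {text!r}")
        return cls.from_counts(counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def count(self, element: str) -> int:
        return self.as_dict().get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        a = self.as_dict()
        for el, n in other.counts:
            a[el] = a.get(el, 0) + n
        return MolecularFormula.from_counts(a)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        a = self.as_dict()
        for el, n in other.counts:
            a[el] = a.get(el, 0) - n
            if a[el] < 0:
                raise ChemistryError(
                    f"cannot remove {n} {el} atoms: only {a[el] + n} present"
                )
        return MolecularFormula.from_counts(a)

    def __str__(self) -> str:
        d = self.as_dict()
        # Hill order: C, H, then alphabetical
        keys = [k for k in ("C", "H") if k in d] + sorted(
            k for k in d if k not in ("C", "H")
        )
        return "".join(f"{k}{d[k] if d[k] != 1 else ''}" for k in keys)


WATER = MolecularFormula.parse("H2O")
ZEAXANTHIN = MolecularFormula.parse("C40H56O2")
MYRISTIC_ACID = MolecularFormula.parse("C14H28O2")

#: Neutral losses typical of xanthophyll-ester negative-mode spectra:
#: short and long acyl-chain alkyl cleavages plus water.
DEFAULT_LOSS_LIBRARY = (
    MolecularFormula.parse("C4H8"),
    MolecularFormula.parse("C12H24"),
    WATER,
)


def formula_mass(f: MolecularFormula, scale: str = "nominal") -> float:
    """Mass of a formula on the nominal or monoisotopic scale."""
    if scale == "nominal":
        table: Mapping[str, float] = NOMINAL_MASS
    elif scale == "monoisotopic":
        table = MONOISOTOPIC_MASS
    else:
        raise ValidationError(f"unknown mass scale {scale!r}")
    total = 0.0
    for el, n in f.counts:
        if el not in table:
            raise ValidationError(
                f"element {el!r} not in the embedded mass table "
                f"({sorted(table)}); refusing to guess"
            )
        total += table[el] * n
    return total


@dataclass(frozen=True)
class EsterCandidate:
    """A xanthophyll + fatty-acid monoester composition with its masses."""

    backbone_name: str
    backbone: MolecularFormula
    acyl_name: str
    acyl: MolecularFormula
    ester: MolecularFormula
    nominal_mass: int
    monoisotopic_mass: float
    deprotonated_mz: float  # [M−H]⁻ on the nominal scale
    deprotonated_mz_monoisotopic: float


def build_ester(
    backbone: MolecularFormula,
    acyl: MolecularFormula,
    backbone_name: str = "",
    acyl_name: str = "",
) -> EsterCandidate:
    """Condense a hydroxylated backbone with a fatty acid (− H2O).

    The backbone must carry at least one oxygen (the esterifiable
    hydroxyl) and the acyl partner must be a carboxylic acid (>= 2 O).
    """
    if backbone.count("O") < 1:
        raise ChemistryError("backbone has no oxygen: no hydroxyl to esterify")
    if acyl.count("O") < 2:
        raise ChemistryError("acyl partner is not a carboxylic acid (needs >= 2 O)")
    ester = backbone + acyl - WATER
    nominal = formula_mass(ester, "nominal")
    mono = formula_mass(ester, "monoisotopic")
    return EsterCandidate(
        backbone_name=backbone_name,
        backbone=backbone,
        acyl_name=acyl_name,
        acyl=acyl,
        ester=ester,
        nominal_mass=int(round(nominal)),
        monoisotopic_mass=mono,
        deprotonated_mz=nominal - NOMINAL_MASS["H"],
        deprotonated_mz_monoisotopic=mono - MONOISOTOPIC_MASS["H"],
    )


@dataclass(frozen=True)
class FragmentAnnotation:
    fragment_mz: float
    neutral_loss_mz: float
    assigned_formula: MolecularFormula | None
    label: str  # formula string, "polyene backbone fragment", or "unassigned"
    error_da: float | None  # loss − formula mass; None when unassigned
    # nearest library candidate regardless of tolerance, so a printed label
    # that is off by a couple of Da can be reported with its discrepancy
    nearest_formula: MolecularFormula | None = None
    nearest_error_da: float | None = None


def annotate_fragments(
    parent_mz: float,
    fragments: Sequence[float],
    loss_library: Sequence[MolecularFormula] = DEFAULT_LOSS_LIBRARY,
    tolerance_da: float = 1.0,
    scale: str = "nominal",
    flag_polyene: bool = True,
) -> list[FragmentAnnotation]:
    """Annotate negative-mode fragments as neutral losses from a parent ion.

    Each fragment's neutral loss (parent − fragment) is matched to the
    nearest library formula; a match further than ``tolerance_da`` is
    reported as unassigned.  The ``error_da`` of a match is the signed
    discrepancy between the observed loss and the formula mass — printed
    ester tables sometimes carry formula labels that are off by a couple
    of Da, and the discrepancy is surfaced rather than hidden.  When
    ``flag_polyene`` is set, fragments within tolerance of m/z 377 are
    labeled as the characteristic carotenoid polyene-backbone fragment.
    """
    if not tolerance_da > 0:
        raise ValidationError(f"tolerance must be positive, got {tolerance_da}")
    out = []
    for mz in fragments:
        if mz >= parent_mz:
            raise ValidationError(
                f"fragment m/z {mz} is not below the parent {parent_mz}"
            )
        loss = parent_mz - mz
        if flag_polyene and abs(mz - POLYENE_FRAGMENT_MZ) <= tolerance_da:
            out.append(
                FragmentAnnotation(mz, loss, None, "polyene backbone fragment", None)
            )
            continue
        best: MolecularFormula | None = None
        best_err = float("inf")
        for f in loss_library:
            err = loss - formula_mass(f, scale)
            if abs(err) < abs(best_err):
                best, best_err = f, err
        if best is not None and abs(best_err) <= tolerance_da:
            out.append(
                FragmentAnnotation(mz, loss, best, str(best), best_err, best, best_err)
            )
        elif best is not None:
            out.append(
                FragmentAnnotation(mz, loss, None, "unassigned", None, best, best_err)
            )
        else:
            out.append(FragmentAnnotation(mz, loss, None, "unassigned", None))
    return out
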