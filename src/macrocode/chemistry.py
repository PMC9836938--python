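"""Elemental-formula arithmetic, monomer registry and mass computation.

Every mass in the package flows through this module. Three mass modes are
supported and never mixed silently:

``monoisotopic``
    exact mass of the most abundant isotope of each element,
``average``
    abundance-weighted standard atomic weight,
``nominal``
    integer mass number of the most abundant isotope (the scale on which
    low-resolution ESI quadrupole spectra are read out).

Monomers are the polymerizable units of the translation machinery: the 20
canonical amino acids, non-canonical amino acids (ncAAs) and alpha hydroxy
acids. A hydroxy acid carries an alpha-hydroxyl instead of an alpha-amine,
so its incorporation places an ester rather than an amide bond in the
backbone (``backbone_link``). Condensation loses one water per bond
regardless of link type, so residue formula = free formula − H2O for amide
and ester monomers alike.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "MassMode",
    "IonType",
    "BackboneLink",
    "SideChainClass",
    "ElementalFormula",
    "MassValue",
    "Monomer",
    "MonomerRegistry",
    "ModificationDelta",
    "BOC_LOSS",
    "AZIDE_REDUCTION",
    "MODIFICATIONS",
    "parse_formula",
    "formula_mass",
    "ion_mz",
    "residue_mass",
    "apply_modification",
    "carbamate",
    "hydroxy_from_amino",
    "load_registry",
    "WATER",
    "PROTON_MASS",
]


class MassMode(str, Enum):
    MONOISOTOPIC = "monoisotopic"
    AVERAGE = "average"
    NOMINAL = "nominal"


class IonType(str, Enum):
    M_PLUS_H = "M+H"
    M_MINUS_H = "M-H"


class BackboneLink(str, Enum):
    AMIDE = "amide"
    ESTER = "ester"


class SideChainClass(str, Enum):
    ALIPHATIC = "aliphatic"
    AROMATIC = "aromatic"
    CANONICAL = "canonical"


# IUPAC 2021 values. monoisotopic: mass of the most abundant isotope;
# average: conventional standard atomic weight; nominal: mass number of the
# most abundant isotope. Embedded so results are bit-reproducible offline.
ATOMIC_MASS: dict[MassMode, dict[str, float]] = {
    MassMode.MONOISOTOPIC: {
        "H": 1.0078250319,
        "C": 12.0,
        "N": 14.0030740052,
        "O": 15.9949146221,
        "S": 31.97207069,
        "P": 30.97376151,
        "I": 126.904473,
    },
    MassMode.AVERAGE: {
        "H": 1.008,
        "C": 12.011,
        "N": 14.007,
        "O": 15.999,
        "S": 32.06,
        "P": 30.973762,
        "I": 126.90447,
    },
    MassMode.NOMINAL: {
        "H": 1,
        "C": 12,
        "N": 14,
        "O": 16,
        "S": 32,
        "P": 31,
        "I": 127,
    },
}

KNOWN_ELEMENTS = frozenset(ATOMIC_MASS[MassMode.MONOISOTOPIC])

#: proton mass used for m/z conversion; nominal spectra count it as 1 Da
PROTON_MASS: dict[MassMode, float] = {
    MassMode.MONOISOTOPIC: 1.00727646,
    MassMode.AVERAGE: 1.00727646,
    MassMode.NOMINAL: 1,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula text or chemically impossible element counts."""


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element → count map with element-wise arithmetic.

    Counts are non-negative integers; subtraction that would drive any
    count negative raises :class:`FormulaError` instead of silently
    clamping (a negative count means the requested chemistry is
    impossible on this species).
    """

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for element, count in self.element_counts.items():
            if element not in KNOWN_ELEMENTS:
                raise FormulaError(f"unknown element symbol: {element!r}")
            count = int(count)
            if count < 0:
                raise FormulaError(f"negative count for {element}: {count}")
            if count:
                clean[element] = count
        object.__setattr__(self, "element_counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.element_counts)
        for element, count in other.element_counts.items():
            counts[element] = counts.get(element, 0) + count
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.element_counts)
        for element, count in other.element_counts.items():
            remaining = counts.get(element, 0) - count
            if remaining < 0:
                raise FormulaError(
                    f"subtraction drives {element} count negative "
                    f"({counts.get(element, 0)} - {count})"
                )
            counts[element] = remaining
        return ElementalFormula(counts)

    def __mul__(self, n: int) -> "ElementalFormula":
        if n < 0:
            raise FormulaError("multiplier must be non-negative")
        return ElementalFormula({e: c * n for e, c in self.element_counts.items()})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.element_counts)

    def hill_format(self) -> str:
        """Format in Hill order (C, H, then alphabetical); '' for empty."""
        parts: list[str] = []
        for element in ("C", "H"):
            count = self[element]
            if count:
                parts.append(element + (str(count) if count > 1 else ""))
        for element in sorted(self.element_counts):
            if element in ("C", "H"):
                continue
            count = self[element]
            parts.append(element + (str(count) if count > 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill_format()


def parse_formula(text: str) -> ElementalFormula:
    """Parse a molecular formula string such as ``"C6H13NO3"``.

    An omitted count means 1. Raises :class:`FormulaError` on unknown
    element symbols or text that is not fully consumed by the
    element-count grammar.
    """
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"malformed formula near {text[pos:]!r}")
        element, digits = match.groups()
        if element not in KNOWN_ELEMENTS:
            raise FormulaError(f"unknown element symbol: {element!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula near {text[pos:]!r}")
    return ElementalFormula(counts)


WATER = parse_formula("H2O")


@dataclass(frozen=True)
class MassValue:
    """A mass in daltons tagged with its mode.

    Arithmetic between :class:`MassValue` objects of different modes is
    forbidden: mixing monoisotopic and average values is the classic MS
    bookkeeping bug, and it must fail loudly.
    """

    value: float
    mode: MassMode

    def __post_init__(self) -> None:
        if self.mode == MassMode.NOMINAL and self.value != int(self.value):
            raise ValueError(f"nominal mass must be an integer, got {self.value}")

    def _check(self, other: "MassValue") -> None:
        if not isinstance(other, MassValue):
            raise TypeError("MassValue arithmetic requires MassValue operands")
        if other.mode != self.mode:
            raise ValueError(
                f"mixed-mode mass arithmetic forbidden: {self.mode.value} vs {other.mode.value}"
            )

    def __add__(self, other: "MassValue") -> "MassValue":
        self._check(other)
        return MassValue(self.value + other.value, self.mode)

    def __sub__(self, other: "MassValue") -> "MassValue":
        self._check(other)
        return MassValue(self.value - other.value, self.mode)


def formula_mass(f: ElementalFormula, mode: MassMode = MassMode.MONOISOTOPIC) -> MassValue:
    """Neutral mass of a formula: sum of count × atomic mass for *mode*."""
    mode = MassMode(mode)
    table = ATOMIC_MASS[mode]
    return MassValue(sum(count * table[e] for e, count in f.element_counts.items()), mode)


def ion_mz(neutral: MassValue, ion: IonType, charge: int = 1) -> float:
    """m/z of ``[M + zH]z+`` or ``[M − zH]z−`` from a neutral mass.

    Uses the proton mass consistent with the neutral's mode (1 Da on the
    nominal scale). ``charge`` must be a positive integer.
    """
    if charge < 1:
        raise ValueError(f"invalid charge state: {charge}")
    ion = IonType(ion)
    proton = PROTON_MASS[neutral.mode]
    sign = 1 if ion == IonType.M_PLUS_H else -1
    return (neutral.value + sign * charge * proton) / charge


@dataclass(frozen=True)
class Monomer:
    """A polymerizable unit: canonical amino acid, ncAA, or hydroxy acid.

    ``formula_free`` is the formula of the free monomer (with its own
    water); the residue formula is ``formula_free − H2O``. Hydroxy acids
    must declare ``backbone_link = ester``.
    """

    id: str
    name: str
    formula_free: ElementalFormula
    backbone_link: BackboneLink
    side_chain_class: SideChainClass

    @property
    def residue_formula(self) -> ElementalFormula:
        return self.formula_free - WATER


def residue_mass(m: Monomer, mode: MassMode = MassMode.MONOISOTOPIC) -> MassValue:
    """Residue (condensed) mass of a monomer: free mass minus one water."""
    return formula_mass(m.residue_formula, mode)


class MonomerRegistry:
    """Lookup table of monomers by id, with name-based aliasing."""

    def __init__(self, monomers: Iterable[Monomer]):
        self._by_id: dict[str, Monomer] = {}
        self._by_name: dict[str, Monomer] = {}
        for m in monomers:
            if m.id in self._by_id:
                raise ValueError(f"duplicate monomer id {m.id!r}")
            self._by_id[m.id] = m
            self._by_name.setdefault(m.name, m)

    def __contains__(self, key: str) -> bool:
        return key in self._by_id or key in self._by_name

    def __iter__(self):
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def get(self, key: str) -> Monomer:
        try:
            return self._by_id.get(key) or self._by_name[key]
        except KeyError:
            raise KeyError(f"monomer {key!r} not in registry") from None

    def ids(self) -> list[str]:
        return list(self._by_id)


def load_registry(path: str | Path | None = None) -> MonomerRegistry:
    """Load a monomer registry TSV (id, name, formula, backbone_link,
    side_chain_class; UTF-8; ``#`` comments). ``path=None`` loads the
    registry shipped with the package (canonical amino acids plus the 16
    non-canonical monomers)."""
    if path is None:
        source = resources.files("macrocode.data").joinpath("monomers.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    monomers: list[Monomer] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(f"registry line {lineno}: expected 5 tab-separated fields")
        mid, name, formula, link, side = fields
        monomer = Monomer(
            id=mid,
            name=name,
            formula_free=parse_formula(formula),
            backbone_link=BackboneLink(link),
            side_chain_class=SideChainClass(side),
        )
        if monomer.backbone_link == BackboneLink.ESTER and monomer.formula_free["O"] < 3:
            raise ValueError(f"registry line {lineno}: ester monomer lacks alpha-hydroxyl oxygens")
        monomers.append(monomer)
    return MonomerRegistry(monomers)


@dataclass(frozen=True)
class ModificationDelta:
    """A signed element-count change applied to a species formula."""

    name: str
    gain: ElementalFormula
    loss: ElementalFormula


#: loss of a tert-butoxycarbonyl protecting group (−C4H8 −CO2 as the
#: carbamic-acid collapse; net −C5H8O2, the −100 Da satellite)
BOC_LOSS = ModificationDelta("boc_loss", ElementalFormula({}), parse_formula("C5H8O2"))
#: reduction of an aryl azide to the amine (−N2 +H2)
AZIDE_REDUCTION = ModificationDelta("azide_reduction", parse_formula("H2"), parse_formula("N2"))

MODIFICATIONS: dict[str, ModificationDelta] = {
    m.name: m for m in (BOC_LOSS, AZIDE_REDUCTION)
}


def apply_modification(f: ElementalFormula, mod: ModificationDelta) -> ElementalFormula:
    """Apply a signed modification; errors if any count would go negative."""
    try:
        return (f + mod.gain) - mod.loss
    except FormulaError as exc:
        raise FormulaError(f"modification {mod.name!r} impossible on {f.hill_format()}: {exc}") from exc


def carbamate(amine: ElementalFormula, alcohol: ElementalFormula) -> ElementalFormula:
    """Formula of the carbamate R-NH-C(=O)-O-R' formed from a primary
    amine and the chloroformate of an alcohol.

    Net formula arithmetic: amine + alcohol + CO2 − H2O. This is the
    route by which the lysine-scaffold hydroxy acids (Alloc/Alkyn/But/
    Pen/Nor carbamates of (S)-6-amino-2-hydroxyhexanoic acid) are made.
    """
    return amine + alcohol + parse_formula("CO2") - WATER


def hydroxy_from_amino(amino_acid: ElementalFormula) -> ElementalFormula:
    """Formula of the alpha hydroxy acid analogue of an amino acid.

    Diazotization/hydrolysis replaces the alpha-NH2 with OH: net
    −N −H +O. Errors if the input has no nitrogen to lose.
    """
    return amino_acid + parse_formula("O") - parse_formula("NH")
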