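"""Ring-opening enumeration and a/b/y fragment theory for cyclic species.

A cyclic (depsi)peptide of *n* monomers can ring-open at any of its *n*
backbone bonds (amide or ester alike), so collision-induced dissociation
must be interpreted against *n* rotationally related linear sequences.
For each linearization the standard singly protonated series are

* ``b_i`` = Σ residues(1..i) + proton
* ``a_i`` = b_i − CO
* ``y_i`` = Σ residues(n−i+1..n) + H2O + proton

Residue masses already encode the O-for-NH swap of ester-linked
positions, so depsipeptide fragments use the same arithmetic; fragments
across an opened ester bond carry the standard b/y labels, with the
linearization flagging which opened bond was an ester.

Observed peak lists are annotated by tolerance matching against the
union of ions over all linearizations; one matched peak may legitimately
correspond to several theoretical ions (rotations share sub-sums), and
all candidates within tolerance are reported rather than silently
choosing one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import (
    MassMode,
    PROTON_MASS,
    WATER,
    formula_mass,
    ion_mz,
    parse_formula,
)
from .design import CyclicSpecies

__all__ = [
    "Linearization",
    "FragmentIon",
    "PeakList",
    "linearize",
    "theoretical_ions",
    "annotate",
]

_CO = parse_formula("CO")


@dataclass(frozen=True)
class Linearization:
    """One ring-opened linear reading of a cyclic species."""

    opened_bond: int
    monomers: tuple[str, ...]
    opened_ester: bool
    species: CyclicSpecies = field(repr=False, compare=False)


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'a', 'b' or 'y'
    index: int  # 1..n
    mz: float
    source: Linearization = field(repr=False, compare=False)

    @property
    def label(self) -> str:
        return f"{self.series}{self.index}"


@dataclass(frozen=True)
class PeakList:
    """Observed (m/z, intensity) pairs with a match tolerance in Da."""

    peaks: tuple[tuple[float, float], ...]
    precursor_mz: float
    tolerance: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple((float(m), float(i)) for m, i in self.peaks))
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if any(m <= 0 for m, _ in self.peaks):
            raise ValueError("peak m/z must be positive")


def linearize(s: CyclicSpecies) -> list[Linearization]:
    """All *n* ring-opened linear sequences of an *n*-ring.

    Opening bond *i* yields the rotation starting at monomer *i+1*
    (the bond's acceptor). Distinct sequences number ≤ n, with equality
    iff the ring has no rotational symmetry.
    """
    n = len(s)
    esters = s.ester_positions
    return [
        Linearization(
            opened_bond=i,
            monomers=tuple(s.monomers[(i + 1 + k) % n] for k in range(n)),
            opened_ester=i in esters,
            species=s,
        )
        for i in range(n)
    ]


def theoretical_ions(
    lin: Linearization,
    series: frozenset[str] | set[str] = frozenset({"a", "b", "y"}),
    mode: MassMode = MassMode.MONOISOTOPIC,
) -> list[FragmentIon]:
    """Singly protonated a/b/y ions of a linearization, indices 1..n."""
    mode = MassMode(mode)
    unknown = set(series) - {"a", "b", "y"}
    if unknown:
        raise ValueError(f"unknown ion series {sorted(unknown)}")
    registry = lin.species.registry
    residues = [
        formula_mass(registry.get(m).residue_formula, mode).value for m in lin.monomers
    ]
    n = len(residues)
    proton = PROTON_MASS[mode]
    water = formula_mass(WATER, mode).value
    co = formula_mass(_CO, mode).value
    prefix = np.cumsum(residues)
    suffix = np.cumsum(residues[::-1])
    ions: list[FragmentIon] = []
    for i in range(1, n + 1):
        b = prefix[i - 1] + proton
        if "b" in series:
            ions.append(FragmentIon("b", i, b, lin))
        if "a" in series:
            ions.append(FragmentIon("a", i, b - co, lin))
        if "y" in series:
            ions.append(FragmentIon("y", i, suffix[i - 1] + water + proton, lin))
    return ions


def annotate(
    p: PeakList,
    s: CyclicSpecies,
    series: frozenset[str] | set[str] = frozenset({"a", "b", "y"}),
    mode: MassMode = MassMode.MONOISOTOPIC,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Match observed peaks to theoretical ions of every linearization.

    Returns ``(table, coverage)``. The table has one row per observed
    peak with all ion assignments within tolerance (``matches`` holds
    ``(opened_bond, label)`` tuples; multiple entries mark an ambiguous
    assignment), a precursor flag, and the mass difference from the
    cyclic precursor's [M+H]+ (low-resolution spectra are often read as
    losses relative to the precursor). ``coverage`` counts, per
    linearization, how many of its distinct theoretical ions were
    observed.
    """
    linearizations = linearize(s)
    all_ions: list[FragmentIon] = []
    for lin in linearizations:
        all_ions.extend(theoretical_ions(lin, series=series, mode=mode))
    ion_mzs = np.array([ion.mz for ion in all_ions])
    precursor = ion_mz(s.neutral_mass(mode), "M+H", 1)

    rows = []
    matched_ions: dict[int, set[str]] = {lin.opened_bond: set() for lin in linearizations}
    for mz, intensity in p.peaks:
        within = np.flatnonzero(np.abs(ion_mzs - mz) <= p.tolerance)
        matches = [
            (all_ions[k].source.opened_bond, all_ions[k].label) for k in within
        ]
        for k in within:
            matched_ions[all_ions[k].source.opened_bond].add(all_ions[k].label)
        rows.append(
            {
                "mz": mz,
                "intensity": intensity,
                "matches": sorted(set(matches)),
                "n_matches": len(set(matches)),
                "ambiguous": len(set(matches)) > 1,
                "is_precursor": abs(mz - precursor) <= p.tolerance,
                "delta_from_precursor": mz - precursor,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "mz",
            "intensity",
            "matches",
            "n_matches",
            "ambiguous",
            "is_precursor",
            "delta_from_precursor",
        ],
    )
    coverage = {bond: len(labels) for bond, labels in matched_ions.items()}
    return table, coverage
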