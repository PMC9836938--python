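"""Macrocycle template instantiation and depsipeptide mass accounting.

A macrocycle template is an ordered list of slots: canonical residue
codes plus exactly one ``A`` and one ``B`` placeholder. Instantiating a
template under a reassignment scheme substitutes the scheme's monomers
into the placeholders and yields a :class:`CyclicSpecies` — a
head-to-tail ring of monomers with no termini.

Mass accounting is pure condensation arithmetic:

* linear species: Σ residue masses + H2O
* cyclic species: Σ residue masses (one extra water lost on ring closure)

Ester bonds enter through hydroxy-acid monomers. Ring bond *i* joins the
carbonyl of monomer *i* to the backbone of monomer *i+1 (mod n)*; the
bond is an ester iff the *acceptor* monomer is a hydroxy acid, whose
alpha-OH esterifies the preceding carbonyl. Hydrolysis therefore splits
N-terminal-side | hydroxy-acid, leaving the upstream fragment as a free
acid and the downstream fragment with a free alpha-hydroxyl.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chemistry import (
    BackboneLink,
    MassMode,
    MassValue,
    MonomerRegistry,
    WATER,
    formula_mass,
)
from .recoding import ReassignmentScheme

__all__ = [
    "MacrocycleTemplate",
    "CyclicSpecies",
    "HydrolysisProduct",
    "ProteinVariant",
    "instantiate",
    "species_mass",
    "hydrolysis_products",
    "protein_variant_mass",
]


@dataclass(frozen=True)
class MacrocycleTemplate:
    """Ordered ring slots with exactly one A and one B placeholder.

    ``"A"`` and ``"B"`` are reserved for the placeholders, so canonical
    alanine in a template must be written by its registry name
    (``"Ala"``); slots resolve against the registry by id or name.
    """

    name: str
    slots: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "slots", tuple(self.slots))
        if len(self.slots) < 3:
            raise ValueError(f"{self.name}: macrocycle needs at least 3 slots")
        for placeholder in ("A", "B"):
            if self.slots.count(placeholder) != 1:
                raise ValueError(
                    f"{self.name}: template must contain exactly one {placeholder!r} placeholder"
                )


@dataclass(frozen=True)
class CyclicSpecies:
    """An ordered ring of monomer ids resolved against a registry."""

    name: str
    monomers: tuple[str, ...]
    registry: MonomerRegistry = field(repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "monomers", tuple(self.monomers))
        if not self.monomers:
            raise ValueError(f"{self.name}: empty ring")
        for mid in self.monomers:
            if mid not in self.registry:
                raise KeyError(f"{self.name}: monomer {mid!r} not in registry")

    def __len__(self) -> int:
        return len(self.monomers)

    @property
    def ester_positions(self) -> frozenset[int]:
        """Ring bond indices whose acceptor monomer is ester-linked.

        Bond i connects monomer i (carbonyl donor) to monomer
        (i+1) mod n (acceptor).
        """
        n = len(self.monomers)
        return frozenset(
            i
            for i in range(n)
            if self.registry.get(self.monomers[(i + 1) % n]).backbone_link
            == BackboneLink.ESTER
        )

    def neutral_mass(self, mode: MassMode = MassMode.MONOISOTOPIC) -> MassValue:
        return species_mass(self.monomers, self.registry, cyclic=True, mode=mode)


def instantiate(
    template: MacrocycleTemplate,
    scheme: ReassignmentScheme,
    registry: MonomerRegistry,
) -> CyclicSpecies:
    """Resolve A/B placeholders with the scheme's monomers."""
    scheme.validate_registry(registry)
    mapping = {"A": scheme.monomer_A, "B": scheme.monomer_B}
    monomers = tuple(mapping.get(slot, slot) for slot in template.slots)
    return CyclicSpecies(f"{template.name}_{scheme.scheme_id}", monomers, registry)


def species_mass(
    monomers: tuple[str, ...] | list[str],
    registry: MonomerRegistry,
    cyclic: bool = False,
    mode: MassMode = MassMode.MONOISOTOPIC,
) -> MassValue:
    """Neutral mass of a linear chain or ring of monomers."""
    mode = MassMode(mode)
    total = MassValue(0.0 if mode != MassMode.NOMINAL else 0, mode)
    for mid in monomers:
        total = total + formula_mass(registry.get(mid).residue_formula, mode)
    if not cyclic:
        total = total + formula_mass(WATER, mode)
    return total


@dataclass(frozen=True)
class HydrolysisProduct:
    """A linear product of ester-bond hydrolysis of a cyclic species.

    ``opened_bonds`` lists the cleaved ring bond indices; single-cleavage
    products carry the whole ring, double-cleavage products carry the arc
    between the two opened bonds.
    """

    monomers: tuple[str, ...]
    opened_bonds: tuple[int, ...]
    registry: MonomerRegistry = field(repr=False, compare=False)

    def neutral_mass(self, mode: MassMode = MassMode.MONOISOTOPIC) -> MassValue:
        return species_mass(self.monomers, self.registry, cyclic=False, mode=mode)


def hydrolysis_products(s: CyclicSpecies) -> list[HydrolysisProduct]:
    """Enumerate ester-hydrolysis products of a cyclic (depsi)peptide.

    One ring-opened linear product per ester bond (mass = cyclic + H2O,
    the asterisk species of post-cyclization hydrolysis). When the ring
    carries two or more esters, each unordered pair of ester bonds also
    yields a complementary fragment pair whose masses sum to
    cyclic + 2 H2O. Rings without esters return an empty list.
    """
    esters = sorted(s.ester_positions)
    n = len(s)
    products: list[HydrolysisProduct] = []
    for i in esters:
        # ring opens after bond i: linear sequence starts at the acceptor
        seq = tuple(s.monomers[(i + 1 + k) % n] for k in range(n))
        products.append(HydrolysisProduct(seq, (i,), s.registry))
    for a_idx in range(len(esters)):
        for b_idx in range(a_idx + 1, len(esters)):
            i, j = esters[a_idx], esters[b_idx]
            arc1 = tuple(s.monomers[(i + 1 + k) % n] for k in range((j - i) % n))
            arc2 = tuple(s.monomers[(j + 1 + k) % n] for k in range((i - j) % n))
            products.append(HydrolysisProduct(arc1, (i, j), s.registry))
            products.append(HydrolysisProduct(arc2, (j, i), s.registry))
    return products


@dataclass(frozen=True)
class ProteinVariant:
    """A carrier protein with one residue substituted by a registry monomer.

    ``position`` is 1-based, matching the construct nomenclature of
    single-site reporters (e.g. a TCG codon at position 3).
    """

    name: str
    sequence: tuple[str, ...]
    position: int
    monomer: str
    registry: MonomerRegistry = field(repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", tuple(self.sequence))
        if not 1 <= self.position <= len(self.sequence):
            raise ValueError(
                f"{self.name}: position {self.position} outside 1..{len(self.sequence)}"
            )
        if self.monomer not in self.registry:
            raise KeyError(f"{self.name}: monomer {self.monomer!r} not in registry")

    @property
    def substituted_sequence(self) -> tuple[str, ...]:
        seq = list(self.sequence)
        seq[self.position - 1] = self.monomer
        return tuple(seq)


def protein_variant_mass(
    v: ProteinVariant,
    hydrolysed_at_ester: bool = False,
    mode: MassMode = MassMode.AVERAGE,
) -> MassValue | tuple[MassValue, MassValue]:
    """Intact mass of a substituted carrier protein, or its two
    ester-cleavage fragments.

    With ``hydrolysed_at_ester`` the substituted monomer must be a
    hydroxy acid: the backbone ester on its N-terminal side is cleaved,
    giving the upstream fragment (residues before the substitution, as a
    free acid) and the downstream fragment (the hydroxy acid with its
    free alpha-hydroxyl plus everything C-terminal). Fragment masses sum
    to intact + H2O.
    """
    seq = v.substituted_sequence
    if not hydrolysed_at_ester:
        return species_mass(seq, v.registry, cyclic=False, mode=mode)
    monomer = v.registry.get(v.monomer)
    if monomer.backbone_link != BackboneLink.ESTER:
        raise ValueError(
            f"{v.name}: hydrolysis requested at an amide position "
            f"({v.monomer} is not a hydroxy acid)"
        )
    if v.position == 1:
        raise ValueError(f"{v.name}: no N-terminal-side backbone bond at position 1")
    n_term = species_mass(seq[: v.position - 1], v.registry, cyclic=False, mode=mode)
    c_term = species_mass(seq[v.position - 1 :], v.registry, cyclic=False, mode=mode)
    return n_term, c_term
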