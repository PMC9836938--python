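"""Codon compression and translation under codon-reassignment schemes.

The host strain context is a synthetic-genome *E. coli* (Syn61Δ3 lineage)
in which every annotated TCG and TCA sense codon has been replaced by a
synonym, the amber stop TAG replaced by ochre TAA, and the decoding tRNAs
plus release factor 1 deleted. Coding sequences destined for such cells
must first be *compressed* with the same synonymous substitutions
(TCG→AGC, TCA→AGT, TAG→TAA); the three liberated codons can then be
reintroduced into synthetic genes and reassigned: TCG programmes
non-canonical monomer A and TAG programmes monomer B, while TCA has no
decoder at all and is a hard error in this context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .chemistry import MonomerRegistry

__all__ = [
    "CodingSequence",
    "RecodingRuleSet",
    "ReassignmentScheme",
    "DEFAULT_RULES",
    "compress",
    "validate_syn61",
    "translate_reassigned",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_STOP_CODONS = frozenset(_STANDARD.stop_codons)


def _standard_aa(codon: str) -> str | None:
    """One-letter amino acid for a codon under the standard code; None for stop."""
    if codon in _STOP_CODONS:
        return None
    return _STANDARD.forward_table[codon]


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame DNA coding sequence over the uppercase ACGT alphabet."""

    id: str
    nucleotides: str

    def __post_init__(self) -> None:
        seq = self.nucleotides.upper()
        object.__setattr__(self, "nucleotides", seq)
        if len(seq) % 3 != 0:
            raise ValueError(
                f"{self.id}: length {len(seq)} is not divisible by 3 (frame error)"
            )
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"{self.id}: non-ACGT characters {sorted(bad)}")

    def codons(self) -> list[str]:
        seq = self.nucleotides
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]


#: the Syn61 recoding rules: serine TCG/TCA to their synonyms, amber to ochre
DEFAULT_RULES: dict[str, str] = {"TCG": "AGC", "TCA": "AGT", "TAG": "TAA"}


@dataclass(frozen=True)
class RecodingRuleSet:
    """Codon→codon substitutions, each synonymous (or stop→stop)."""

    substitutions: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_RULES))

    def __post_init__(self) -> None:
        for src, dst in self.substitutions.items():
            if dst in self.substitutions:
                raise ValueError(f"substitution target {dst} is itself a source codon")
            if _standard_aa(src) != _standard_aa(dst):
                raise ValueError(
                    f"substitution {src}->{dst} is not synonymous under the standard code"
                )


def compress(cds: CodingSequence, rules: RecodingRuleSet | None = None) -> CodingSequence:
    """Apply the recoding rules frame-aware, at codon boundaries only.

    The output contains no in-frame occurrence of any source codon, and
    its standard-code translation is unchanged. Idempotent.
    """
    rules = rules or RecodingRuleSet()
    codons = [rules.substitutions.get(c, c) for c in cds.codons()]
    return CodingSequence(cds.id, "".join(codons))


def validate_syn61(
    cds: CodingSequence, rules: RecodingRuleSet | None = None
) -> list[tuple[int, str]]:
    """List every in-frame target codon as (0-based codon index, codon).

    An empty list means the sequence is compression-compliant. Codon
    indices are 0-based throughout the reporting layer.
    """
    rules = rules or RecodingRuleSet()
    targets = rules.substitutions.keys()
    return [(i, c) for i, c in enumerate(cds.codons()) if c in targets]


@dataclass(frozen=True)
class ReassignmentScheme:
    """A declared mapping of the liberated codons to monomers.

    TCG decodes ``monomer_A`` and TAG decodes ``monomer_B`` via the named
    synthetase/tRNA pairs; TCA has no assignment (its decoder was deleted).
    """

    scheme_id: str
    monomer_A: str
    monomer_B: str
    pair_A: str = ""
    pair_B: str = ""

    def __post_init__(self) -> None:
        if self.monomer_A == self.monomer_B:
            raise ValueError(f"{self.scheme_id}: monomer A and B must differ")

    def validate_registry(self, registry: MonomerRegistry) -> None:
        for mid in (self.monomer_A, self.monomer_B):
            if mid not in registry:
                raise KeyError(f"{self.scheme_id}: monomer {mid!r} not in registry")


class UndecodableCodonError(ValueError):
    """An in-frame codon with no decoder in the Syn61Δ3 context."""


def translate_reassigned(
    cds: CodingSequence,
    scheme: ReassignmentScheme,
    registry: MonomerRegistry | None = None,
) -> list[str]:
    """Translate a CDS with TCG→monomer A and TAG→monomer B.

    Returns monomer ids in order (one-letter codes for canonical
    residues). A terminal TAA/TGA is treated as stop and not emitted; an
    internal one is a premature-stop error, and any in-frame TCA is an
    :class:`UndecodableCodonError` — Syn61Δ3 deleted its decoding tRNA,
    so silently accepting it would fabricate biology.
    """
    if registry is not None:
        scheme.validate_registry(registry)
    codons = cds.codons()
    out: list[str] = []
    for i, codon in enumerate(codons):
        if codon == "TCA":
            raise UndecodableCodonError(
                f"{cds.id}: unassigned TCA at codon {i} (no decoding tRNA)"
            )
        if codon == "TCG":
            out.append(scheme.monomer_A)
        elif codon == "TAG":
            out.append(scheme.monomer_B)
        elif codon in ("TAA", "TGA"):
            if i != len(codons) - 1:
                raise ValueError(f"{cds.id}: premature stop {codon} at codon {i}")
        else:
            out.append(_standard_aa(codon))
    return out
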