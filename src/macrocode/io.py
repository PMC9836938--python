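"""Format readers/writers and run configuration.

Dialects are deliberately rigid so fixtures are bit-exact: FASTA wrapped
at 60 columns with single-line headers; CSV/TSV UTF-8 with ``#``
comments and no implicit NA; MGF restricted to a minimal
BEGIN IONS/TITLE/PEPMASS dialect. Every writer's output round-trips
through the corresponding reader.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .chemistry import MassMode
from .fragmentation import PeakList
from .orthogonality import ActivityMatrix
from .recoding import CodingSequence, ReassignmentScheme

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_peaklist_tsv",
    "write_peaklist_tsv",
    "read_mgf",
    "write_mgf",
    "read_activity_csv",
    "write_activity_csv",
    "write_violations_tsv",
    "write_pairs_tsv",
    "load_schemes",
    "RunConfig",
]


def read_fasta(path: str | Path) -> list[CodingSequence]:
    return [
        CodingSequence(record.id, str(record.seq)) for record in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(sequences: list[CodingSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(cds.nucleotides), id=cds.id, description="") for cds in sequences
    ]
    with open(path, "w", encoding="utf-8") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(records)


def read_peaklist_tsv(
    path: str | Path, precursor_mz: float, tolerance: float = 0.1
) -> PeakList:
    """Two-column TSV (mz, intensity), '#' comments allowed."""
    peaks = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        peaks.append((float(parts[0]), float(parts[1])))
    return PeakList(tuple(peaks), precursor_mz=precursor_mz, tolerance=tolerance)


def write_peaklist_tsv(p: PeakList, path: str | Path) -> None:
    lines = ["# mz\tintensity"]
    lines += [f"{mz:.6f}\t{intensity:.4f}" for mz, intensity in p.peaks]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_mgf(p: PeakList, path: str | Path, title: str = "spectrum") -> None:
    spectrum = {
        "m/z array": [mz for mz, _ in p.peaks],
        "intensity array": [i for _, i in p.peaks],
        "params": {"title": title, "pepmass": p.precursor_mz},
    }
    _mgf.write([spectrum], str(path), file_mode="w")


def read_mgf(path: str | Path, tolerance: float = 0.1) -> PeakList:
    with _mgf.read(str(path)) as reader:
        spectrum = next(iter(reader))
    return PeakList(
        tuple(zip(spectrum["m/z array"], spectrum["intensity array"])),
        precursor_mz=float(spectrum["params"]["pepmass"][0]),
        tolerance=tolerance,
    )


def read_activity_csv(path: str | Path) -> ActivityMatrix:
    """CSV: first column aaRS label, second column group, remaining
    columns monomer ids. Missing values are an error, never zeros."""
    df = pd.read_csv(path, comment="#", index_col=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a group column plus at least one monomer column")
    if df.columns[0] != "group":
        raise ValueError(f"{path}: second column must be named 'group', got {df.columns[0]!r}")
    groups = df["group"].astype(str)
    values = df.drop(columns="group")
    return ActivityMatrix(values, groups)


def write_activity_csv(m: ActivityMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.insert(0, "group", m.groups)
    df.to_csv(path, index_label="aaRS")


def write_violations_tsv(
    violations: dict[str, list[tuple[int, str]]], path: str | Path
) -> None:
    """Per-sequence compression violations (0-based codon indices)."""
    lines = ["# seq_id\tcodon_index\tcodon"]
    for seq_id, items in violations.items():
        lines += [f"{seq_id}\t{idx}\t{codon}" for idx, codon in items]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_pairs_tsv(pairs, path: str | Path) -> None:
    lines = ["# aaRS1\tmonomer1\taaRS2\tmonomer2"]
    for p in sorted(pairs):
        lines.append(f"{p.left[0]}\t{p.left[1]}\t{p.right[0]}\t{p.right[1]}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_schemes(path: str | Path | None = None) -> dict[str, ReassignmentScheme]:
    """Load reassignment schemes from YAML; ``None`` loads the shipped
    r.s. 1–8 (TCG→monomer A, TAG→monomer B)."""
    if path is None:
        text = resources.files("macrocode.data").joinpath("schemes.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    schemes = {}
    for scheme_id, entry in raw.items():
        unknown = set(entry) - {"monomer_A", "monomer_B", "pair_A", "pair_B"}
        if unknown:
            raise ValueError(f"scheme {scheme_id}: unknown keys {sorted(unknown)}")
        schemes[scheme_id] = ReassignmentScheme(
            scheme_id=scheme_id,
            monomer_A=str(entry["monomer_A"]),
            monomer_B=str(entry["monomer_B"]),
            pair_A=entry.get("pair_A", ""),
            pair_B=entry.get("pair_B", ""),
        )
    return schemes


@dataclass(frozen=True)
class RunConfig:
    """Top-level YAML run configuration; unknown keys are rejected and
    all referenced files must exist at load time."""

    registry: str | None = None
    schemes: str | None = None
    templates: str | None = None
    active_min: float = 10_000.0
    inactive_max: float = 2_500.0
    tolerance: float = 0.1
    mass_mode: str = MassMode.MONOISOTOPIC.value
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        config = cls(**raw)
        MassMode(config.mass_mode)
        for name in ("registry", "schemes", "templates"):
            value = getattr(config, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{path}: {name} file {value!r} does not exist")
        return config
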