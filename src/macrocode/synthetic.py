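"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its spec and seed, and carries its
own ground truth, so compression, translation, fragment annotation and
orthogonal-pair identification are all testable without downloads. The
default activity-matrix spec emulates the screening-campaign geometry:
three mutually orthogonal synthetase classes of sizes (3, 2, 2) crossed
with 16 monomers, active readouts uniform in 15,000–40,000 RFU/OD600
and inactive readouts uniform in 0–1,000, straddling the 10,000 / 2,500
thresholds by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import ion_mz
from .design import CyclicSpecies
from .fragmentation import PeakList, linearize, theoretical_ions
from .orthogonality import ActivityMatrix, OrthogonalPair
from .recoding import CodingSequence

__all__ = [
    "MatrixSpec",
    "CdsSpec",
    "SpectrumSpec",
    "gen_activity_matrix",
    "gen_cds",
    "gen_spectrum",
]

_SENSE_CODONS = [
    a + b + c
    for a, b, c in itertools.product("ACGT", repeat=3)
    if a + b + c not in ("TCG", "TCA", "TAG", "TAA", "TGA")
]


@dataclass(frozen=True)
class MatrixSpec:
    """Geometry and levels of a synthetic screening matrix."""

    group_sizes: tuple[int, ...] = (3, 2, 2)
    n_monomers: int = 16
    n_active_per_aars: int = 2
    active_range: tuple[float, float] = (15_000.0, 40_000.0)
    inactive_range: tuple[float, float] = (0.0, 1_000.0)
    noise_sd: float = 0.0


@dataclass(frozen=True)
class CdsSpec:
    """A random compressed-alphabet CDS with planted target codons."""

    n_codons: int = 100
    n_tcg: int = 0
    n_tca: int = 0
    n_tag: int = 0
    stop: bool = False


@dataclass(frozen=True)
class SpectrumSpec:
    """A synthetic fragment spectrum of a cyclic species."""

    planted_per_linearization: int = 3
    n_decoys: int = 5
    mz_jitter_sd: float = 0.0
    tolerance: float = 0.1
    decoy_range: tuple[float, float] = (50.0, 2000.0)


def _implied_pairs(
    active: np.ndarray, aars: list[str], monomers: list[str], groups: list[str]
) -> set[OrthogonalPair]:
    """Brute-force ground-truth enumeration over a boolean activity map.

    Independent of find_pairs: iterates every ordered quadruple of the
    planted pattern, where inactive is the complement of active.
    """
    truth: set[OrthogonalPair] = set()
    n_rows, n_cols = active.shape
    for r1 in range(n_rows):
        for r2 in range(n_rows):
            if r1 == r2 or groups[r1] == groups[r2]:
                continue
            for c1 in range(n_cols):
                for c2 in range(n_cols):
                    if (
                        active[r1, c1]
                        and not active[r1, c2]
                        and active[r2, c2]
                        and not active[r2, c1]
                    ):
                        truth.add(
                            OrthogonalPair.make(
                                (aars[r1], monomers[c1]), (aars[r2], monomers[c2])
                            )
                        )
    return truth


def gen_activity_matrix(
    spec: MatrixSpec = MatrixSpec(), seed: int = 0
) -> tuple[ActivityMatrix, set[OrthogonalPair]]:
    """Synthetic activity matrix plus its exact ground-truth pair set.

    Each synthetase is planted with ``n_active_per_aars`` cognate
    monomers drawn at random; every other cell is inactive. Ground truth
    is enumerated from the planted boolean pattern by brute force, so at
    zero noise it equals what threshold-based pair finding must recover.
    Gaussian noise (``noise_sd``) is added after planting and clipped at
    zero; large noise may legitimately cross the thresholds.
    """
    rng = np.random.default_rng(seed)
    aars = [
        f"aaRS_g{g + 1}_{k + 1}"
        for g, size in enumerate(spec.group_sizes)
        for k in range(size)
    ]
    groups = [
        f"group{g + 1}" for g, size in enumerate(spec.group_sizes) for _ in range(size)
    ]
    monomers = [str(i + 1) for i in range(spec.n_monomers)]
    n_rows = len(aars)

    active = np.zeros((n_rows, spec.n_monomers), dtype=bool)
    for r in range(n_rows):
        cols = rng.choice(spec.n_monomers, size=spec.n_active_per_aars, replace=False)
        active[r, cols] = True

    values = rng.uniform(*spec.inactive_range, size=active.shape)
    values[active] = rng.uniform(*spec.active_range, size=int(active.sum()))
    if spec.noise_sd > 0:
        values = np.clip(values + rng.normal(0.0, spec.noise_sd, size=values.shape), 0, None)

    matrix = ActivityMatrix(
        pd.DataFrame(values, index=aars, columns=monomers),
        pd.Series(groups, index=aars),
    )
    truth = _implied_pairs(active, aars, monomers, groups)
    return matrix, truth


def gen_cds(spec: CdsSpec = CdsSpec(), seed: int = 0) -> tuple[CodingSequence, dict[str, int]]:
    """Random CDS with exact planted counts of TCG/TCA/TAG codons.

    Background codons are drawn from the 59 sense codons that are
    neither reassignment targets nor stops, so the planted counts are
    the true in-frame counts. With ``stop=True`` a terminal TAA is
    appended (not counted in ``n_codons``).
    """
    n_planted = spec.n_tcg + spec.n_tca + spec.n_tag
    if spec.n_codons < 1 or n_planted > spec.n_codons:
        raise ValueError("planted codons exceed sequence length")
    rng = np.random.default_rng(seed)
    codons = list(rng.choice(_SENSE_CODONS, size=spec.n_codons))
    planted = ["TCG"] * spec.n_tcg + ["TCA"] * spec.n_tca + ["TAG"] * spec.n_tag
    positions = rng.choice(spec.n_codons, size=n_planted, replace=False)
    for pos, codon in zip(positions, planted):
        codons[int(pos)] = codon
    if spec.stop:
        codons.append("TAA")
    cds = CodingSequence(f"synthetic_cds_seed{seed}", "".join(codons))
    return cds, {"TCG": spec.n_tcg, "TCA": spec.n_tca, "TAG": spec.n_tag}


def gen_spectrum(
    s: CyclicSpecies, spec: SpectrumSpec = SpectrumSpec(), seed: int = 0
) -> tuple[PeakList, list[tuple[int, str]]]:
    """Synthetic fragment spectrum of a cyclic species with ground truth.

    Plants ``planted_per_linearization`` distinct theoretical ions per
    ring opening (m/z jittered by a Gaussian truncated to half the match
    tolerance, so every planted peak annotates) and adds decoy peaks
    kept at least 2× tolerance away from every theoretical ion. Raises
    if a decoy cannot be placed within 1,000 attempts (overcrowded m/z
    range). Returns the peak list and the planted (opened_bond, label)
    ground truth.
    """
    rng = np.random.default_rng(seed)
    linearizations = linearize(s)
    all_ions = [ion for lin in linearizations for ion in theoretical_ions(lin)]
    all_mzs = np.array([ion.mz for ion in all_ions])

    peaks: list[tuple[float, float]] = []
    truth: list[tuple[int, str]] = []
    half_tol = spec.tolerance / 2
    for lin in linearizations:
        ions = theoretical_ions(lin)
        if spec.planted_per_linearization > len(ions):
            raise ValueError("more planted ions requested than exist")
        chosen = rng.choice(len(ions), size=spec.planted_per_linearization, replace=False)
        for k in chosen:
            jitter = 0.0
            if spec.mz_jitter_sd > 0:
                jitter = float(
                    np.clip(rng.normal(0.0, spec.mz_jitter_sd), -half_tol, half_tol)
                )
            peaks.append((ions[k].mz + jitter, float(rng.uniform(10.0, 100.0))))
            truth.append((lin.opened_bond, ions[k].label))

    for _ in range(spec.n_decoys):
        for _attempt in range(1000):
            mz = float(rng.uniform(*spec.decoy_range))
            if np.abs(all_mzs - mz).min() > 2 * spec.tolerance:
                peaks.append((mz, float(rng.uniform(1.0, 10.0))))
                break
        else:
            raise RuntimeError("decoy collision after 1000 attempts: m/z range overcrowded")

    precursor = ion_mz(s.neutral_mass(), "M+H", 1)
    return PeakList(tuple(peaks), precursor_mz=precursor, tolerance=spec.tolerance), truth
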