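"""Automated identification of mutually orthogonal synthetase/monomer pairs.

Input is a fluorescence activity matrix: engineered aminoacyl-tRNA
synthetase (aaRS) variants as rows, candidate monomers as columns,
values in RFU/OD600 from a single-reassigned-codon fluorescent-reporter
readout. Rows carry a class label — synthetases within one class share
tRNA/aminoacylation cross-reactivity, so orthogonal pairs may only be
drawn across classes.

(aaRS1, monomer1) and (aaRS2, monomer2) form a mutually orthogonal pair
when aaRS1 is active with monomer 1 and inactive with monomer 2 while
aaRS2 is active with monomer 2 and inactive with monomer 1, activity and
inactivity being strict threshold comparisons. Excluded cells (e.g.
readouts known to report incorporation of a metabolite rather than the
supplied monomer) never contribute to either judgement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ActivityMatrix",
    "Thresholds",
    "OrthogonalPair",
    "DEFAULT_EXCLUSIONS",
    "apply_exclusions",
    "find_pairs",
    "unique_pairings",
    "sweep_inactive_max",
]


@dataclass(frozen=True)
class Thresholds:
    """Activity/inactivity cutoffs in RFU/OD600.

    ``active_min`` = 10,000 is the published activity threshold. The
    inactivity threshold defaults to 2,500 and should be treated as a
    tunable: see :func:`sweep_inactive_max`.
    """

    active_min: float = 10_000.0
    inactive_max: float = 2_500.0

    def __post_init__(self) -> None:
        if not self.inactive_max < self.active_min:
            raise ValueError("inactive_max must be below active_min")


@dataclass(frozen=True, order=True)
class OrthogonalPair:
    """Unordered pair of (aaRS, monomer) assignments, canonicalized."""

    left: tuple[str, str]
    right: tuple[str, str]

    @staticmethod
    def make(a: tuple[str, str], b: tuple[str, str]) -> "OrthogonalPair":
        return OrthogonalPair(*sorted((tuple(a), tuple(b))))

    @property
    def substrates(self) -> tuple[str, str]:
        return tuple(sorted((self.left[1], self.right[1])))


class ActivityMatrix:
    """aaRS × monomer normalized fluorescence with groups and exclusions.

    ``values`` is a DataFrame (rows aaRS, columns monomer ids) with no
    missing entries — a silent zero would fabricate inactivity, so NaN
    is rejected at construction. ``groups`` maps each aaRS to its class
    label; ``excluded`` is the set of masked (aaRS, monomer) cells.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        groups: pd.Series | dict[str, str],
        excluded: set[tuple[str, str]] | None = None,
    ):
        values = values.astype(float)
        if values.isna().any().any():
            missing = [
                (r, c)
                for r, c in zip(*np.where(values.isna().to_numpy()))
            ]
            raise ValueError(f"activity matrix has missing values at {missing[:5]}")
        if (values.to_numpy() < 0).any():
            raise ValueError("activity values must be non-negative")
        groups = pd.Series(groups)
        if set(groups.index) != set(values.index):
            raise ValueError("every aaRS row needs exactly one group label")
        excluded = set(excluded or ())
        for aars, monomer in excluded:
            if aars not in values.index:
                raise KeyError(f"exclusion names unknown aaRS {aars!r}")
            if monomer not in values.columns:
                raise KeyError(f"exclusion names unknown monomer {monomer!r}")
        self.values = values
        self.groups = groups.loc[values.index]
        self.excluded = frozenset(excluded)

    @property
    def aars(self) -> list[str]:
        return list(self.values.index)

    @property
    def monomers(self) -> list[str]:
        return list(self.values.columns)

    def with_exclusions(self, cells: set[tuple[str, str]]) -> "ActivityMatrix":
        return ActivityMatrix(self.values, self.groups, set(self.excluded) | set(cells))

    def is_excluded(self, aars: str, monomer: str) -> bool:
        return (aars, monomer) in self.excluded


#: the published exclusion rule: the aromatic hydroxy acids F-OH (14),
#: pIF-OH (15) and NapA-OH (16) read out amino-acid incorporation with
#: the two tyrosyl synthetases, so those six cells are masked.
DEFAULT_EXCLUSIONS: frozenset[tuple[str, str]] = frozenset(
    (aars, monomer)
    for aars in ("AfTyrRS(pIF)", "AfTyrRS(pAzF)")
    for monomer in ("14", "15", "16")
)


def apply_exclusions(
    m: ActivityMatrix,
    rules: set[tuple[str, str]] | frozenset[tuple[str, str]] = DEFAULT_EXCLUSIONS,
) -> ActivityMatrix:
    """Mask the named cells; values are retained but become inert."""
    return m.with_exclusions(set(rules))


def find_pairs(m: ActivityMatrix, t: Thresholds = Thresholds()) -> set[OrthogonalPair]:
    """All mutually orthogonal (aaRS, monomer) pairs at thresholds *t*.

    Deterministic and order-independent: the result is a set of
    canonicalized unordered pairs drawn across distinct groups, with no
    excluded cell participating in any of the four judgements.
    """
    values = m.values.to_numpy()
    aars = m.aars
    monomers = m.monomers
    groups = m.groups.to_numpy()
    excl = np.zeros(values.shape, dtype=bool)
    for a, mono in m.excluded:
        excl[aars.index(a), monomers.index(mono)] = True

    usable = ~excl
    active = (values > t.active_min) & usable
    inactive = (values < t.inactive_max) & usable

    pairs: set[OrthogonalPair] = set()
    n_rows = len(aars)
    for r1, r2 in itertools.combinations(range(n_rows), 2):
        if groups[r1] == groups[r2]:
            continue
        # monomer1 candidates: active on r1, inactive on r2; vice versa for monomer2
        m1_idx = np.flatnonzero(active[r1] & inactive[r2])
        m2_idx = np.flatnonzero(active[r2] & inactive[r1])
        for c1 in m1_idx:
            for c2 in m2_idx:
                pairs.add(
                    OrthogonalPair.make(
                        (aars[r1], monomers[c1]), (aars[r2], monomers[c2])
                    )
                )
    return pairs


def unique_pairings(pairs: set[OrthogonalPair]) -> set[tuple[str, str]]:
    """Project pairs to their distinct unordered substrate combinations."""
    return {p.substrates for p in pairs}


def sweep_inactive_max(
    m: ActivityMatrix,
    candidates: list[float] | np.ndarray,
    active_min: float = 10_000.0,
) -> pd.DataFrame:
    """Pair and unique-substrate-pairing counts as inactive_max varies.

    The published analysis states its activity threshold but the
    inactivity threshold is not recoverable from the text; this sweep is
    the tool for recovering it against a transcribed matrix (find the
    thresholds reproducing the published pair counts).
    """
    rows = []
    for cutoff in candidates:
        pairs = find_pairs(m, Thresholds(active_min=active_min, inactive_max=float(cutoff)))
        rows.append(
            {
                "inactive_max": float(cutoff),
                "n_pairs": len(pairs),
                "n_unique_pairings": len(unique_pairings(pairs)),
            }
        )
    return pd.DataFrame(rows)
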