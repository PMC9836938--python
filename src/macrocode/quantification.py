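"""Gel-fluorescence peptide quantification.

Macrocycle yields are read off SDS-PAGE gels of fluorophore-labelled
peptide: a standard curve of labelled reference peptide (amount in nmol
vs integrated band intensity, fitted on replicate means), an internal
standard of known amount run alongside each gel to correct lane-to-lane
variation, and a hard zero rule — no estimate is reported unless the
labelling control shows a visible signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = ["StandardCurve", "fit_curve", "quantify"]


@dataclass(frozen=True)
class StandardCurve:
    """Linear intensity = slope × amount + intercept, fitted on replicate means."""

    slope: float
    intercept: float
    r_squared: float

    def predict(self, amount: float) -> float:
        return self.slope * amount + self.intercept

    def invert(self, intensity: float) -> float:
        if self.slope == 0:
            raise ZeroDivisionError("cannot invert a flat standard curve")
        return (intensity - self.intercept) / self.slope


def fit_curve(points: Iterable[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of mean band intensity on amount (nmol).

    ``points`` are (amount, intensity) observations; replicates of the
    same amount are averaged before the fit, mirroring a triplicate
    standard-curve protocol. Requires ≥ 2 distinct amounts and
    non-negative intensities.
    """
    pts = [(float(a), float(i)) for a, i in points]
    if any(i < 0 for _, i in pts):
        raise ValueError("intensities must be non-negative")
    amounts = sorted({a for a, _ in pts})
    if len(amounts) < 2:
        raise ValueError("need at least 2 distinct amounts to fit a line")
    means = [float(np.mean([i for a, i in pts if a == amount])) for amount in amounts]
    fit = stats.linregress(amounts, means)
    return StandardCurve(slope=fit.slope, intercept=fit.intercept, r_squared=fit.rvalue**2)


def quantify(
    intensity: float,
    curve: StandardCurve,
    internal_standard: tuple[float, float] | None = None,
    control_visible: bool = True,
) -> float:
    """Amount (nmol) for an observed band intensity.

    ``internal_standard`` is (known amount, observed intensity) of the
    co-run reference; the correction factor is known / curve-inverted
    observed amount, applied multiplicatively. If the labelling control
    shows no visible signal (``control_visible=False``) the reported
    amount is 0 regardless of intensity.
    """
    if not control_visible:
        return 0.0
    estimate = curve.invert(intensity)
    if internal_standard is not None:
        known, observed_intensity = internal_standard
        if observed_intensity <= 0:
            raise ValueError("internal-standard intensity must be positive")
        observed_amount = curve.invert(observed_intensity)
        if observed_amount <= 0:
            raise ValueError("internal standard inverts to a non-positive amount")
        estimate *= known / observed_amount
    return estimate
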