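"""Serial-dilution calibration analysis.

For each concentration of the dilution series the replicate spectra (36 per
substrate position scan in the reference protocol) are averaged point-wise,
the average is baseline-corrected, and the ratio of the two PFOS marker
peaks P1 (997 cm^-1, C-C) over P2 (1044 cm^-1, S-O3) is computed.  The
P1/P2 ratio rather than a raw intensity is plotted against concentration
because it cancels spot-to-spot SERS enhancement variability.

A concentration whose P2 apex does not rise above ``k`` times the local
noise level is flagged below-detection instead of contributing a spurious
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, EmptyInputError
from .spectra import RamanSpectrum, peak_intensity, remove_baseline

__all__ = ["CalibrationPoint", "average_spectra", "calibration_curve",
           "noise_std", "P1", "P2"]

P1 = 997.0
P2 = 1044.0


def average_spectra(replicates: list[RamanSpectrum]) -> RamanSpectrum:
    """Point-wise arithmetic mean of replicate spectra on one grid."""
    if not replicates:
        raise EmptyInputError("no replicate spectra to average")
    w = replicates[0].wavenumbers
    for s in replicates[1:]:
        if not np.array_equal(s.wavenumbers, w):
            raise AlignmentError("replicates must share one wavenumber grid")
    mean = np.mean([s.intensities for s in replicates], axis=0)
    return RamanSpectrum(w, mean, {"source": "mean_spectrum",
                                   "n_replicates": len(replicates)})


def noise_std(s: RamanSpectrum) -> float:
    """Robust white-noise estimate from first differences.

    For white noise of standard deviation sigma the first differences have
    standard deviation sigma*sqrt(2); the median absolute deviation makes the
    estimate insensitive to the sparse large differences at peak edges.
    """
    d = np.diff(s.intensities)
    madn = 1.4826 * np.median(np.abs(d - np.median(d)))
    return float(madn / np.sqrt(2.0))


@dataclass(frozen=True)
class CalibrationPoint:
    """One concentration of the calibration curve.

    Peak intensities are net heights: the windowed apex minus the local
    background level around the peak (median of an annulus excluding both
    marker windows), so any residual offset the baseline smoother leaves
    behind cancels out of the ratio."""

    concentration: float
    n_replicates: int
    mean_spectrum: RamanSpectrum
    p1_intensity: float
    p2_intensity: float
    p1_over_p2: float  # NaN when below detection
    below_detection: bool


def _local_background(s: RamanSpectrum, center: float, inner: float = 15.0,
                      outer: float = 70.0) -> float:
    """Median intensity in an annulus around ``center``, excluding the
    windows of both marker peaks."""
    w = s.wavenumbers
    mask = (np.abs(w - center) <= outer) & (np.abs(w - center) > inner)
    for other in (P1, P2):
        mask &= np.abs(w - other) > inner
    if not mask.any():
        return 0.0
    return float(np.median(s.intensities[mask]))


def calibration_curve(groups: dict[float, list[RamanSpectrum]],
                      window: float = 10.0, lam: float = 1e5, p: float = 0.001,
                      detection_k: float = 3.0) -> list[CalibrationPoint]:
    """Build the P1/P2 calibration curve from per-concentration replicates.

    Parameters
    ----------
    groups : dict
        concentration (ppb) -> replicate spectra.
    detection_k : float
        P2 must exceed ``detection_k`` times the estimated noise standard
        deviation of the averaged, baseline-corrected spectrum, or the point
        is flagged below-detection (the three-sigma convention by default).

    Returns points sorted by concentration ascending.
    """
    if len(groups) < 2:
        raise ValueError("need at least two concentration groups")
    points = []
    for conc in sorted(groups):
        mean = average_spectra(groups[conc])
        flat = remove_baseline(mean, lam=lam, p=p)
        p1 = peak_intensity(flat, P1, window) - _local_background(flat, P1)
        p2 = peak_intensity(flat, P2, window) - _local_background(flat, P2)
        sigma = noise_std(flat)
        below = p2 < detection_k * sigma
        ratio = float("nan") if below else p1 / p2
        points.append(CalibrationPoint(
            concentration=conc, n_replicates=len(groups[conc]),
            mean_spectrum=mean, p1_intensity=p1, p2_intensity=p2,
            p1_over_p2=ratio, below_detection=below,
        ))
    return points


def calibration_frame(points: list[CalibrationPoint]) -> pd.DataFrame:
    """Flatten calibration points into the CSV-ready table."""
    return pd.DataFrame([{
        "concentration_ppb": pt.concentration,
        "n_replicates": pt.n_replicates,
        "p1_intensity": pt.p1_intensity,
        "p2_intensity": pt.p2_intensity,
        "p1_over_p2": pt.p1_over_p2,
        "below_detection": pt.below_detection,
    } for pt in points])
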