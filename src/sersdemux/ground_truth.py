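"""Ground-truth estimation for measured PFOS-on-SERS spectra.

A measured PFOS-on-SERS spectrum has no directly observable "clean PFOS"
component, so its training target is estimated from the powder reference in
three steps:

1. remove the baselines of both the on-SERS spectrum and the powder
   reference (same smoother, same parameters, so both sit at zero trend);
2. take the ratio of their peak intensities at the 1044 cm^-1 S-O3 anchor
   -- the one strong PFOS line the substrate background does not overlap;
3. multiply the baseline-removed powder reference by that ratio.

The result is a scaled powder signature whose 1044 cm^-1 intensity matches
the measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AlignmentError, DegenerateInputError
from .spectra import RamanSpectrum, peak_intensity, remove_baseline

__all__ = ["GroundTruthEstimate", "estimate_ground_truth", "ANCHOR_WAVENUMBER"]

ANCHOR_WAVENUMBER = 1044.0


@dataclass(frozen=True)
class GroundTruthEstimate:
    """Output of :func:`estimate_ground_truth`: the estimated clean PFOS
    component, the scale ratio that produced it, and the anchor used."""

    truth: RamanSpectrum
    ratio: float
    anchor_wavenumber: float = ANCHOR_WAVENUMBER


def estimate_ground_truth(on_sers: RamanSpectrum, powder: RamanSpectrum,
                          lam: float = 1e5, p: float = 0.001,
                          window: float = 10.0,
                          anchor: float = ANCHOR_WAVENUMBER) -> GroundTruthEstimate:
    """Estimate the clean PFOS component of a measured on-SERS spectrum.

    Parameters
    ----------
    on_sers, powder : RamanSpectrum
        Measured PFOS-on-SERS spectrum and the powder reference, on one grid
        covering the anchor wavenumber.
    lam, p : float
        Asymmetric-least-squares baseline parameters, applied identically to
        both spectra.
    window : float
        Half-width (cm^-1) of the windowed peak maximum at the anchor.
    """
    if not np.array_equal(on_sers.wavenumbers, powder.wavenumbers):
        raise AlignmentError("on-SERS and powder spectra must share one grid")
    flat_sers = remove_baseline(on_sers, lam=lam, p=p)
    flat_powder = remove_baseline(powder, lam=lam, p=p)
    i_sers = peak_intensity(flat_sers, anchor, window)
    i_powder = peak_intensity(flat_powder, anchor, window)
    if i_powder <= 0:
        raise DegenerateInputError(
            f"powder reference has non-positive intensity at {anchor} cm^-1"
        )
    ratio = i_sers / i_powder
    truth = flat_powder.with_intensities(ratio * flat_powder.intensities,
                                         source="ground_truth")
    return GroundTruthEstimate(truth=truth, ratio=ratio, anchor_wavenumber=anchor)
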