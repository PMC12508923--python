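"""Spectrum data model, file I/O, resampling, normalization, baseline
correction and peak utilities.

A :class:`RamanSpectrum` is the currency of every stage of the pipeline: a
strictly increasing wavenumber axis (cm^-1) paired with finite intensities
(arbitrary units) and a free-form metadata map.  All downstream modelling
happens on a fixed common grid (:class:`GridSpec`, 896 points by default)
because the networks consume fixed-length tensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    EmptyInputError,
    GridRangeError,
    ParameterError,
    SpectrumFormatError,
)

__all__ = [
    "RamanSpectrum",
    "GridSpec",
    "ScaleRecord",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "normalize_symmetric",
    "denormalize",
    "asls_baseline",
    "remove_baseline",
    "peak_intensity",
    "peak_ratio",
    "DEFAULT_GRID",
]


@dataclass(frozen=True)
class RamanSpectrum:
    """A single Raman spectrum.

    Parameters
    ----------
    wavenumbers : ndarray
        Strictly increasing Raman shifts in cm^-1, length >= 2.
    intensities : ndarray
        Intensities (a.u.), same length, all finite.
    meta : mapping
        Free-form labels (source, concentration_ppb, substrate id, ...).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1:
            raise SpectrumFormatError("wavenumbers and intensities must be 1-D")
        if w.size != y.size:
            raise SpectrumFormatError(
                f"length mismatch: {w.size} wavenumbers vs {y.size} intensities"
            )
        if w.size < 2:
            raise SpectrumFormatError("a spectrum needs at least 2 points")
        if not np.all(np.diff(w) > 0):
            raise SpectrumFormatError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(y)):
            raise SpectrumFormatError("non-finite values in spectrum")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, y: np.ndarray, **meta: object) -> "RamanSpectrum":
        """Return a copy sharing this axis but with new intensities."""
        merged = {**dict(self.meta), **meta}
        return RamanSpectrum(self.wavenumbers, np.asarray(y, dtype=float), merged)


@dataclass(frozen=True)
class GridSpec:
    """A uniform wavenumber grid.  The default covers 400-1800 cm^-1 with
    896 points, which brackets the PFOS marker peaks at 997 and 1044 cm^-1
    with the margin typical of 785 nm Raman work."""

    start: float = 400.0
    stop: float = 1800.0
    n_points: int = 896

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ConfigurationError("grid start must be < stop")
        if self.n_points < 2:
            raise ConfigurationError("grid needs at least 2 points")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)


DEFAULT_GRID = GridSpec()


# ---------------------------------------------------------------------------
# file I/O

def _parse_row(token_row: list[str]) -> tuple[float, float] | None:
    if len(token_row) < 2:
        return None
    try:
        return float(token_row[0]), float(token_row[1])
    except ValueError:
        return None


def read_spectrum(path: str | Path, delimiter: str | None = None,
                  meta: Mapping[str, object] | None = None) -> RamanSpectrum:
    """Read a two-column (wavenumber, intensity) delimited text file.

    Comma, tab or whitespace delimiters are auto-detected per line; a single
    leading header row is skipped.  Rows are sorted by wavenumber; duplicate
    wavenumbers are rejected.
    """
    path = Path(path)
    text = path.read_text()
    rows: list[tuple[float, float]] = []
    n_seen = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if delimiter is not None:
            tokens = [t for t in line.split(delimiter) if t.strip()]
        elif "," in line:
            tokens = [t for t in line.split(",") if t.strip()]
        else:
            tokens = line.split()
        n_seen += 1
        parsed = _parse_row(tokens)
        if parsed is None:
            if n_seen == 1:
                continue  # header row
            raise SpectrumFormatError(f"{path}: unparseable row at line {lineno}: {line!r}")
        rows.append(parsed)
    if not rows:
        raise EmptyInputError(f"{path}: no numeric rows")
    if len(rows) < 2:
        raise SpectrumFormatError(f"{path}: need at least 2 numeric rows, got {len(rows)}")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) == 0):
        dup = arr[:-1, 0][np.diff(arr[:, 0]) == 0][0]
        raise SpectrumFormatError(f"{path}: duplicate wavenumber {dup}")
    return RamanSpectrum(arr[:, 0], arr[:, 1], dict(meta or {}))


def write_spectrum(s: RamanSpectrum, path: str | Path, delimiter: str = ",",
                   header: bool = True) -> None:
    """Write a spectrum as two-column delimited text (full float precision)."""
    path = Path(path)
    lines = []
    if header:
        lines.append(delimiter.join(["wavenumber_cm-1", "intensity"]))
    for w, y in zip(s.wavenumbers, s.intensities):
        lines.append(f"{float(w)!r}{delimiter}{float(y)!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# resampling and normalization

def resample(s: RamanSpectrum, grid: GridSpec) -> RamanSpectrum:
    """Linearly interpolate a spectrum onto a uniform grid.

    The grid must lie within the measured range; extrapolation is refused.
    """
    w = grid.wavenumbers
    if w[0] < s.wavenumbers[0] or w[-1] > s.wavenumbers[-1]:
        raise GridRangeError(
            f"grid [{w[0]}, {w[-1]}] extends beyond data range "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]"
        )
    y = np.interp(w, s.wavenumbers, s.intensities)
    return RamanSpectrum(w, y, dict(s.meta))


@dataclass(frozen=True)
class ScaleRecord:
    """The affine map used by :func:`normalize_symmetric`; retains (min, max)
    so the transform can be inverted and applied to paired spectra."""

    lo: float
    hi: float

    def apply(self, y: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(y, dtype=float) - self.lo) / (self.hi - self.lo) - 1.0

    def invert(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) + 1.0) * (self.hi - self.lo) / 2.0 + self.lo


def normalize_symmetric(s: RamanSpectrum) -> tuple[RamanSpectrum, ScaleRecord]:
    """Min-max map of the intensities onto [-1, +1].

    The network's final Tanh restricts outputs to (-1, 1), so inputs are
    brought onto the same scale.  The returned :class:`ScaleRecord` lets the
    caller apply the identical affine map to the paired ground truth (so that
    mixture and target share one scale) and to invert predictions.
    """
    y = s.intensities
    lo, hi = float(y.min()), float(y.max())
    if hi <= lo:
        raise DegenerateInputError("constant spectrum cannot be normalized to [-1, 1]")
    rec = ScaleRecord(lo, hi)
    return s.with_intensities(rec.apply(y)), rec


def denormalize(s: RamanSpectrum, rec: ScaleRecord) -> RamanSpectrum:
    """Undo :func:`normalize_symmetric` using its stored scale record."""
    return s.with_intensities(rec.invert(s.intensities))


# ---------------------------------------------------------------------------
# baseline correction

def asls_baseline(y: np.ndarray, lam: float = 1e5, p: float = 0.001,
                  n_iter: int = 10) -> np.ndarray:
    """Asymmetric least-squares baseline estimate (Whittaker smoother with
    asymmetric weights).

    Minimises ``sum_i w_i (y_i - z_i)^2 + lam * sum_i (Delta^2 z_i)^2`` where
    the weights are iteratively set to ``p`` above the current baseline and
    ``1 - p`` below it, so peaks barely pull the baseline up while the valleys
    anchor it.

    Parameters
    ----------
    lam : float
        Smoothness (typical Raman range 1e4 - 1e7).
    p : float
        Asymmetry, 0 < p < 1 (typical 0.001 - 0.1).
    """
    if lam <= 0:
        raise ParameterError(f"lam must be > 0, got {lam}")
    if not 0.0 < p < 1.0:
        raise ParameterError(f"p must be in (0, 1), got {p}")
    y = np.asarray(y, dtype=float)
    n = y.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    dtd = lam * (d @ d.T)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        wmat = sparse.diags(w)
        z = spsolve((wmat + dtd).tocsc(), w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def remove_baseline(s: RamanSpectrum, lam: float = 1e5, p: float = 0.001,
                    n_iter: int = 10) -> RamanSpectrum:
    """Subtract the asymmetric-least-squares baseline estimate.

    Removes the slowly varying background (fluorescence, substrate continuum)
    while leaving peak positions untouched; required before peak intensities
    of different spectra can be ratioed.
    """
    if len(s) < 10:
        raise ParameterError("baseline removal needs a spectrum of length >= 10")
    z = asls_baseline(s.intensities, lam=lam, p=p, n_iter=n_iter)
    return s.with_intensities(s.intensities - z)


# ---------------------------------------------------------------------------
# peak utilities

def peak_intensity(s: RamanSpectrum, center: float, window: float = 10.0) -> float:
    """Maximum intensity within ``center +/- window`` cm^-1.

    A windowed maximum rather than a single-bin lookup, so a few cm^-1 of
    peak-position jitter against the grid does not miss the apex.
    """
    mask = (s.wavenumbers >= center - window) & (s.wavenumbers <= center + window)
    if not mask.any():
        raise GridRangeError(
            f"window [{center - window}, {center + window}] does not intersect "
            f"the spectrum range [{s.wavenumbers[0]}, {s.wavenumbers[-1]}]"
        )
    return float(s.intensities[mask].max())


def peak_ratio(s: RamanSpectrum, w1: float, w2: float, window: float = 10.0) -> float:
    """Ratio of windowed peak intensities ``I(w1) / I(w2)``.

    Used for the P1/P2 calibration ratio with w1 = 997 cm^-1 (C-C) and
    w2 = 1044 cm^-1 (S-O3).
    """
    i1 = peak_intensity(s, w1, window)
    i2 = peak_intensity(s, w2, window)
    if i2 == 0.0:
        raise DegenerateInputError(
            f"zero peak intensity at {w2} cm^-1; ratio undefined"
        )
    return i1 / i2
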