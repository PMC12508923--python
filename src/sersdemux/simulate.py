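"""Synthetic spectra, mixture simulation and dataset assembly.

The deep networks are trained on mixtures of three components:

* a PFOS reference spectrum (the powder signature, dominated by the
  997 cm^-1 C-C and 1044 cm^-1 S-O3 peaks, the latter the stronger),
* a SERS-substrate background (broad continuum plus substrate peaks, none
  of which fall near 1044 cm^-1 -- the identifiability assumption that makes
  the S-O3 peak the quantitation anchor),
* white Gaussian noise.

A simulated mixture is ``K1*BKG + K2*PFOS + K3*GN`` with K1, K2 drawn
uniformly from [0.5, 5] and K3 equal to the peak intensity of the noiseless
mixture times a uniform [0.01, 1] factor; the paired ground truth is
``K2*PFOS``.  Experimental-like records are PFOS-on-SERS stand-ins spanning
a serial dilution, augmented once each by ``C1*spectrum + C2*noise``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .exceptions import AlignmentError, ConfigurationError
from .ground_truth import estimate_ground_truth
from .spectra import DEFAULT_GRID, GridSpec, RamanSpectrum

__all__ = [
    "PeakModel",
    "MixtureRecord",
    "DatasetSplits",
    "DatasetConfig",
    "PFOS_PEAKS",
    "BACKGROUND_PEAKS",
    "make_reference_pfos",
    "make_background",
    "simulate_mixture",
    "augment_actual",
    "make_pfos_on_sers",
    "build_dataset",
    "P2_EXCLUSION_HALFWIDTH",
]

#: no background peak may sit within this distance of the 1044 cm^-1 anchor
P2_EXCLUSION_HALFWIDTH = 15.0
_P2 = 1044.0


@dataclass(frozen=True)
class PeakModel:
    """A single spectral line: Lorentzian or Gaussian, parameterised by
    center (cm^-1), amplitude (a.u.) and full width at half maximum."""

    center: float
    amplitude: float
    width: float
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError("peak amplitude must be >= 0")
        if self.width <= 0:
            raise ConfigurationError("peak width must be > 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ConfigurationError(f"unknown peak shape {self.shape!r}")

    def profile(self, w: np.ndarray) -> np.ndarray:
        x = np.asarray(w, dtype=float) - self.center
        half = self.width / 2.0
        if self.shape == "lorentzian":
            return self.amplitude / (1.0 + (x / half) ** 2)
        return self.amplitude * np.exp(-np.log(2.0) * (x / half) ** 2)


#: default PFOS powder signature: the two marker peaks plus minor lines
PFOS_PEAKS: tuple[PeakModel, ...] = (
    PeakModel(997.0, 0.55, 9.0),    # P1, C-C stretch
    PeakModel(1044.0, 1.00, 8.0),   # P2, S-O3 stretch (dominant)
    PeakModel(590.0, 0.12, 12.0),
    PeakModel(735.0, 0.22, 11.0),
    PeakModel(822.0, 0.10, 10.0),
    PeakModel(1150.0, 0.18, 13.0),
    PeakModel(1218.0, 0.12, 12.0),
    PeakModel(1372.0, 0.08, 14.0),
)

#: default blank-substrate peaks; none within the P2 exclusion zone.  Broad
#: substrate bands are modelled as Gaussians: their tails decay fast enough
#: that nothing leaks under the 1044 cm^-1 anchor, preserving the
#: identifiability assumption after baseline removal.
BACKGROUND_PEAKS: tuple[PeakModel, ...] = (
    PeakModel(520.0, 0.35, 30.0, "gaussian"),
    PeakModel(655.0, 0.25, 35.0, "gaussian"),
    PeakModel(960.0, 0.45, 24.0, "gaussian"),
    PeakModel(1098.0, 0.30, 26.0, "gaussian"),
    PeakModel(1290.0, 0.40, 32.0, "gaussian"),
    PeakModel(1448.0, 0.28, 30.0, "gaussian"),
    PeakModel(1595.0, 0.50, 28.0, "gaussian"),
)


def _sum_peaks(peaks: Iterable[PeakModel], grid: GridSpec) -> np.ndarray:
    w = grid.wavenumbers
    y = np.zeros_like(w)
    for p in peaks:
        if not grid.start <= p.center <= grid.stop:
            raise ConfigurationError(
                f"peak center {p.center} cm^-1 outside grid "
                f"[{grid.start}, {grid.stop}]"
            )
        y += p.profile(w)
    return y


def make_reference_pfos(peaks: Sequence[PeakModel] | None = None,
                        grid: GridSpec = DEFAULT_GRID) -> RamanSpectrum:
    """Deterministic PFOS reference spectrum on the given grid.

    The default peak set carries the 997 and 1044 cm^-1 markers with the
    1044 line dominant, plus six minor lines.
    """
    peaks = PFOS_PEAKS if peaks is None else tuple(peaks)
    return RamanSpectrum(grid.wavenumbers, _sum_peaks(peaks, grid),
                         {"source": "pfos_reference"})


def make_background(peaks: Sequence[PeakModel] | None = None,
                    baseline_amplitude: float = 1.0,
                    grid: GridSpec = DEFAULT_GRID) -> RamanSpectrum:
    """Deterministic blank-substrate background: a broad smooth continuum
    plus substrate peaks.

    Placing a peak within +/- 15 cm^-1 of 1044 is refused: the whole method
    rests on the substrate having no line under the S-O3 anchor.
    """
    peaks = BACKGROUND_PEAKS if peaks is None else tuple(peaks)
    for p in peaks:
        if abs(p.center - _P2) < P2_EXCLUSION_HALFWIDTH:
            raise ConfigurationError(
                f"background peak at {p.center} cm^-1 lies within "
                f"{P2_EXCLUSION_HALFWIDTH} cm^-1 of the {_P2} anchor"
            )
    w = grid.wavenumbers
    # slowly decaying continuum with a broad hump, typical of substrate
    # fluorescence under 785 nm excitation
    t = (w - grid.start) / (grid.stop - grid.start)
    continuum = baseline_amplitude * (
        0.9 * np.exp(-2.2 * t) + 0.5 * np.exp(-0.5 * ((t - 0.55) / 0.25) ** 2)
    )
    y = continuum + _sum_peaks(peaks, grid)
    return RamanSpectrum(w, y, {"source": "background"})


# ---------------------------------------------------------------------------
# records and splits

@dataclass(frozen=True)
class MixtureRecord:
    """A mixture spectrum paired with its ground-truth PFOS component and the
    coefficients that produced it.

    ``coefficients`` is (K1, K2, K3) for simulated records and (C1, C2) for
    experimental-like ones; ``noise`` stores the unit-variance noise draw so
    simulated mixtures reconstruct exactly from their components.
    """

    mixture: RamanSpectrum
    truth: RamanSpectrum
    coefficients: tuple[float, ...]
    provenance: str  # "simulated" | "experimental_like"
    record_id: int = -1
    concentration: float | None = None
    noise: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.provenance not in ("simulated", "experimental_like"):
            raise ConfigurationError(f"unknown provenance {self.provenance!r}")
        if not np.array_equal(self.mixture.wavenumbers, self.truth.wavenumbers):
            raise AlignmentError("mixture and truth must share one grid")


@dataclass
class DatasetSplits:
    """Train/validation/test collections of :class:`MixtureRecord`."""

    train: list[MixtureRecord]
    validation: list[MixtureRecord]
    test: list[MixtureRecord]
    seed: int

    def __iter__(self):
        yield from (self.train, self.validation, self.test)

    @property
    def counts_by_provenance(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for name, split in zip(("train", "validation", "test"), self):
            tally: dict[str, int] = {}
            for r in split:
                tally[r.provenance] = tally.get(r.provenance, 0) + 1
            out[name] = tally
        return out


# ---------------------------------------------------------------------------
# mixture simulation

def simulate_mixture(bkg: RamanSpectrum, pfos: RamanSpectrum,
                     rng: np.random.Generator,
                     k1: float | None = None, k2: float | None = None,
                     k3: float | None = None) -> MixtureRecord:
    """Draw one simulated mixture ``K1*BKG + K2*PFOS + K3*GN``.

    K1, K2 ~ Uniform(0.5, 5); K3 = max(K1*BKG + K2*PFOS) * Uniform(0.01, 1);
    GN is zero-mean unit-variance white Gaussian noise on the grid.  Explicit
    ``k1``/``k2``/``k3`` override the draws (used for controlled fixtures).
    The ground truth is ``K2*PFOS``.
    """
    if not np.array_equal(bkg.wavenumbers, pfos.wavenumbers):
        raise AlignmentError("background and PFOS reference must share one grid")
    K1 = float(rng.uniform(0.5, 5.0)) if k1 is None else float(k1)
    K2 = float(rng.uniform(0.5, 5.0)) if k2 is None else float(k2)
    clean = K1 * bkg.intensities + K2 * pfos.intensities
    K3 = float(clean.max() * rng.uniform(0.01, 1.0)) if k3 is None else float(k3)
    gn = rng.standard_normal(len(bkg))
    mixture = clean + K3 * gn
    return MixtureRecord(
        mixture=bkg.with_intensities(mixture, source="simulated_mixture"),
        truth=bkg.with_intensities(K2 * pfos.intensities, source="ground_truth"),
        coefficients=(K1, K2, K3),
        provenance="simulated",
        noise=gn,
    )


# ---------------------------------------------------------------------------
# experimental-like stand-ins and augmentation

#: enhancement factor vs concentration (ppb); non-monotone, strongest signal
#: at 0.05 ppb, reflecting SERS hot-spot saturation at high coverage
ENHANCEMENT_PROFILE: dict[float, float] = {
    5.0: 0.8,
    0.5: 1.2,
    0.05: 2.0,
    0.005: 0.9,
    0.0005: 0.35,
    0.00005: 0.0,  # below detection: the S-O3 peak vanishes
}


def make_pfos_on_sers(concentration: float, pfos: RamanSpectrum,
                      bkg: RamanSpectrum, rng: np.random.Generator,
                      enhancement: dict[float, float] | None = None,
                      noise_sigma_frac: float = 0.02) -> RamanSpectrum:
    """One PFOS-on-SERS stand-in spectrum at the given concentration.

    Built as ``enh * PFOS + atten * BKG + noise`` where ``enh`` is the
    concentration's enhancement factor with ~15% lognormal spot-to-spot
    jitter, ``atten ~ U(0.4, 0.9)`` attenuates the substrate background, and
    the additive noise has standard deviation ``noise_sigma_frac`` times the
    clean maximum.  The PFOS component amplitude is stored in ``meta`` for
    oracle checks.
    """
    prof = ENHANCEMENT_PROFILE if enhancement is None else enhancement
    if concentration not in prof:
        raise ConfigurationError(
            f"no enhancement factor for concentration {concentration} ppb"
        )
    enh = prof[concentration] * float(np.exp(rng.normal(0.0, 0.15)))
    if prof[concentration] == 0.0:
        enh = 0.0
    atten = float(rng.uniform(0.4, 0.9))
    clean = enh * pfos.intensities + atten * bkg.intensities
    sigma = noise_sigma_frac * max(clean.max(), 1e-12)
    y = clean + sigma * rng.standard_normal(len(pfos))
    return RamanSpectrum(pfos.wavenumbers, y, {
        "source": "pfos_on_sers",
        "concentration_ppb": concentration,
        "enhancement": enh,
        "attenuation": atten,
    })


def augment_actual(base: MixtureRecord, rng: np.random.Generator,
                   draw_log: set[tuple[float, float]] | None = None,
                   c1: float | None = None,
                   c2: float | None = None) -> MixtureRecord:
    """Augment an experimental-like record: ``C1*spectrum + C2*noise``.

    C1 ~ Uniform(0.5, 5); C2 = max(C1*spectrum) * Uniform(0.01, 1) (the same
    laws as K1/K3 of the simulator).  Freshly drawn (C1, C2) pairs are checked
    against ``draw_log`` so no pair repeats within one dataset build.  The
    ground truth scales with C1.
    """
    C1 = float(rng.uniform(0.5, 5.0)) if c1 is None else float(c1)
    scaled = C1 * base.mixture.intensities
    C2 = float(np.abs(scaled).max() * rng.uniform(0.01, 1.0)) if c2 is None else float(c2)
    if draw_log is not None:
        while (C1, C2) in draw_log:  # pragma: no cover - measure-zero event
            C1 = float(rng.uniform(0.5, 5.0))
            scaled = C1 * base.mixture.intensities
            C2 = float(np.abs(scaled).max() * rng.uniform(0.01, 1.0))
        draw_log.add((C1, C2))
    noise = rng.standard_normal(len(base.mixture))
    return MixtureRecord(
        mixture=base.mixture.with_intensities(scaled + C2 * noise),
        truth=base.truth.with_intensities(C1 * base.truth.intensities),
        coefficients=(C1, C2),
        provenance="experimental_like",
        concentration=base.concentration,
        noise=noise,
    )


# ---------------------------------------------------------------------------
# dataset assembly

@dataclass(frozen=True)
class DatasetConfig:
    """Counts, seed and generator parameters for :func:`build_dataset`.

    The defaults replicate the study's arithmetic: 1080/120/30 simulated
    spectra; 630 experimental-like base spectra over five concentrations,
    30 reserved for the test split, the other 600 augmented once each to a
    pool of 1200 split 1080/120; merged totals 2160/240/60.
    """

    seed: int = 0
    grid: GridSpec = DEFAULT_GRID
    n_sim_train: int = 1080
    n_sim_val: int = 120
    n_sim_test: int = 30
    n_exp_base: int = 630
    n_exp_reserved_test: int = 30
    concentrations: tuple[float, ...] = (5.0, 0.5, 0.05, 0.005, 0.0005)
    noise_sigma_frac: float = 0.02
    truth_method: str = "procedure"  # "procedure" | "construction"
    baseline_lam: float = 1e5
    baseline_p: float = 0.001

    def __post_init__(self) -> None:
        if self.n_exp_reserved_test > self.n_exp_base:
            raise ConfigurationError("cannot reserve more spectra than the base pool")
        if self.n_exp_base < len(self.concentrations):
            raise ConfigurationError(
                "need at least one experimental spectrum per concentration"
            )
        pool = 2 * (self.n_exp_base - self.n_exp_reserved_test)
        if self.n_exp_train + self.n_exp_val != pool:
            raise ConfigurationError(
                f"augmented pool of {pool} cannot split into "
                f"{self.n_exp_train}/{self.n_exp_val}"
            )
        if self.truth_method not in ("procedure", "construction"):
            raise ConfigurationError(f"unknown truth_method {self.truth_method!r}")

    @property
    def n_exp_train(self) -> int:
        return self.n_sim_train

    @property
    def n_exp_val(self) -> int:
        return self.n_sim_val

    def scaled(self, factor: int) -> "DatasetConfig":
        """An integer-divided copy of the default counts (for quick runs)."""
        return replace(
            self,
            n_sim_train=self.n_sim_train // factor,
            n_sim_val=self.n_sim_val // factor,
            n_sim_test=self.n_sim_test // factor,
            n_exp_base=self.n_exp_base // factor,
            n_exp_reserved_test=self.n_exp_reserved_test // factor,
        )


def _experimental_truth(on_sers: RamanSpectrum, pfos: RamanSpectrum,
                        config: DatasetConfig) -> RamanSpectrum:
    if config.truth_method == "procedure":
        est = estimate_ground_truth(on_sers, pfos, lam=config.baseline_lam,
                                    p=config.baseline_p)
        return est.truth
    enh = float(on_sers.meta["enhancement"])
    return pfos.with_intensities(enh * pfos.intensities, source="ground_truth")


def build_dataset(config: DatasetConfig = DatasetConfig(),
                  pfos: RamanSpectrum | None = None,
                  bkg: RamanSpectrum | None = None) -> DatasetSplits:
    """Assemble seeded train/validation/test splits of mixture records.

    Simulated records come from :func:`simulate_mixture`; experimental-like
    records are PFOS-on-SERS stand-ins whose ground truth is estimated with
    the three-step powder-scaling procedure (baseline removal, 1044 cm^-1
    intensity ratio, powder rescaling), then augmented per the C1/C2 rule.
    All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pfos = make_reference_pfos(grid=config.grid) if pfos is None else pfos
    bkg = make_background(grid=config.grid) if bkg is None else bkg

    counter = 0

    def stamp(rec: MixtureRecord) -> MixtureRecord:
        nonlocal counter
        rec = replace(rec, record_id=counter)
        counter += 1
        return rec

    sim_splits = [
        [stamp(simulate_mixture(bkg, pfos, rng)) for _ in range(n)]
        for n in (config.n_sim_train, config.n_sim_val, config.n_sim_test)
    ]

    # experimental-like base pool over the dilution series; counts split as
    # evenly as the total allows, earlier concentrations taking the remainder
    n_conc = len(config.concentrations)
    per_conc_counts = [config.n_exp_base // n_conc + (1 if i < config.n_exp_base % n_conc else 0)
                       for i in range(n_conc)]
    base_records: list[MixtureRecord] = []
    for conc, n_at_conc in zip(config.concentrations, per_conc_counts):
        for _ in range(n_at_conc):
            on_sers = make_pfos_on_sers(conc, pfos, bkg, rng,
                                        noise_sigma_frac=config.noise_sigma_frac)
            truth = _experimental_truth(on_sers, pfos, config)
            base_records.append(stamp(MixtureRecord(
                mixture=on_sers, truth=truth, coefficients=(1.0, 0.0),
                provenance="experimental_like", concentration=conc,
            )))

    order = rng.permutation(len(base_records))
    reserved = [base_records[i] for i in order[:config.n_exp_reserved_test]]
    remaining = [base_records[i] for i in order[config.n_exp_reserved_test:]]

    draw_log: set[tuple[float, float]] = set()
    augmented = [stamp(augment_actual(r, rng, draw_log)) for r in remaining]
    pool = remaining + augmented
    pool_order = rng.permutation(len(pool))
    exp_train = [pool[i] for i in pool_order[:config.n_exp_train]]
    exp_val = [pool[i] for i in pool_order[config.n_exp_train:]]

    train = sim_splits[0] + exp_train
    val = sim_splits[1] + exp_val
    test = sim_splits[2] + reserved
    return DatasetSplits(train=train, validation=val, test=test, seed=config.seed)
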