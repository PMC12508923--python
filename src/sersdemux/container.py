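"""HDF5 dataset container: aligned arrays of mixtures, ground truths,
coefficients and provenance tags for each split."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .simulate import DatasetSplits, MixtureRecord
from .spectra import RamanSpectrum

__all__ = ["save_dataset", "load_dataset"]

_SPLITS = ("train", "validation", "test")


def save_dataset(splits: DatasetSplits, path: str | Path) -> None:
    """Write splits to one HDF5 file (one group per split)."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = splits.seed
        for name, records in zip(_SPLITS, splits):
            g = f.create_group(name)
            if not records:
                continue
            w = records[0].mixture.wavenumbers
            g.create_dataset("wavenumbers", data=w)
            g.create_dataset("mixtures",
                             data=np.stack([r.mixture.intensities for r in records]))
            g.create_dataset("truths",
                             data=np.stack([r.truth.intensities for r in records]))
            coeffs = np.full((len(records), 3), np.nan)
            for i, r in enumerate(records):
                coeffs[i, :len(r.coefficients)] = r.coefficients
            g.create_dataset("coefficients", data=coeffs)
            g.create_dataset("provenance", data=np.array(
                [r.provenance for r in records], dtype="S20"))
            g.create_dataset("record_id", data=np.array(
                [r.record_id for r in records], dtype=np.int64))
            g.create_dataset("concentration", data=np.array(
                [np.nan if r.concentration is None else r.concentration
                 for r in records]))


def load_dataset(path: str | Path) -> DatasetSplits:
    """Read splits back from :func:`save_dataset` output.  The stored
    per-record noise draws are not retained in the container."""
    out: dict[str, list[MixtureRecord]] = {}
    with h5py.File(path, "r") as f:
        seed = int(f.attrs["seed"])
        for name in _SPLITS:
            g = f[name]
            records: list[MixtureRecord] = []
            if "mixtures" in g:
                w = g["wavenumbers"][...]
                mixtures = g["mixtures"][...]
                truths = g["truths"][...]
                coeffs = g["coefficients"][...]
                prov = [p.decode() for p in g["provenance"][...]]
                rec_id = g["record_id"][...]
                conc = g["concentration"][...]
                for i in range(mixtures.shape[0]):
                    c = tuple(float(v) for v in coeffs[i] if np.isfinite(v))
                    records.append(MixtureRecord(
                        mixture=RamanSpectrum(w, mixtures[i]),
                        truth=RamanSpectrum(w, truths[i]),
                        coefficients=c,
                        provenance=prov[i],
                        record_id=int(rec_id[i]),
                        concentration=None if np.isnan(conc[i]) else float(conc[i]),
                    ))
            out[name] = records
    return DatasetSplits(train=out["train"], validation=out["validation"],
                         test=out["test"], seed=seed)
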