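"""Similarity metrics and model evaluation reports.

Two metrics quantify how well a demultiplexed spectrum matches its ground
truth: the zero-lag normalized cross-correlation

    R = sum((x_i - xbar)(y_i - ybar)) /
        sqrt(sum((x_i - xbar)^2) * sum((y_i - ybar)^2))

(a Pearson-type coefficient in [-1, 1]) and the mean absolute error over the
spectrum's sampling points, computed in the [-1, 1]-normalized space the
models operate in.  Aggregates are reported as mean +/- sample standard
deviation (ddof = 1).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ComparabilityError, DegenerateInputError
from .simulate import MixtureRecord
from .spectra import normalize_symmetric

__all__ = ["cross_correlation", "mae", "EvalReport", "evaluate",
           "compare_models", "records_to_arrays"]

logger = logging.getLogger(__name__)


def cross_correlation(pred: np.ndarray, truth: np.ndarray) -> float:
    """Zero-lag normalized cross-correlation between two equal-length signals.

    Invariant under positive affine rescaling of either argument; sign flips
    under negation.  Raises on zero-variance input rather than returning a
    silent 0.
    """
    x = np.asarray(pred, dtype=float)
    y = np.asarray(truth, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx @ dx) * (dy @ dy))
    if denom == 0.0:
        raise DegenerateInputError("zero-variance input; correlation undefined")
    return float(np.clip((dx @ dy) / denom, -1.0, 1.0))


def mae(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute difference over all sampling points."""
    x = np.asarray(pred, dtype=float)
    y = np.asarray(truth, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(np.mean(np.abs(y - x)))


def records_to_arrays(records: list[MixtureRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Normalize records for the models: each mixture is min-max mapped onto
    [-1, 1] and the identical affine map is applied to its ground truth, so
    the pair shares one scale and the MAE in normalized units is meaningful.

    Returns (X, Y) arrays of shape (n_records, n_points).
    """
    xs, ys = [], []
    for r in records:
        norm_mix, rec = normalize_symmetric(r.mixture)
        xs.append(norm_mix.intensities)
        ys.append(rec.apply(r.truth.intensities))
    return np.stack(xs), np.stack(ys)


def _test_set_hash(records: list[MixtureRecord]) -> str:
    h = hashlib.sha256()
    for r in records:
        h.update(np.ascontiguousarray(r.mixture.intensities).tobytes())
        h.update(np.ascontiguousarray(r.truth.intensities).tobytes())
    return h.hexdigest()


@dataclass
class EvalReport:
    """Per-record and aggregate metrics for one model on one test set."""

    model_id: str
    cross_correlations: np.ndarray
    maes: np.ndarray
    test_set_hash: str
    n_excluded: int = 0

    @property
    def n_records(self) -> int:
        return int(self.cross_correlations.size)

    @property
    def mean_cross_correlation(self) -> float:
        return float(self.cross_correlations.mean())

    @property
    def std_cross_correlation(self) -> float:
        return float(self.cross_correlations.std(ddof=1))

    @property
    def mean_mae(self) -> float:
        return float(self.maes.mean())

    @property
    def std_mae(self) -> float:
        return float(self.maes.std(ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": self.model_id,
            "cross_correlation": self.cross_correlations,
            "mae": self.maes,
        })

    def summary(self) -> str:
        return (f"{self.model_id}: cross-correlation "
                f"{self.mean_cross_correlation:.4f} +/- {self.std_cross_correlation:.4f}, "
                f"MAE {self.mean_mae:.4f} +/- {self.std_mae:.4f} "
                f"(n={self.n_records})")


def evaluate(model, records: list[MixtureRecord], model_id: str | None = None) -> EvalReport:
    """Run a fitted demultiplexer over a test set and score every record.

    ``model`` is anything with a ``predict(X) -> Y`` method operating on
    [-1, 1]-normalized arrays.  Records whose normalized truth has zero
    variance are excluded with a logged warning and counted in the report.
    """
    if not records:
        raise ValueError("empty test set")
    X, Y = records_to_arrays(records)
    pred = np.asarray(model.predict(X))
    ccs, maes_, excluded = [], [], 0
    for i in range(X.shape[0]):
        try:
            ccs.append(cross_correlation(pred[i], Y[i]))
        except DegenerateInputError:
            logger.warning("record %d excluded: zero-variance spectrum", i)
            excluded += 1
            continue
        maes_.append(mae(pred[i], Y[i]))
    return EvalReport(
        model_id=model_id or getattr(model, "model_id", type(model).__name__),
        cross_correlations=np.array(ccs),
        maes=np.array(maes_),
        test_set_hash=_test_set_hash(records),
        n_excluded=excluded,
    )


def compare_models(reports: list[EvalReport]) -> pd.DataFrame:
    """Tabulate several reports on one test set, best correlation first."""
    if not reports:
        raise ValueError("need at least one report")
    hashes = {r.test_set_hash for r in reports}
    if len(hashes) > 1:
        raise ComparabilityError(
            f"reports cover {len(hashes)} different test sets; cannot compare"
        )
    rows = [{
        "model": r.model_id,
        "mean_cross_correlation": r.mean_cross_correlation,
        "std_cross_correlation": r.std_cross_correlation,
        "mean_mae": r.mean_mae,
        "std_mae": r.std_mae,
        "n": r.n_records,
    } for r in reports]
    df = pd.DataFrame(rows).sort_values(
        "mean_cross_correlation", ascending=False, ignore_index=True
    )
    return df
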