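"""Dilution removal by probabilistic quotient normalization (PQN) and
unit-variance scaling for multivariate modelling.

Urine concentration varies several-fold between voids for purely osmotic
reasons; PQN estimates each sample's dilution as the median ratio of its
spectrum to a reference (median) spectrum and divides it out.  Unit-variance
scaling then gives every bucket equal weight in the model regardless of its
absolute intensity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import BucketTable

logger = logging.getLogger(__name__)

_SD_TOL = 1e-12


@dataclass
class DilutionEstimates:
    """Per-sample dilution factors recovered by PQN.

    ``factors`` is the overall multiplicative factor divided out of each raw
    row, i.e. the median of (raw row / reference spectrum); it decomposes as
    ``integral_factors * quotient_medians`` where the first term is the
    row-total / cohort-mean-total ratio of the initial integral
    normalization and the second is the quotient median computed after it.
    """

    sample_ids: list[str]
    factors: np.ndarray
    integral_factors: np.ndarray
    quotient_medians: np.ndarray

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "sample_ids": self.sample_ids,
                    "factors": self.factors.tolist(),
                    "integral_factors": self.integral_factors.tolist(),
                    "quotient_medians": self.quotient_medians.tolist(),
                }
            )
        )


def pqn_normalize(table: BucketTable) -> tuple[BucketTable, DilutionEstimates]:
    """Probabilistic quotient normalization of a bucket table.

    Steps: (1) integral-normalize each row to the cohort-mean total
    intensity; (2) reference = element-wise median spectrum of the
    normalized rows; (3) per-sample quotients x_ij / ref_j over buckets with
    ref_j > 0; (4) d_i = median of the quotients; (5) divide row i by d_i.
    Small negative bucket values (noise) are tolerated.
    """
    if table.n_samples < 2:
        raise ValueError("PQN needs at least 2 samples")
    V = table.values
    totals = V.sum(axis=1)
    if np.any(totals <= 0):
        bad = table.sample_ids[int(np.argmin(totals))]
        raise ValueError(f"sample {bad!r} has non-positive total intensity")
    mean_total = totals.mean()
    integral_factors = totals / mean_total
    Vn = V / integral_factors[:, None]

    ref = np.median(Vn, axis=0)
    positive = ref > 0
    if not positive.any():
        raise ValueError("reference (median) spectrum is entirely non-positive")
    quotients = Vn[:, positive] / ref[positive]
    d = np.median(quotients, axis=1)
    if np.any(d <= 0):
        bad = table.sample_ids[int(np.argmin(d))]
        raise ValueError(f"sample {bad!r} has non-positive quotient median")

    out = table.copy()
    out.values = Vn / d[:, None]
    est = DilutionEstimates(
        list(table.sample_ids), integral_factors * d, integral_factors, d
    )
    return out, est


@dataclass
class ScalingModel:
    """Per-bucket mean and standard deviation (n-1 denominator) fitted on a
    training table; columns with zero variance are dropped on application."""

    means: np.ndarray
    sds: np.ndarray
    kept: np.ndarray  # boolean mask over the fitted table's buckets

    def apply(self, table: BucketTable) -> BucketTable:
        if table.n_buckets != len(self.means):
            raise ValueError("table does not match the fitted bucket set")
        out = table.select_buckets(self.kept)
        out.values = (out.values - self.means[self.kept]) / self.sds[self.kept]
        return out

    def inverse(self, values: np.ndarray) -> np.ndarray:
        """Map scaled values (over retained buckets) back to original units."""
        return values * self.sds[self.kept] + self.means[self.kept]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "means": self.means.tolist(),
                    "sds": self.sds.tolist(),
                    "kept": self.kept.astype(int).tolist(),
                }
            )
        )


def uv_scale(table: BucketTable) -> tuple[BucketTable, ScalingModel]:
    """Mean-centre each bucket and divide by its standard deviation.

    Zero-variance buckets carry no between-sample information and cannot be
    put on unit variance; they are dropped with a logged warning.
    """
    if table.n_samples < 2:
        raise ValueError("unit-variance scaling needs at least 2 samples")
    means = table.values.mean(axis=0)
    sds = table.values.std(axis=0, ddof=1)
    kept = sds > _SD_TOL
    if not kept.all():
        logger.warning(
            "dropping %d zero-variance bucket(s) at %s ppm",
            int((~kept).sum()),
            ", ".join(f"{c:.3f}" for c in table.centers[~kept][:5]),
        )
    model = ScalingModel(means, np.where(kept, sds, 1.0), kept)
    return model.apply(table), model
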