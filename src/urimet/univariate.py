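"""Confirmatory per-metabolite analysis: variable-size bucket integration
over named ppm windows, Mann-Whitney U tests and percent-variation summaries.

These tests run on PQN-normalized but *unscaled* intensities — unit-variance
scaling is a modelling device, whereas integrated intensities in arbitrary
units are what a per-metabolite table reports.  No multiple-testing
correction is applied by default (raw two-sided p < 0.05); Benjamini-
Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import BucketTable
from .regions import MetaboliteRegion

logger = logging.getLogger(__name__)


def integrate_region(table: BucketTable, region: MetaboliteRegion) -> np.ndarray:
    """Per-sample integral of bucket values over a ppm window.

    Buckets partially covered by the window contribute in proportion to the
    overlapped fraction of their width.
    """
    lo, hi = region.window
    for r_lo, r_hi in table.excluded_regions:
        if lo >= r_lo and hi <= r_hi:
            raise ValueError(
                f"region {region.name!r} ({lo}-{hi} ppm) lies inside the "
                f"excluded region ({r_lo}, {r_hi})"
            )
    overlap = np.minimum(table.edges[:, 1], hi) - np.maximum(table.edges[:, 0], lo)
    weights = np.clip(overlap, 0.0, None) / (table.edges[:, 1] - table.edges[:, 0])
    if not (weights > 0).any():
        raise ValueError(f"region {region.name!r} overlaps no bucket")
    return table.values @ weights


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when the combined sample size is ≤ 20 and there
    are no ties; otherwise the normal approximation with tie and continuity
    corrections.  Returns (U of the first sample, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def percent_variation(mean_reference: float, mean_case: float) -> float:
    """Percent change of the case-group mean relative to the reference mean."""
    if mean_reference == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (mean_case - mean_reference) / mean_reference


@dataclass
class RegionResult:
    """One row of the per-metabolite summary table."""

    name: str
    window: tuple[float, float]
    mean_reference: float
    sem_reference: float
    mean_case: float
    sem_case: float
    u_statistic: float
    p_value: float
    percent_variation: float
    significant: bool
    p_adjusted: float | None = None


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def build_table(
    table: BucketTable,
    regions: list[MetaboliteRegion],
    reference_group: str,
    case_group: str,
    alpha: float = 0.05,
    adjust: bool = False,
) -> list[RegionResult]:
    """Integrate each region, test case vs reference, summarise.

    Rows are sorted by window position (ascending ppm).  With ``adjust``
    the significance flag uses Benjamini-Hochberg adjusted p-values; the
    default mirrors a raw p < alpha rule, which over a list of regions does
    not control the family-wise error rate.
    """
    if table.groups is None:
        raise ValueError("bucket table carries no group labels")
    groups = np.asarray(table.groups)
    ref_mask = groups == reference_group
    case_mask = groups == case_group
    if ref_mask.sum() < 2 or case_mask.sum() < 2:
        raise ValueError("both groups need at least 2 samples")

    rows = []
    for region in sorted(regions, key=lambda r: r.window[0]):
        values = integrate_region(table, region)
        ref_v, case_v = values[ref_mask], values[case_mask]
        u, p = mann_whitney(ref_v, case_v)
        rows.append(
            RegionResult(
                name=region.name,
                window=region.window,
                mean_reference=float(ref_v.mean()),
                sem_reference=_sem(ref_v),
                mean_case=float(case_v.mean()),
                sem_case=_sem(case_v),
                u_statistic=u,
                p_value=p,
                percent_variation=percent_variation(float(ref_v.mean()), float(case_v.mean())),
                significant=p < alpha,
            )
        )
    if adjust:
        logger.info("applying Benjamini-Hochberg adjustment over %d regions", len(rows))
        p_adj = _benjamini_hochberg(np.array([r.p_value for r in rows]))
        for r, pa in zip(rows, p_adj):
            r.p_adjusted = float(pa)
            r.significant = pa < alpha
    return rows


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out
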