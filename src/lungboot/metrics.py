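"""Summary statistics over masked maps.

Quartiles use Tukey hinges (medians of the lower/upper halves of the sorted
sample, the halves sharing the middle value for odd n) — the convention that
reproduces the published precision figures of the repeatability study from
their printed per-scan inputs; linear-interpolation quantiles do not.

precision of the median error
    IQR over scans of the per-scan median bootstrap errors in the lung.
accuracy of the median error
    Median over scans of (GSE median - per-scan bootstrap median); the sign is
    retained (positive = bootstrap underestimates the repeated-measurement
    error).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def tukey_hinges(values) -> tuple[float, float, float]:
    """(Q1, median, Q3) by the median-of-halves rule."""
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    med = float(np.median(x))
    if n == 1:
        return med, med, med
    half = (n + 1) // 2  # odd n: halves include the median
    q1 = float(np.median(x[:half]))
    q3 = float(np.median(x[n - half:]))
    return q1, med, q3


def median_iqr(values) -> tuple[float, float]:
    q1, med, q3 = tukey_hinges(values)
    return med, q3 - q1


def _masked(values, mask) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(values, dtype=float)[mask]
    return vals[np.isfinite(vals)]


def masked_median_iqr(map_or_values, mask) -> tuple[float, float]:
    """Median and Tukey-hinge IQR of a map restricted to ``mask``.

    Accepts a ParamMap/ErrorMap (uses ``.values``) or a bare array; non-finite
    (invalid) voxels inside the mask are dropped.
    """
    values = getattr(map_or_values, "values", map_or_values)
    vals = _masked(values, mask)
    if vals.size == 0:
        raise ValueError("no finite values under the mask")
    return median_iqr(vals)


@dataclass
class CDFCurve:
    """Empirical cumulative distribution of masked map values."""

    sorted_values: np.ndarray
    cum_fraction: np.ndarray

    def value_at(self, fraction: float) -> float:
        """Smallest value whose cumulative fraction reaches ``fraction``."""
        i = int(np.searchsorted(self.cum_fraction, fraction, side="left"))
        i = min(i, self.sorted_values.size - 1)
        return float(self.sorted_values[i])


def error_cdf(error_map, mask) -> CDFCurve:
    """Empirical CDF of an error (or parameter) map over ``mask``."""
    vals = _masked(getattr(error_map, "values", error_map), mask)
    if vals.size == 0:
        raise ValueError("no finite values under the mask")
    x = np.sort(vals)
    frac = np.arange(1, x.size + 1, dtype=float) / x.size
    return CDFCurve(sorted_values=x, cum_fraction=frac)


def precision_of_median(median_errors) -> float:
    """IQR (Tukey hinges) of per-scan median errors."""
    vals = np.asarray(median_errors, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 per-scan medians")
    q1, _, q3 = tukey_hinges(vals)
    return q3 - q1


def accuracy_of_median(gse_median: float, boot_medians) -> float:
    """Median over scans of (GSE median - bootstrap median); sign retained."""
    vals = np.asarray(boot_medians, dtype=float)
    if vals.size < 1:
        raise ValueError("need at least 1 bootstrap median")
    return float(np.median(gse_median - vals))


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (away from zero), as in printed report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
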