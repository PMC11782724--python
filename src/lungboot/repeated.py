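"""Gold-standard repeated-measurement errors and the breathing-depth rule.

The gold-standard error (GSE) is the per-voxel sample SD of a functional map
across registered repeated scans of the same subject — the experimental
reference against which bootstrap error maps are validated.  Because the
ventilation estimate depends on breathing depth, scans whose depth falls
strictly outside mean +/- SD of the set are excluded before computing the GSE.

Breathing depth is the relative change in 2D lung area between expiration and
inspiration, ``100 * (A_max - A_min) / A_max`` in percent (expiration area as
the denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boot import ErrorMap
from .cine import RESPIRATORY, CineSeries
from .funcmaps import ParamMap


@dataclass
class DepthSummary:
    """Per-scan breathing depths with the mean +/- SD inclusion rule."""

    depths: np.ndarray          # percent
    mean: float
    sd: float
    lower_bound: float
    upper_bound: float
    included: np.ndarray        # boolean per scan

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    @property
    def gse_defined(self) -> bool:
        """At least two scans remain: the SD over scans exists."""
        return self.n_included >= 2


def breathing_depth(
    resp_series: CineSeries, lung_areas_per_phase=None
) -> float:
    """Breathing depth in percent from per-phase lung areas.

    Areas may be passed explicitly (real data: from per-phase segmentations)
    or carried by the series (phantom data fill ``lung_area_per_phase``).
    """
    if resp_series.cycle_kind != RESPIRATORY:
        raise ValueError("breathing depth requires a respiratory series")
    areas = (
        np.asarray(lung_areas_per_phase, dtype=float)
        if lung_areas_per_phase is not None
        else resp_series.lung_area_per_phase
    )
    if areas is None:
        raise ValueError("no per-phase lung areas available")
    a_max = float(areas.max())
    a_min = float(areas.min())
    if a_max <= 0:
        raise ValueError("maximal lung area must be positive")
    return 100.0 * (a_max - a_min) / a_max


def depth_bounds(mean: float, sd: float) -> tuple[float, float]:
    """The inclusion interval [mean - SD, mean + SD] of the depth rule."""
    return mean - sd, mean + sd


def select_scans(depths) -> DepthSummary:
    """Apply the mean +/- SD breathing-depth exclusion rule.

    Mean and SD (ddof=1) are taken over all scans; a scan is included iff its
    depth lies in the closed interval [mean - SD, mean + SD] (only strictly
    outlying depths are excluded).
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size < 2:
        raise ValueError("need at least 2 depths")
    mean = float(depths.mean())
    sd = float(depths.std(ddof=1))
    lo, hi = depth_bounds(mean, sd)
    included = (depths >= lo) & (depths <= hi)
    return DepthSummary(
        depths=depths,
        mean=mean,
        sd=sd,
        lower_bound=lo,
        upper_bound=hi,
        included=included,
    )


def gold_standard_error(map_stack: list[ParamMap]) -> ErrorMap:
    """Per-voxel sample SD across repeated-scan maps (ddof=1).

    Maps must be pre-registered (phantom maps are aligned by construction),
    of identical shape and kind.  A voxel invalid in any scan is NaN in the
    GSE and excluded from its validity mask.
    """
    if len(map_stack) < 2:
        raise ValueError("need at least 2 maps for a repeated-measurement SD")
    kinds = {m.kind for m in map_stack}
    if len(kinds) > 1:
        raise ValueError(f"mixed map kinds: {sorted(kinds)}")
    shapes = {m.values.shape for m in map_stack}
    if len(shapes) > 1:
        raise ValueError("maps have differing shapes")
    stack = np.stack([m.values for m in map_stack])
    sd = stack.std(axis=0, ddof=1)
    return ErrorMap(
        values=sd,
        kind=map_stack[0].kind,
        B_used=len(map_stack),
        seed=-1,
        mean_map=stack.mean(axis=0),
        meta={"source": "repeated-measurements"},
    )
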