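"""Bootstrapping residuals: voxel-wise statistical error maps from one scan.

The procedure (per cine series):

1. fit the first-harmonic model voxel-wise,
2. compute residuals = data - model,
3. randomly shuffle each voxel's residuals along the phase axis and add them
   back to the model, creating a synthetic series,
4. recompute the functional parameter map from the synthetic series,

repeat steps 3-4 ``B`` times (default 2000) and reduce the stack to the
per-voxel sample SD — the bootstrap error map.  Re-running the whole error-map
computation ``R`` times (default 1000) yields the per-voxel width of the 95%
confidence interval of the error, a reproducibility measure for the choice of
``B``.

Shuffling defaults to independent per-voxel permutations (``shuffle_mode=
"per-voxel"``); one shared permutation for all voxels (``"shared"``) preserves
spatial noise correlation.  ``sampling="permutation"`` (default) shuffles
without replacement; ``"with-replacement"`` is classical residual resampling.

In permutation mode the multiset of residuals per voxel is preserved, so the
temporal mean of every synthetic series equals the original ``a0`` exactly and
all bootstrap variation enters through ``c1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from ._seeds import STREAM_BOOT, STREAM_CI, child_seed, rng_for
from .cine import CineSeries
from .funcmaps import CYCLE_FOR_KIND, MAP_KINDS, compute_map
from .harmonic import (
    HarmonicFitResults,
    ResidualSeries,
    compute_residuals,
    fit_first_harmonic,
)

PER_VOXEL = "per-voxel"
SHARED = "shared"
PERMUTATION = "permutation"
WITH_REPLACEMENT = "with-replacement"


@dataclass(frozen=True)
class BootConfig:
    """Bootstrap parameters.

    B = 2000 shuffles per error map and R = 1000 error-map re-computations for
    the CI are the defaults of the underlying protocol; ``sd_ddof=1`` uses the
    sample SD over the stack.
    """

    B: int = 2000
    R: int = 1000
    shuffle_mode: str = PER_VOXEL
    sampling: str = PERMUTATION
    seed: int = 0
    sd_ddof: int = 1

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if self.shuffle_mode not in (PER_VOXEL, SHARED):
            raise ValueError(f"unknown shuffle_mode: {self.shuffle_mode!r}")
        if self.sampling not in (PERMUTATION, WITH_REPLACEMENT):
            raise ValueError(f"unknown sampling: {self.sampling!r}")
        if self.sd_ddof not in (0, 1):
            raise ValueError("sd_ddof must be 0 or 1")


@dataclass
class ErrorMap:
    """Per-voxel SD of a functional parameter over bootstrap replicates.

    ``mean_map`` is the stack summary (per-voxel mean of the bootstrap maps).
    Values are >= 0 wherever finite; voxels that are invalid in the underlying
    parameter map (e.g. non-positive expiration signal) propagate NaN.
    """

    values: np.ndarray
    kind: str
    B_used: int
    seed: int
    mean_map: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)


@dataclass
class CIWidthMap:
    """Width of the 95% CI of the bootstrap error, per voxel."""

    values: np.ndarray
    kind: str
    R_used: int
    B_used: int
    seed: int


def _shuffle_indices(rng, shape, mode: str, sampling: str) -> np.ndarray:
    """Phase-axis resampling indices of ``shape`` (rows, cols, N)."""
    n = shape[-1]
    if sampling == PERMUTATION:
        if mode == PER_VOXEL:
            return np.argsort(rng.random(shape), axis=-1)
        perm = rng.permutation(n)
        return np.broadcast_to(perm, shape)
    if mode == PER_VOXEL:
        return rng.integers(0, n, size=shape)
    draw = rng.integers(0, n, size=n)
    return np.broadcast_to(draw, shape)


def shuffle_residuals(
    res: ResidualSeries,
    seed: int = 0,
    mode: str = PER_VOXEL,
    sampling: str = PERMUTATION,
) -> ResidualSeries:
    """Step 3 in isolation: resample each voxel's residuals along the phase axis."""
    if mode not in (PER_VOXEL, SHARED):
        raise ValueError(f"unknown mode: {mode!r}")
    if sampling not in (PERMUTATION, WITH_REPLACEMENT):
        raise ValueError(f"unknown sampling: {sampling!r}")
    rng = rng_for(seed, STREAM_BOOT, 0)
    idx = _shuffle_indices(rng, res.data.shape, mode, sampling)
    data = np.take_along_axis(res.data, idx, axis=-1)
    return ResidualSeries(
        data=data, source_fingerprint=res.source_fingerprint, cycle_kind=res.cycle_kind
    )


def _check_kinds(series: CineSeries, kinds: Iterable[str], roi) -> list[str]:
    kinds = list(kinds)
    for kind in kinds:
        if kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind: {kind!r}")
        if CYCLE_FOR_KIND[kind] != series.cycle_kind:
            raise ValueError(
                f"{kind} map incompatible with a {series.cycle_kind} series"
            )
        if kind != "ventilation" and roi is None:
            raise ValueError(f"{kind} requires an aorta ROI")
    return kinds


def bootstrap_error_maps(
    series: CineSeries,
    kinds: Iterable[str],
    roi=None,
    cfg: BootConfig | None = None,
    return_stack: bool = False,
) -> dict[str, ErrorMap]:
    """Bootstrap error maps for one or several map kinds of one series.

    All requested kinds share the same shuffles (one pass over the B
    replicates), exactly as a sequential computation with the same seed would.
    Statistics are accumulated streaming (per-voxel running sums), which is
    identical to the stored-stack computation up to float round-off;
    ``return_stack=True`` additionally stores the full stack (for tests and
    small problems).
    """
    cfg = cfg or BootConfig()
    kinds = _check_kinds(series, kinds, roi)
    fit = fit_first_harmonic(series)
    resid = compute_residuals(series, fit).data
    n = series.n_phases
    # first-harmonic weights: c1 contribution of an arbitrary real series
    w = (2.0 / n) * np.exp(-2j * np.pi * np.arange(n) / n)

    # accumulate deviations from the original-fit map: numerically stable
    # streaming variance even when the bootstrap spread is ~eps * mean
    ref = {k: compute_map(fit, k, roi=roi).values for k in kinds}
    acc_sum = {k: np.zeros(fit.a0.shape) for k in kinds}
    acc_sq = {k: np.zeros(fit.a0.shape) for k in kinds}
    stacks = {k: [] for k in kinds} if return_stack else None

    for b in range(cfg.B):
        rng = rng_for(cfg.seed, STREAM_BOOT, b)
        idx = _shuffle_indices(rng, resid.shape, cfg.shuffle_mode, cfg.sampling)
        shuf = np.take_along_axis(resid, idx, axis=-1)
        if cfg.sampling == PERMUTATION:
            a0_b = fit.a0  # multiset preserved: temporal mean conserved exactly
        else:
            a0_b = fit.a0 + shuf.mean(axis=-1)
        c1_b = fit.c1 + np.tensordot(shuf, w, axes=([-1], [0]))
        fit_b = HarmonicFitResults(
            a0=a0_b,
            c1=c1_b,
            n_phases=n,
            cycle_kind=series.cycle_kind,
            cycle_duration_ms=series.cycle_duration_ms,
            n_avg=series.n_avg,
        )
        for kind in kinds:
            vals = compute_map(fit_b, kind, roi=roi).values
            dev = vals - ref[kind]
            acc_sum[kind] += dev
            acc_sq[kind] += dev * dev
            if return_stack:
                stacks[kind].append(vals)

    out = {}
    for kind in kinds:
        dev_mean = acc_sum[kind] / cfg.B
        mean = ref[kind] + dev_mean
        var = (acc_sq[kind] - cfg.B * dev_mean * dev_mean) / (cfg.B - cfg.sd_ddof)
        with np.errstate(invalid="ignore"):
            sd = np.sqrt(np.maximum(var, 0.0))
            sd = np.where(np.isnan(var), np.nan, sd)
        out[kind] = ErrorMap(
            values=sd,
            kind=kind,
            B_used=cfg.B,
            seed=cfg.seed,
            mean_map=mean,
            meta={
                "shuffle_mode": cfg.shuffle_mode,
                "sampling": cfg.sampling,
                "sd_ddof": cfg.sd_ddof,
            },
        )
        if return_stack:
            out[kind].meta["stack"] = np.stack(stacks[kind])
    return out


def bootstrap_error_map(
    series: CineSeries,
    map_kind: str,
    roi=None,
    cfg: BootConfig | None = None,
    return_stack: bool = False,
) -> ErrorMap:
    """Bootstrap error map for a single map kind (steps 1-4, B replicates)."""
    return bootstrap_error_maps(
        series, [map_kind], roi=roi, cfg=cfg, return_stack=return_stack
    )[map_kind]


def error_map_ci(
    series: CineSeries,
    map_kind: str,
    roi=None,
    cfg: BootConfig | None = None,
) -> CIWidthMap:
    """Reproducibility of the error map: 95% CI width over R re-computations.

    Runs the full bootstrap ``R`` times with independent sub-seeds and takes
    the per-voxel 97.5th minus 2.5th percentile of the R error values.
    """
    cfg = cfg or BootConfig()
    if cfg.R < 2:
        raise ValueError("R must be >= 2")
    errs = []
    for r in range(cfg.R):
        cfg_r = replace(cfg, seed=child_seed(cfg.seed, STREAM_CI, r))
        errs.append(bootstrap_error_map(series, map_kind, roi=roi, cfg=cfg_r).values)
    stack = np.stack(errs)
    with warnings.catch_warnings():
        # voxels invalid in every replicate (e.g. no signal) stay NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        lo, hi = np.nanpercentile(stack, [2.5, 97.5], axis=0)
    return CIWidthMap(
        values=hi - lo, kind=map_kind, R_used=cfg.R, B_used=cfg.B, seed=cfg.seed
    )
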