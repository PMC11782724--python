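"""Digital cine phantom with known ground truth.

The phantom emulates the statistical structure of self-gated functional lung
data: every voxel follows a DC + first-harmonic time course, with additive
white Gaussian noise whose SD scales as ``1/sqrt(n_avg)`` (the high-SNR
approximation to magnitude noise).  Geometry is two half-elliptical lungs, a
circular blood-filled aorta ROI between them, inside an elliptical body.

Ground-truth fields are calibrated so that the lung medians match typical
healthy values: ventilation 0.22 mL air/mL parenchyma, perfusion amplitude
0.028 of the reference-blood signal, perfusion timing -82 ms.

Ventilation-to-modulation mapping: a voxel with ventilation v modulates as
``a0 * (1 + m cos(2 pi t / N))`` with ``m = v / (2 - v)``, which makes
``(S_exp - S_ins) / S_exp = v`` exact, so the downstream map formula recovers
the ground truth identically in the noiseless limit.

``depth_scale`` is a dimensionless breathing-depth multiplier: it scales the
ventilation modulation of every lung voxel and the lung-area excursion over
the cycle.  ``depth_scale = 1`` corresponds to the phantom's nominal breathing
depth (default 24.3% area change between expiration and inspiration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from ._seeds import (
    STREAM_CARD,
    STREAM_DEPTHS,
    STREAM_PHANTOM,
    STREAM_RESP,
    rng_for,
    seed_sequence,
)
from .cine import CARDIAC, RESPIRATORY, CineSeries

log = logging.getLogger(__name__)

SeedLike = Union[int, np.random.SeedSequence]


def _wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into [-pi, pi)."""
    return (np.asarray(phi) + np.pi) % (2.0 * np.pi) - np.pi


@dataclass(frozen=True)
class PhantomConfig:
    """Tunable phantom parameters (defaults = the study conditions)."""

    grid_shape: tuple[int, int] = (64, 64)
    vent_median: float = 0.22        # mL air / mL parenchyma, lung median
    vent_scale: float = 1.0          # overall ventilation multiplier (0 => no vent)
    perf_amp_median: float = 0.028   # fraction of reference-blood signal
    perf_timing_median_ms: float = -82.0
    breathing_depth_frac: float = 0.243   # lung-area change at depth_scale = 1
    cycle_duration_resp_ms: float = 4000.0
    cycle_duration_card_ms: float = 1000.0  # T_RR
    noise_sigma: float = 0.025       # SD of one un-averaged sample, signal units
    baseline_lung: float = 0.4       # parenchyma DC level (low proton density)
    baseline_body: float = 1.0
    baseline_aorta: float = 3.0      # fully blood-filled reference
    aorta_pulse_amp: float = 0.10    # aorta first-harmonic amplitude / S_ref
    vent_log_sd: float = 0.25        # spatial heterogeneity of ventilation
    perf_log_sd: float = 0.35
    phase_sd: float = 0.30           # radians, spatial spread of perfusion phase
    field_smooth_frac: float = 1 / 16.0  # Gaussian kernel, fraction of grid


@dataclass
class Phantom:
    """Ground-truth parameter fields plus masks."""

    config: PhantomConfig
    seed: int
    lung_mask: np.ndarray
    aorta_roi: np.ndarray
    body_mask: np.ndarray
    baseline_signal: np.ndarray
    vent_true: np.ndarray
    perf_amp_true: np.ndarray
    perf_phase_true: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.lung_mask.shape

    @property
    def cycle_duration_resp_ms(self) -> float:
        return self.config.cycle_duration_resp_ms

    @property
    def cycle_duration_card_ms(self) -> float:
        return self.config.cycle_duration_card_ms

    @property
    def noise_sigma(self) -> float:
        return self.config.noise_sigma

    @property
    def s_ref_true(self) -> float:
        """Ground-truth reference (aorta) DC signal level."""
        return float(self.baseline_signal[self.aorta_roi].mean())

    @property
    def timing_true_ms(self) -> np.ndarray:
        """Ground-truth perfusion timing implied by the phase field (ms)."""
        t_rr = self.config.cycle_duration_card_ms
        return _wrap_phase(self.perf_phase_true) / (2.0 * np.pi) * t_rr

    def validate(self) -> None:
        if not self.lung_mask.any():
            raise ValueError("empty lung mask")
        if (self.lung_mask & self.aorta_roi).any():
            raise ValueError("lung mask and aorta ROI must be disjoint")
        for m in (self.lung_mask, self.aorta_roi):
            if (m & ~self.body_mask).any():
                raise ValueError("masks must be subsets of the body mask")
        if not (self.baseline_signal[self.body_mask] > 0).all():
            raise ValueError("baseline must be positive inside the body")
        if (self.baseline_signal[~self.body_mask] != 0).any():
            raise ValueError("baseline must be zero outside the body")
        v = self.vent_true
        if (v[self.lung_mask] < 0).any() or (v[self.lung_mask] >= 1).any():
            raise ValueError("vent_true must be in [0, 1) inside the lung")
        if (v[~self.lung_mask] != 0).any():
            raise ValueError("vent_true must be zero outside the lung")
        if (self.perf_amp_true < 0).any():
            raise ValueError("perf_amp_true must be non-negative")


def _ellipse(shape, center, semi) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def _smooth_field(rng, shape, smooth_frac, ref_mask) -> np.ndarray:
    """Unit-SD smooth Gaussian random field with median 0 over ``ref_mask``."""
    g = ndimage.gaussian_filter(
        rng.standard_normal(shape), sigma=max(1.0, smooth_frac * min(shape))
    )
    g = g / g.std()
    return g - np.median(g[ref_mask])


def make_phantom(config: PhantomConfig | None = None, seed: int = 0) -> Phantom:
    """Build a phantom with calibrated ground truth; deterministic per seed."""
    cfg = config or PhantomConfig()
    rows, cols = cfg.grid_shape
    if rows < 32 or cols < 32:
        raise ValueError(
            f"grid {cfg.grid_shape} too small for the default lung/aorta "
            "geometry; need at least 32x32"
        )
    shape = (rows, cols)
    rng = rng_for(seed, STREAM_PHANTOM)

    body = _ellipse(shape, (0.50 * rows, 0.50 * cols), (0.42 * rows, 0.40 * cols))
    diaphragm = np.arange(rows)[:, None] < 0.78 * rows  # flat-bottomed lungs
    lung_l = _ellipse(shape, (0.48 * rows, 0.30 * cols), (0.30 * rows, 0.16 * cols))
    lung_r = _ellipse(shape, (0.48 * rows, 0.70 * cols), (0.30 * rows, 0.16 * cols))
    lung = (lung_l | lung_r) & diaphragm & body
    aorta = _ellipse(
        shape,
        (0.55 * rows, 0.50 * cols),
        (max(2.0, 0.03 * rows), max(2.0, 0.03 * cols)),
    ) & body
    aorta &= ~lung
    if not lung.any() or not aorta.any():
        raise ValueError("grid too small to contain the lung/aorta geometry")

    g_base = _smooth_field(rng, shape, cfg.field_smooth_frac, lung)
    g_vent = _smooth_field(rng, shape, cfg.field_smooth_frac, lung)
    g_perf = _smooth_field(rng, shape, cfg.field_smooth_frac, lung)
    g_phase = _smooth_field(rng, shape, cfg.field_smooth_frac, lung)

    baseline = np.zeros(shape)
    baseline[body] = cfg.baseline_body
    baseline[lung] = cfg.baseline_lung * np.clip(1.0 + 0.10 * g_base[lung], 0.5, 1.5)
    baseline[aorta] = cfg.baseline_aorta

    vent = np.zeros(shape)
    # exp() of a median-centred field: the lung median is vent_median exactly
    # (up to the even-count median average), heterogeneity is log-normal.
    vent[lung] = cfg.vent_scale * cfg.vent_median * np.exp(cfg.vent_log_sd * g_vent[lung])
    vent = np.clip(vent, 0.0, 0.95)

    perf_amp = np.zeros(shape)
    perf_amp[lung] = cfg.perf_amp_median * np.exp(cfg.perf_log_sd * g_perf[lung])
    perf_amp[aorta] = cfg.aorta_pulse_amp

    t_rr = cfg.cycle_duration_card_ms
    phase_center = 2.0 * np.pi * cfg.perf_timing_median_ms / t_rr
    perf_phase = np.zeros(shape)
    perf_phase[lung] = _wrap_phase(phase_center + cfg.phase_sd * g_phase[lung])
    # aorta keeps phase 0: it *is* the timing reference.

    ph = Phantom(
        config=cfg,
        seed=int(seed),
        lung_mask=lung,
        aorta_roi=aorta,
        body_mask=body,
        baseline_signal=baseline,
        vent_true=vent,
        perf_amp_true=perf_amp,
        perf_phase_true=perf_phase,
    )
    ph.validate()
    return ph


def noiseless_cine(
    phantom: Phantom,
    cycle_kind: str,
    n_phases: int = 20,
    depth_scale: float = 1.0,
) -> np.ndarray:
    """The noise-free voxel time courses, shape (rows, cols, n_phases)."""
    if n_phases < 4:
        raise ValueError("need at least 4 phases")
    t = np.arange(n_phases)
    omega_t = 2.0 * np.pi * t / n_phases
    a0 = phantom.baseline_signal[..., None]
    if cycle_kind == RESPIRATORY:
        if depth_scale < 0:
            raise ValueError("depth_scale must be >= 0")
        v = np.clip(phantom.vent_true * depth_scale, 0.0, 0.97)
        m = (v / (2.0 - v))[..., None]
        return a0 * (1.0 + m * np.cos(omega_t))
    if cycle_kind == CARDIAC:
        s_ref = phantom.s_ref_true
        with np.errstate(divide="ignore", invalid="ignore"):
            m = np.where(
                phantom.body_mask,
                phantom.perf_amp_true * s_ref / np.where(phantom.body_mask, phantom.baseline_signal, 1.0),
                0.0,
            )[..., None]
        phi = phantom.perf_phase_true[..., None]
        return a0 * (1.0 + m * np.cos(omega_t + phi))
    raise ValueError(f"unknown cycle_kind: {cycle_kind!r}")


def simulate_cine(
    phantom: Phantom,
    cycle_kind: str,
    n_phases: int = 20,
    n_avg: int = 1,
    depth_scale: float = 1.0,
    seed: SeedLike = 0,
) -> CineSeries:
    """Simulate one cine series: noiseless model + white Gaussian noise.

    Noise SD is ``phantom.noise_sigma / sqrt(n_avg)`` per sample (averaging is
    emulated through the variance rather than by storing replicates).
    """
    if n_avg < 1:
        raise ValueError("n_avg must be >= 1")
    if cycle_kind == CARDIAC and depth_scale != 1.0:
        log.warning("depth_scale ignored for cardiac series")
        depth_scale = 1.0
    clean = noiseless_cine(phantom, cycle_kind, n_phases, depth_scale)
    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
    else:
        stream = STREAM_RESP if cycle_kind == RESPIRATORY else STREAM_CARD
        rng = rng_for(seed, stream)
    sigma = phantom.noise_sigma / np.sqrt(n_avg)
    data = clean + (rng.normal(0.0, sigma, clean.shape) if sigma > 0 else 0.0)

    areas = None
    if cycle_kind == RESPIRATORY:
        a_exp = float(phantom.lung_mask.sum())
        d = phantom.config.breathing_depth_frac * depth_scale
        t = np.arange(n_phases)
        areas = a_exp * (1.0 - d * (1.0 - np.cos(2.0 * np.pi * t / n_phases)) / 2.0)

    duration = (
        phantom.cycle_duration_resp_ms
        if cycle_kind == RESPIRATORY
        else phantom.cycle_duration_card_ms
    )
    return CineSeries(
        data=data,
        cycle_kind=cycle_kind,
        cycle_duration_ms=duration,
        n_avg=n_avg,
        lung_area_per_phase=areas,
        meta={"depth_scale": float(depth_scale), "noise_sigma": phantom.noise_sigma},
    )


def draw_depths(
    rng: np.random.Generator, n: int, depth_mean: float, depth_sd: float
) -> np.ndarray:
    """Per-scan depth scales ~ Gaussian(mean, sd) truncated at 0 (rejection)."""
    if depth_sd < 0:
        raise ValueError("depth_sd must be >= 0")
    if depth_sd == 0:
        return np.full(n, float(depth_mean))
    out = np.empty(n)
    for i in range(n):
        d = rng.normal(depth_mean, depth_sd)
        while d < 0:
            d = rng.normal(depth_mean, depth_sd)
        out[i] = d
    return out


@dataclass
class ScanSet:
    """Simulated repeated scans: aligned (respiratory, cardiac) series pairs."""

    phantom: Phantom
    scans: list[tuple[CineSeries, CineSeries]]
    depths_true: np.ndarray
    seed: int
    n_avg: int

    def __post_init__(self) -> None:
        if len(self.scans) != len(self.depths_true):
            raise ValueError("one depth per scan required")

    @property
    def n_scans(self) -> int:
        return len(self.scans)


def simulate_scan_set(
    phantom: Phantom,
    n_scans: int = 10,
    depth_mean: float = 1.0,
    depth_sd: float = 0.0,
    n_avg: int = 1,
    n_phases: int = 20,
    seed: int = 0,
) -> ScanSet:
    """A set of repeated scans with variable breathing depth.

    Scans are spatially aligned by construction (registration of repeated real
    scans precedes this package and is a no-op for phantom data).  Each scan
    gets independent noise through its own sub-seed.
    """
    if n_scans < 2:
        raise ValueError("need at least 2 scans (SD over scans undefined)")
    depths = draw_depths(rng_for(seed, STREAM_DEPTHS), n_scans, depth_mean, depth_sd)
    scans = []
    for i, d in enumerate(depths):
        resp = simulate_cine(
            phantom,
            RESPIRATORY,
            n_phases=n_phases,
            n_avg=n_avg,
            depth_scale=float(d),
            seed=seed_sequence(seed, STREAM_RESP, i),
        )
        card = simulate_cine(
            phantom,
            CARDIAC,
            n_phases=n_phases,
            n_avg=n_avg,
            seed=seed_sequence(seed, STREAM_CARD, i),
        )
        scans.append((resp, card))
    return ScanSet(
        phantom=phantom, scans=scans, depths_true=depths, seed=int(seed), n_avg=n_avg
    )
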