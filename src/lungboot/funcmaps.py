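"""Quantitative functional parameter maps from first-harmonic fits.

Three maps are computed voxel-wise:

ventilation (mL air / mL lung parenchyma)
    ``V = (S_exp - S_ins) / S_exp`` with ``S_exp = a0 + v`` and
    ``S_ins = a0 - v``, where ``v = Re(c1)`` is the signed ventilation signal
    under the phase-0-is-expiration convention, i.e. ``V = 2 v / (a0 + v)``.
    Voxels with ``S_exp <= 0`` are flagged invalid (NaN + mask), never
    silently zeroed; values are not clamped to [0, 1] so that implausible
    estimates stay visible.

perfusion amplitude (dimensionless)
    ``|c1| / S_ref`` with ``S_ref`` the mean DC signal over a fully
    blood-filled reference ROI (descending aorta).

perfusion timing (ms)
    Phase shift of the voxel first harmonic relative to the reference ROI,
    scaled by the heartbeat duration:
    ``timing = wrap(arg c1 - phi_ref) / (2 pi) * T_RR`` with the reference
    phase ``phi_ref = arg(sum_ROI c1)`` (argument of the complex mean, robust
    to wrapping inside the ROI) and the wrap interval ``[-T_RR/2, T_RR/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cine import CARDIAC, RESPIRATORY
from .harmonic import HarmonicFitResults

VENTILATION = "ventilation"
PERFUSION_AMPLITUDE = "perfusion_amplitude"
PERFUSION_TIMING = "perfusion_timing"

MAP_KINDS = (VENTILATION, PERFUSION_AMPLITUDE, PERFUSION_TIMING)

UNITS = {
    VENTILATION: "mL air/mL lung parenchyma",
    PERFUSION_AMPLITUDE: "dimensionless",
    PERFUSION_TIMING: "ms",
}

#: cycle kind required by each map kind
CYCLE_FOR_KIND = {
    VENTILATION: RESPIRATORY,
    PERFUSION_AMPLITUDE: CARDIAC,
    PERFUSION_TIMING: CARDIAC,
}


def wrap_phase(phi):
    """Wrap angles into [-pi, pi); a tie at exactly +pi maps to -pi."""
    return (np.asarray(phi) + np.pi) % (2.0 * np.pi) - np.pi


@dataclass
class ParamMap:
    """A 2D quantitative map with a validity mask."""

    values: np.ndarray
    kind: str
    mask: np.ndarray
    reference_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind: {self.kind!r}")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    @property
    def units(self) -> str:
        return UNITS[self.kind]


def _require_cycle(fit: HarmonicFitResults, kind: str) -> None:
    want = CYCLE_FOR_KIND[kind]
    if fit.cycle_kind != want:
        raise ValueError(f"{kind} map requires a {want} fit, got {fit.cycle_kind}")


def ventilation_map(fit: HarmonicFitResults, mode: str = "real") -> ParamMap:
    """Absolute ventilation in mL air per mL lung parenchyma.

    ``mode="real"`` (default) uses the signed real part of c1; the
    ``"magnitude"`` mode uses |c1| for robustness when the phase alignment of
    the reconstructed cycle is unknown.
    """
    _require_cycle(fit, VENTILATION)
    if mode == "real":
        v = fit.c1.real
    elif mode == "magnitude":
        v = np.abs(fit.c1)
    else:
        raise ValueError(f"unknown ventilation mode: {mode!r}")
    s_exp = fit.a0 + v
    valid = s_exp > 0
    values = np.full(fit.a0.shape, np.nan)
    values[valid] = 2.0 * v[valid] / s_exp[valid]
    return ParamMap(values=values, kind=VENTILATION, mask=valid,
                    reference_meta={"mode": mode})


def _roi_reference(fit: HarmonicFitResults, aorta_roi: np.ndarray):
    aorta_roi = np.asarray(aorta_roi, dtype=bool)
    if aorta_roi.shape != fit.a0.shape:
        raise ValueError("ROI shape does not match the fit")
    if not aorta_roi.any():
        raise ValueError("empty aorta ROI")
    return aorta_roi


def perfusion_amplitude_map(fit: HarmonicFitResults, aorta_roi) -> ParamMap:
    """First-harmonic amplitude normalised to the blood-filled reference ROI."""
    _require_cycle(fit, PERFUSION_AMPLITUDE)
    roi = _roi_reference(fit, aorta_roi)
    s_ref = float(fit.a0[roi].mean())
    if s_ref <= 0:
        raise ValueError("non-positive reference signal in the aorta ROI")
    values = np.abs(fit.c1) / s_ref
    return ParamMap(
        values=values,
        kind=PERFUSION_AMPLITUDE,
        mask=np.ones_like(values, dtype=bool),
        reference_meta={"s_ref": s_ref, "roi_size": int(roi.sum())},
    )


def perfusion_timing_map(fit: HarmonicFitResults, aorta_roi) -> ParamMap:
    """First-harmonic phase shift versus the reference ROI, in milliseconds."""
    _require_cycle(fit, PERFUSION_TIMING)
    if not fit.cycle_duration_ms > 0:
        raise ValueError("cardiac cycle duration (T_RR) must be positive")
    roi = _roi_reference(fit, aorta_roi)
    ref = complex(fit.c1[roi].mean())
    if abs(ref) <= 1e-300 * max(1.0, float(np.abs(fit.c1).max())):
        raise ValueError("reference phase undefined (ROI complex mean ~ 0)")
    phi_ref = np.angle(ref)
    dphi = wrap_phase(np.angle(fit.c1) - phi_ref)
    values = dphi / (2.0 * np.pi) * fit.cycle_duration_ms
    return ParamMap(
        values=values,
        kind=PERFUSION_TIMING,
        mask=np.ones_like(values, dtype=bool),
        reference_meta={
            "phi_ref": float(phi_ref),
            "t_rr_ms": float(fit.cycle_duration_ms),
            "roi_size": int(roi.sum()),
        },
    )


def compute_map(fit: HarmonicFitResults, kind: str, roi=None) -> ParamMap:
    """Dispatch on map kind (perfusion kinds require ``roi``)."""
    if kind == VENTILATION:
        return ventilation_map(fit)
    if kind == PERFUSION_AMPLITUDE:
        return perfusion_amplitude_map(fit, roi)
    if kind == PERFUSION_TIMING:
        return perfusion_timing_map(fit, roi)
    raise ValueError(f"unknown map kind: {kind!r}")
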