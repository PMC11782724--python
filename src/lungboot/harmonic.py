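"""Voxel-wise first-harmonic modelling of a cine series.

The signal of every voxel over the reconstructed cycle is decomposed by a
temporal DFT into a static component ``a0``, the complex first harmonic ``c1``
(which carries the ventilation/perfusion information) and residual higher
components (noise, artifacts, model inadequacy).  Normalisation is fixed so
that ``|c1|`` is the physical cosine amplitude:

    a0 = (1/N) sum_t s(t)
    c1 = (2/N) sum_t s(t) exp(-i 2 pi t / N)
    model(t) = a0 + Re(c1 exp(+i 2 pi t / N))

``FirstHarmonicModel`` / ``HarmonicFitResults`` follow the statsmodels
Model/Results pattern; the module-level functions ``fit_first_harmonic``,
``reconstruct_model`` and ``compute_residuals`` are thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cine import CineSeries


@dataclass
class ResidualSeries:
    """Per-voxel deviations of the data from the harmonic model.

    For residuals produced by :func:`compute_residuals`, the per-voxel phase
    sum and the DFT bins of all modelled harmonics vanish.  A *shuffled*
    residual series (see :mod:`lungboot.boot`) keeps the multiset of values
    per voxel — and hence the zero sum — but generically re-acquires
    first-harmonic content; that is the mechanism of the bootstrap.
    """

    data: np.ndarray
    source_fingerprint: str
    cycle_kind: str = ""

    @property
    def n_phases(self) -> int:
        return self.data.shape[-1]

    def validate(self, atol: float = 1e-9) -> None:
        """Check the fresh-residual invariants (zero bins 0 and 1)."""
        scale = max(1.0, float(np.abs(self.data).max()))
        spec = np.fft.fft(self.data, axis=-1)
        if not np.allclose(spec[..., 0], 0.0, atol=atol * scale * self.n_phases):
            raise ValueError("residuals have nonzero temporal mean")
        if not np.allclose(spec[..., 1], 0.0, atol=atol * scale * self.n_phases):
            raise ValueError("residuals have first-harmonic content")


@dataclass
class HarmonicFitResults:
    """Per-voxel DC term and complex harmonic coefficients of a cine series.

    Attributes
    ----------
    a0 : real map — static component.
    c1 : complex map — first harmonic (ventilation/perfusion signal).
    coeffs : complex array (n_harmonics, rows, cols) of all modelled harmonics
        (``coeffs[0]`` is ``c1``).
    """

    a0: np.ndarray
    c1: np.ndarray
    n_phases: int
    cycle_kind: str
    cycle_duration_ms: float
    n_harmonics: int = 1
    coeffs: Optional[np.ndarray] = None
    source_fingerprint: str = ""
    n_avg: int = 1
    _source: Optional[CineSeries] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.coeffs is None:
            self.coeffs = self.c1[None, ...]

    @property
    def fittedvalues(self) -> np.ndarray:
        """The model time courses, shape (rows, cols, n_phases)."""
        t = np.arange(self.n_phases)
        model = np.repeat(self.a0[..., None], self.n_phases, axis=-1).astype(float)
        for k in range(self.n_harmonics):
            phase = np.exp(2j * np.pi * (k + 1) * t / self.n_phases)
            model += (self.coeffs[k][..., None] * phase).real
        return model

    def model_series(self) -> CineSeries:
        """Model reconstruction packaged as a cine series (same metadata)."""
        src_meta = dict(self._source.meta) if self._source is not None else {}
        return CineSeries(
            data=self.fittedvalues,
            cycle_kind=self.cycle_kind,
            cycle_duration_ms=self.cycle_duration_ms,
            n_avg=self.n_avg,
            meta=src_meta,
        )

    @property
    def resid(self) -> np.ndarray:
        if self._source is None:
            raise ValueError("fit carries no source series; use compute_residuals")
        return self._source.data - self.fittedvalues

    def residual_series(self) -> ResidualSeries:
        return ResidualSeries(
            data=self.resid,
            source_fingerprint=self.source_fingerprint,
            cycle_kind=self.cycle_kind,
        )

    # -- functional maps (implemented in funcmaps; exposed here for the
    #    results-object workflow) ------------------------------------------
    def ventilation_map(self, mode: str = "real"):
        from .funcmaps import ventilation_map

        return ventilation_map(self, mode=mode)

    def perfusion_amplitude_map(self, aorta_roi):
        from .funcmaps import perfusion_amplitude_map

        return perfusion_amplitude_map(self, aorta_roi)

    def perfusion_timing_map(self, aorta_roi):
        from .funcmaps import perfusion_timing_map

        return perfusion_timing_map(self, aorta_roi)

    def bootstrap_error_map(self, map_kind, roi=None, cfg=None):
        from .boot import bootstrap_error_map

        if self._source is None:
            raise ValueError("fit carries no source series")
        return bootstrap_error_map(self._source, map_kind, roi=roi, cfg=cfg)

    def summary(self) -> str:
        amp = np.abs(self.c1)
        lines = [
            "First-harmonic fit",
            "==================",
            f"cycle_kind        : {self.cycle_kind}",
            f"grid              : {self.a0.shape[0]} x {self.a0.shape[1]}",
            f"n_phases          : {self.n_phases}",
            f"cycle duration    : {self.cycle_duration_ms:.0f} ms",
            f"n_harmonics       : {self.n_harmonics}",
            f"a0  median (IQR)  : {np.median(self.a0):.4g}"
            f" ({np.subtract(*np.percentile(self.a0, [75, 25])):.4g})",
            f"|c1| median (IQR) : {np.median(amp):.4g}"
            f" ({np.subtract(*np.percentile(amp, [75, 25])):.4g})",
        ]
        return "\n".join(lines)


class FirstHarmonicModel:
    """Voxel-wise temporal Fourier model of a cine series.

    Parameters
    ----------
    series:
        The cine series to model.
    n_harmonics:
        Number of harmonics in the model (default 1: DC + first harmonic).
        The functional maps always use the first harmonic only.
    """

    def __init__(self, series: CineSeries, n_harmonics: int = 1):
        if n_harmonics < 1 or 2 * n_harmonics >= series.n_phases:
            raise ValueError("n_harmonics out of range for this phase count")
        self.series = series
        self.n_harmonics = int(n_harmonics)

    def fit(self) -> HarmonicFitResults:
        s = self.series
        spec = np.fft.fft(s.data, axis=-1)
        n = s.n_phases
        a0 = spec[..., 0].real / n
        coeffs = np.moveaxis(2.0 * spec[..., 1 : self.n_harmonics + 1] / n, -1, 0)
        return HarmonicFitResults(
            a0=a0,
            c1=coeffs[0],
            n_phases=n,
            cycle_kind=s.cycle_kind,
            cycle_duration_ms=s.cycle_duration_ms,
            n_harmonics=self.n_harmonics,
            coeffs=coeffs,
            source_fingerprint=s.fingerprint(),
            n_avg=s.n_avg,
            _source=s,
        )


def fit_first_harmonic(series: CineSeries, n_harmonics: int = 1) -> HarmonicFitResults:
    """Fit the DC + first-harmonic model voxel-wise (step 1)."""
    return FirstHarmonicModel(series, n_harmonics=n_harmonics).fit()


def reconstruct_model(fit: HarmonicFitResults) -> CineSeries:
    """The model data implied by a fit, as a cine series."""
    return fit.model_series()


def compute_residuals(series: CineSeries, fit: HarmonicFitResults) -> ResidualSeries:
    """Data minus model for every voxel and time point (step 2).

    Rejects a fit that was not computed from ``series`` (fingerprint check) to
    prevent mixing model and data from different series.
    """
    if fit.source_fingerprint != series.fingerprint():
        raise ValueError("fit does not originate from this series")
    res = ResidualSeries(
        data=series.data - fit.fittedvalues,
        source_fingerprint=fit.source_fingerprint,
        cycle_kind=series.cycle_kind,
    )
    return res
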