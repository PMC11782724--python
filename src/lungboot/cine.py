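"""The cine-series container.

A *cine series* is a stack of N phase images spanning one reconstructed
physiological cycle — one pseudo-breath (respiratory) or one pseudo-heartbeat
(cardiac).  Data are stored as a real array of shape ``(rows, cols, n_phases)``
in arbitrary signal units.  The phase-zero convention is part of the contract:
respiratory series start at expiration (signal maximum in lung parenchyma),
cardiac series start at the reference systole.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

RESPIRATORY = "respiratory"
CARDIAC = "cardiac"

_PHASE_ZERO = {
    RESPIRATORY: "expiration-start",
    CARDIAC: "reference-systole-start",
}


@dataclass
class CineSeries:
    """One reconstructed physiological cycle of 2D images.

    Parameters
    ----------
    data:
        Real array ``(rows, cols, n_phases)``; all values finite.
    cycle_kind:
        ``"respiratory"`` or ``"cardiac"``.
    cycle_duration_ms:
        Duration of the reconstructed cycle (for a cardiac series this is the
        RR interval used to convert phase shifts to milliseconds).
    n_avg:
        Averaging factor of the acquisition; noise SD scales as 1/sqrt(n_avg).
    lung_area_per_phase:
        Optional per-phase lung area (voxel count or mm^2), used to measure
        breathing depth.  Filled by the phantom for simulated data; supplied
        externally for real data.
    """

    data: np.ndarray
    cycle_kind: str
    cycle_duration_ms: float
    n_avg: int = 1
    phase_zero_convention: str = ""
    lung_area_per_phase: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.cycle_kind not in (RESPIRATORY, CARDIAC):
            raise ValueError(f"unknown cycle_kind: {self.cycle_kind!r}")
        if self.data.ndim != 3:
            raise ValueError("data must be (rows, cols, n_phases)")
        if self.data.shape[-1] < 4:
            raise ValueError("need at least 4 phases")
        if int(self.n_avg) < 1:
            raise ValueError("n_avg must be >= 1")
        self.n_avg = int(self.n_avg)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in cine data")
        if not self.phase_zero_convention:
            self.phase_zero_convention = _PHASE_ZERO[self.cycle_kind]
        if self.lung_area_per_phase is not None:
            self.lung_area_per_phase = np.asarray(
                self.lung_area_per_phase, dtype=np.float64
            )
            if self.lung_area_per_phase.shape != (self.n_phases,):
                raise ValueError("lung_area_per_phase must have one entry per phase")

    @property
    def n_phases(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def fingerprint(self) -> str:
        """Stable content hash used to pair fits/residuals with their source."""
        h = hashlib.sha1()
        h.update(self.cycle_kind.encode())
        h.update(np.int64(self.data.shape).tobytes())
        h.update(self.data.tobytes())
        return h.hexdigest()
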