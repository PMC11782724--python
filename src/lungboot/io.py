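"""NIfTI + JSON-sidecar I/O.

Cine series are stored as one 3D NIfTI volume (rows x cols x phase) with a
JSON sidecar carrying the cycle metadata; masks as an integer label volume
(0 background, 1 lung, 2 aorta); parameter/error maps as 2D volumes with a
sidecar (kind, units, reference metadata, provenance).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .boot import CIWidthMap, ErrorMap
from .cine import CineSeries
from .funcmaps import UNITS, ParamMap
from .phantom import Phantom

_AFFINE = np.eye(4)

LABEL_BACKGROUND = 0
LABEL_LUNG = 1
LABEL_AORTA = 2


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def _write(path: Path, data: np.ndarray, sidecar: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), _AFFINE), str(path))
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def _read(path: Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    data = np.asarray(nib.load(str(path)).dataobj)
    sc = _sidecar_path(path)
    meta = {}
    if sc.exists():
        with open(sc) as fh:
            meta = json.load(fh)
    return data, meta


def save_cine(series: CineSeries, path) -> None:
    sidecar = {
        "cycle_kind": series.cycle_kind,
        "n_phases": series.n_phases,
        "cycle_duration_ms": series.cycle_duration_ms,
        "n_avg": series.n_avg,
        "phase_zero_convention": series.phase_zero_convention,
        "meta": {k: v for k, v in series.meta.items() if _jsonable(v)},
    }
    if series.lung_area_per_phase is not None:
        sidecar["lung_area_per_phase"] = series.lung_area_per_phase.tolist()
    _write(Path(path), series.data, sidecar)


def load_cine(path) -> CineSeries:
    data, meta = _read(Path(path))
    areas = meta.get("lung_area_per_phase")
    return CineSeries(
        data=np.asarray(data, dtype=np.float64),
        cycle_kind=meta["cycle_kind"],
        cycle_duration_ms=float(meta["cycle_duration_ms"]),
        n_avg=int(meta.get("n_avg", 1)),
        phase_zero_convention=meta.get("phase_zero_convention", ""),
        lung_area_per_phase=np.asarray(areas) if areas is not None else None,
        meta=meta.get("meta", {}),
    )


def save_map(pmap, path, provenance: dict | None = None) -> None:
    """Write a ParamMap, ErrorMap or CIWidthMap with its sidecar."""
    sidecar: dict = {"kind": pmap.kind, "units": UNITS[pmap.kind]}
    if isinstance(pmap, ParamMap):
        sidecar["map_type"] = "parameter"
        sidecar["reference_meta"] = {
            k: v for k, v in pmap.reference_meta.items() if _jsonable(v)
        }
    elif isinstance(pmap, ErrorMap):
        sidecar["map_type"] = "error"
        sidecar["B_used"] = pmap.B_used
        sidecar["seed"] = pmap.seed
        sidecar["meta"] = {k: v for k, v in pmap.meta.items() if _jsonable(v)}
    elif isinstance(pmap, CIWidthMap):
        sidecar["map_type"] = "ci_width"
        sidecar["R_used"] = pmap.R_used
        sidecar["B_used"] = pmap.B_used
        sidecar["seed"] = pmap.seed
    if provenance:
        sidecar["provenance"] = provenance
    _write(Path(path), pmap.values, sidecar)
    if isinstance(pmap, ParamMap):
        mask_path = Path(path)
        name = mask_path.name
        for suf in (".nii.gz", ".nii"):
            if name.endswith(suf):
                mask_path = mask_path.with_name(name[: -len(suf)] + "_mask" + suf)
                break
        nib.save(
            nib.Nifti1Image(pmap.mask.astype(np.uint8), _AFFINE), str(mask_path)
        )


def load_map_values(path) -> tuple[np.ndarray, dict]:
    """Raw map values + sidecar (used by the gse CLI on per-scan map files)."""
    return _read(Path(path))


def save_masks(phantom: Phantom, path) -> None:
    labels = np.zeros(phantom.grid_shape, dtype=np.int16)
    labels[phantom.lung_mask] = LABEL_LUNG
    labels[phantom.aorta_roi] = LABEL_AORTA
    _write(
        Path(path),
        labels,
        {"labels": {"0": "background", "1": "lung", "2": "aorta"}},
    )


def load_masks(path) -> tuple[np.ndarray, np.ndarray]:
    """(lung_mask, aorta_roi) from an integer label volume."""
    labels, _ = _read(Path(path))
    return labels == LABEL_LUNG, labels == LABEL_AORTA


def _jsonable(v) -> bool:
    return isinstance(v, (str, int, float, bool, list, dict, type(None)))
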