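"""End-to-end synthetic validation experiment and report generation.

``run_experiment`` is the desk-scale replica of the repeatability study
design: simulate a set of repeated scans with variable breathing depth, then
per scan and per averaging factor compute the three functional maps and their
bootstrap error maps, measure breathing depths, exclude outlier scans
(mean +/- SD rule), compute the gold-standard error (GSE) from the included
scans, and summarise everything into per-scan median/IQR rows plus the
precision and accuracy of the median error.  Fully deterministic given the
master seed.

``monte_carlo_error_maps`` provides the independent fresh-noise truth: the
per-voxel SD of maps across freshly simulated noise realizations, used to
calibrate the bootstrap.

``table1_check`` re-derives the aggregate rows of the published summary table
from the shipped per-scan values (:mod:`lungboot.published`).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from ._seeds import STREAM_MC, child_seed, seed_sequence
from .boot import BootConfig, ErrorMap, bootstrap_error_maps, error_map_ci
from .cine import CARDIAC, RESPIRATORY
from .funcmaps import (
    MAP_KINDS,
    PERFUSION_AMPLITUDE,
    PERFUSION_TIMING,
    VENTILATION,
    compute_map,
)
from .harmonic import fit_first_harmonic
from .metrics import accuracy_of_median, masked_median_iqr, precision_of_median
from .phantom import Phantom, PhantomConfig, make_phantom, simulate_cine, simulate_scan_set
from .published import PER_SCAN_SUMMARIES
from .repeated import breathing_depth, gold_standard_error, select_scans

log = logging.getLogger(__name__)

_KINDS_BY_CYCLE = {
    RESPIRATORY: [VENTILATION],
    CARDIAC: [PERFUSION_AMPLITUDE, PERFUSION_TIMING],
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of the synthetic repeatability experiment."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_scans: int = 10
    n_avg_levels: tuple[int, ...] = (6, 3, 1)
    depth_mean: float = 1.0
    depth_sd: float = 0.02
    boot: BootConfig = field(default_factory=BootConfig)
    n_phases: int = 20
    seed: int = 0
    compute_ci: bool = False   # CI path runs on one scan only (costly)
    ci_R: int = 100

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_avg_levels):
            raise ValueError("n_avg levels must be >= 1")


@dataclass
class ExperimentReport:
    """All experiment outputs; every number is recomputable from config+seed."""

    rows: pd.DataFrame            # per (scan, kind, n_avg) summary rows
    gse_median: dict              # (kind, n_avg) -> median GSE over lung
    precision: dict               # (kind, n_avg) -> IQR of boot medians
    accuracy: dict                # (kind, n_avg) -> median(gse_med - boot_med)
    boot_vs_gse: list             # dicts: kind, n_avg, gse_median, boot_median
    depth_summary: dict           # per n_avg: depths, bounds, included
    ci_median: dict               # (kind, n_avg) -> median CI width (optional)
    provenance: dict

    def to_json(self, path=None) -> str:
        def _key(d):
            return {f"{k[0]}|{k[1]}": v for k, v in d.items()}

        payload = {
            "provenance": self.provenance,
            "rows": self.rows.to_dict(orient="records"),
            "gse_median": _key(self.gse_median),
            "precision": _key(self.precision),
            "accuracy": _key(self.accuracy),
            "boot_vs_gse": self.boot_vs_gse,
            "depth_summary": self.depth_summary,
            "ci_median": _key(self.ci_median),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _maps_for_scan(resp, card, aorta_roi):
    """The three functional maps of one scan."""
    fit_r = fit_first_harmonic(resp)
    fit_c = fit_first_harmonic(card)
    return {
        VENTILATION: compute_map(fit_r, VENTILATION),
        PERFUSION_AMPLITUDE: compute_map(fit_c, PERFUSION_AMPLITUDE, aorta_roi),
        PERFUSION_TIMING: compute_map(fit_c, PERFUSION_TIMING, aorta_roi),
    }


def _boot_for_scan(resp, card, aorta_roi, cfg: BootConfig, seed: int):
    out = {}
    out.update(
        bootstrap_error_maps(
            resp, [VENTILATION], cfg=BootConfig(**{**asdict(cfg), "seed": seed})
        )
    )
    out.update(
        bootstrap_error_maps(
            card,
            [PERFUSION_AMPLITUDE, PERFUSION_TIMING],
            roi=aorta_roi,
            cfg=BootConfig(**{**asdict(cfg), "seed": child_seed(seed, 1)}),
        )
    )
    return out


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Simulate, map, bootstrap, select, GSE, summarise (see module docstring)."""
    t0 = time.time()
    phantom = make_phantom(cfg.phantom, seed=cfg.seed)
    lung = phantom.lung_mask
    aorta = phantom.aorta_roi

    rows = []
    gse_median: dict = {}
    precision: dict = {}
    accuracy: dict = {}
    pairs: list = []
    depth_summaries: dict = {}
    ci_median: dict = {}

    for n_avg in cfg.n_avg_levels:
        scan_seed = child_seed(cfg.seed, 100, n_avg)
        scans = simulate_scan_set(
            phantom,
            n_scans=cfg.n_scans,
            depth_mean=cfg.depth_mean,
            depth_sd=cfg.depth_sd,
            n_avg=n_avg,
            n_phases=cfg.n_phases,
            seed=scan_seed,
        )
        log.info("n_avg=%d: simulated %d scans (seed %d)", n_avg, cfg.n_scans, scan_seed)

        depths = np.array([breathing_depth(resp) for resp, _ in scans.scans])
        summary = select_scans(depths)
        depth_summaries[str(n_avg)] = {
            "depths_pct": depths.tolist(),
            "mean": summary.mean,
            "sd": summary.sd,
            "lower_bound": summary.lower_bound,
            "upper_bound": summary.upper_bound,
            "included": summary.included.tolist(),
        }

        maps_per_scan = []
        boot_medians = {k: [] for k in MAP_KINDS}
        for i, (resp, card) in enumerate(scans.scans):
            maps = _maps_for_scan(resp, card, aorta)
            boots = _boot_for_scan(
                resp, card, aorta, cfg.boot, seed=child_seed(cfg.seed, 200, n_avg, i)
            )
            maps_per_scan.append(maps)
            for kind in MAP_KINDS:
                mv, iv = masked_median_iqr(maps[kind], lung)
                me, ie = masked_median_iqr(boots[kind], lung)
                boot_medians[kind].append(me)
                rows.append(
                    {
                        "scan_id": i,
                        "kind": kind,
                        "n_avg": n_avg,
                        "depth_pct": float(depths[i]),
                        "included": bool(summary.included[i]),
                        "median_value": mv,
                        "iqr_value": iv,
                        "median_error": me,
                        "iqr_error": ie,
                    }
                )
        log.info("n_avg=%d: maps and bootstrap errors done (%.1f s)", n_avg, time.time() - t0)

        for kind in MAP_KINDS:
            if summary.gse_defined:
                included_maps = [
                    m[kind] for m, ok in zip(maps_per_scan, summary.included) if ok
                ]
                gse = gold_standard_error(included_maps)
                g_med, _ = masked_median_iqr(gse, lung)
            else:
                log.warning("n_avg=%d: fewer than 2 included scans; GSE undefined", n_avg)
                g_med = float("nan")
            gse_median[(kind, n_avg)] = g_med
            precision[(kind, n_avg)] = precision_of_median(boot_medians[kind])
            accuracy[(kind, n_avg)] = accuracy_of_median(g_med, boot_medians[kind])
            pairs.append(
                {
                    "kind": kind,
                    "n_avg": n_avg,
                    "gse_median": g_med,
                    "boot_median": float(np.median(boot_medians[kind])),
                }
            )

        if cfg.compute_ci:
            # reproducibility CI on the first scan only
            resp, card = scans.scans[0]
            ci_cfg = BootConfig(
                **{
                    **asdict(cfg.boot),
                    "R": cfg.ci_R,
                    "seed": child_seed(cfg.seed, 300, n_avg),
                }
            )
            for kind, series, roi in (
                (VENTILATION, resp, None),
                (PERFUSION_AMPLITUDE, card, aorta),
                (PERFUSION_TIMING, card, aorta),
            ):
                ci = error_map_ci(series, kind, roi=roi, cfg=ci_cfg)
                med, _ = masked_median_iqr(ci, lung)
                ci_median[(kind, n_avg)] = med

    report = ExperimentReport(
        rows=pd.DataFrame(rows),
        gse_median=gse_median,
        precision=precision,
        accuracy=accuracy,
        boot_vs_gse=pairs,
        depth_summary=depth_summaries,
        ci_median=ci_median,
        provenance={
            "seed": cfg.seed,
            "n_scans": cfg.n_scans,
            "n_avg_levels": list(cfg.n_avg_levels),
            "depth_mean": cfg.depth_mean,
            "depth_sd": cfg.depth_sd,
            "grid_shape": list(cfg.phantom.grid_shape),
            "B": cfg.boot.B,
            "shuffle_mode": cfg.boot.shuffle_mode,
            "sampling": cfg.boot.sampling,
        },
    )
    log.info("experiment done in %.1f s", time.time() - t0)
    return report


def monte_carlo_error_maps(
    phantom: Phantom,
    cycle_kind: str,
    n_avg: int = 1,
    n_phases: int = 20,
    depth_scale: float = 1.0,
    n_realizations: int = 200,
    roi=None,
    seed: int = 0,
) -> dict[str, ErrorMap]:
    """Fresh-noise Monte-Carlo truth: per-voxel SD over new noise realizations.

    Each realization is a completely new simulated scan of the same phantom
    and conditions; the SD of the resulting maps is what the bootstrap error
    map estimates from a single scan.
    """
    if n_realizations < 2:
        raise ValueError("need at least 2 realizations")
    kinds = _KINDS_BY_CYCLE[cycle_kind]
    acc_sum = None
    acc_sq = None
    for r in range(n_realizations):
        series = simulate_cine(
            phantom,
            cycle_kind,
            n_phases=n_phases,
            n_avg=n_avg,
            depth_scale=depth_scale,
            seed=seed_sequence(seed, STREAM_MC, r),
        )
        fit = fit_first_harmonic(series)
        vals = {k: compute_map(fit, k, roi=roi).values for k in kinds}
        if acc_sum is None:
            acc_sum = {k: np.zeros_like(vals[k]) for k in kinds}
            acc_sq = {k: np.zeros_like(vals[k]) for k in kinds}
        for k in kinds:
            acc_sum[k] += vals[k]
            acc_sq[k] += vals[k] ** 2
    out = {}
    for k in kinds:
        mean = acc_sum[k] / n_realizations
        var = (acc_sq[k] - n_realizations * mean**2) / (n_realizations - 1)
        with np.errstate(invalid="ignore"):
            sd = np.sqrt(np.maximum(var, 0.0))
            sd = np.where(np.isnan(var), np.nan, sd)
        out[k] = ErrorMap(
            values=sd,
            kind=k,
            B_used=n_realizations,
            seed=seed,
            mean_map=mean,
            meta={"source": "fresh-noise-monte-carlo"},
        )
    return out


def table1_check(table_inputs: dict | None = None) -> dict:
    """Re-derive the aggregate summary rows from per-scan published values.

    For each averaging factor and map kind, recomputes the median over the 10
    per-scan map medians / IQRs / error medians / error IQRs, and the
    precision of the median error (Tukey-hinge IQR of the error medians).
    """
    table = table_inputs if table_inputs is not None else PER_SCAN_SUMMARIES
    out: dict = {}
    for n_avg, kinds in table.items():
        out[n_avg] = {}
        for kind, rows in kinds.items():
            for name, vec in rows.items():
                if len(vec) != 10:
                    raise ValueError(
                        f"{n_avg}/{kind}/{name}: expected 10 per-scan values, "
                        f"got {len(vec)}"
                    )
            out[n_avg][kind] = {
                "median_over_maps": float(np.median(rows["map_medians"])),
                "median_over_iqrs": float(np.median(rows["map_iqrs"])),
                "median_over_error_maps": float(np.median(rows["error_medians"])),
                "median_over_error_iqrs": float(np.median(rows["error_iqrs"])),
                "precision_of_median_error": precision_of_median(rows["error_medians"]),
            }
    return out
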