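"""Published per-scan summary values of the 10-scan repeatability study.

These are the printed inputs of the published summary table for a healthy
volunteer scanned 10 times: per-scan lung medians and Tukey-hinge IQRs of the
three functional maps and of their bootstrap error maps, at averaging factors
6, 3 and 1.  They serve as worked-example inputs for re-deriving the table's
aggregate rows (`median over all maps`, `median over all IQRs`, `median over
all error maps`, `precision of the median error`) with :mod:`lungboot.metrics`
— which pins the quartile convention — and for the breathing-depth rule.

Scan order is scans 1-10.  Units: ventilation in mL air/mL lung parenchyma,
perfusion amplitude dimensionless, perfusion timing in ms.
"""

from __future__ import annotations

VENTILATION = "ventilation"
PERFUSION_AMPLITUDE = "perfusion_amplitude"
PERFUSION_TIMING = "perfusion_timing"

#: Printed breathing-depth statistics over the 10 repeated scans (percent).
BREATHING_DEPTH_MEAN_PCT = 24.3
BREATHING_DEPTH_SD_PCT = 5.6

#: Per-scan summary values, keyed by averaging factor and map kind.  Rows:
#: ``map_medians`` / ``map_iqrs`` — per-scan lung median / IQR of the
#: functional map; ``error_medians`` / ``error_iqrs`` — of the bootstrap
#: error map.
PER_SCAN_SUMMARIES: dict[int, dict[str, dict[str, list[float]]]] = {
    6: {
        VENTILATION: {
            "map_medians": [0.179, 0.173, 0.191, 0.222, 0.215,
                            0.219, 0.224, 0.184, 0.221, 0.220],
            "map_iqrs": [0.134, 0.109, 0.124, 0.124, 0.122,
                         0.111, 0.121, 0.096, 0.124, 0.136],
            "error_medians": [0.016, 0.015, 0.017, 0.015, 0.015,
                              0.018, 0.017, 0.016, 0.014, 0.015],
            "error_iqrs": [0.008, 0.007, 0.008, 0.008, 0.008,
                           0.007, 0.007, 0.007, 0.007, 0.007],
        },
        PERFUSION_AMPLITUDE: {
            "map_medians": [0.027, 0.026, 0.027, 0.029, 0.027,
                            0.031, 0.030, 0.027, 0.028, 0.030],
            "map_iqrs": [0.032, 0.030, 0.029, 0.030, 0.029,
                         0.030, 0.032, 0.032, 0.031, 0.031],
            "error_medians": [0.006, 0.006, 0.005, 0.005, 0.005,
                              0.006, 0.006, 0.005, 0.005, 0.006],
            "error_iqrs": [0.004, 0.005, 0.004, 0.005, 0.004,
                           0.004, 0.005, 0.004, 0.004, 0.005],
        },
        PERFUSION_TIMING: {
            "map_medians": [-56.32, -46.92, -75.36, -88.23, -68.33,
                            -112.74, -121.80, -33.47, -99.76, -90.93],
            "map_iqrs": [116.19, 121.30, 125.06, 106.03, 119.20,
                         96.93, 116.77, 120.92, 110.71, 104.75],
            "error_medians": [56.91, 53.76, 49.15, 43.30, 44.50,
                              42.10, 47.80, 52.26, 40.38, 46.96],
            "error_iqrs": [44.98, 34.33, 29.15, 20.56, 22.96,
                           20.01, 23.78, 32.23, 16.69, 22.01],
        },
    },
    3: {
        VENTILATION: {
            "map_medians": [0.181, 0.119, 0.155, 0.188, 0.212,
                            0.188, 0.194, 0.165, 0.181, 0.187],
            "map_iqrs": [0.137, 0.111, 0.123, 0.137, 0.121,
                         0.111, 0.126, 0.117, 0.118, 0.125],
            "error_medians": [0.041, 0.039, 0.038, 0.040, 0.037,
                              0.037, 0.038, 0.037, 0.037, 0.037],
            "error_iqrs": [0.018, 0.022, 0.017, 0.021, 0.017,
                           0.020, 0.020, 0.019, 0.018, 0.015],
        },
        PERFUSION_AMPLITUDE: {
            "map_medians": [0.030, 0.026, 0.024, 0.032, 0.025,
                            0.031, 0.026, 0.029, 0.030, 0.029],
            "map_iqrs": [0.028, 0.025, 0.024, 0.028, 0.025,
                         0.029, 0.029, 0.027, 0.027, 0.029],
            "error_medians": [0.011, 0.009, 0.009, 0.010, 0.009,
                              0.009, 0.009, 0.009, 0.009, 0.010],
            "error_iqrs": [0.005, 0.004, 0.004, 0.004, 0.004,
                           0.004, 0.004, 0.004, 0.004, 0.005],
        },
        PERFUSION_TIMING: {
            "map_medians": [-16.80, -51.45, -13.12, -43.62, 3.05,
                            -11.94, -143.42, -29.00, -85.54, -25.74],
            "map_iqrs": [166.80, 210.10, 203.71, 169.32, 262.25,
                         152.92, 338.30, 152.23, 166.37, 211.35],
            "error_medians": [101.23, 108.92, 115.07, 84.81, 108.40,
                              79.92, 106.24, 84.79, 83.99, 94.60],
            "error_iqrs": [122.89, 139.11, 167.17, 89.47, 143.98,
                           97.81, 171.29, 114.43, 111.26, 113.90],
        },
    },
    1: {
        VENTILATION: {
            "map_medians": [0.163, 0.108, 0.140, 0.176, 0.196,
                            0.178, 0.180, 0.148, 0.168, 0.178],
            "map_iqrs": [0.161, 0.154, 0.149, 0.159, 0.146,
                         0.138, 0.146, 0.140, 0.155, 0.140],
            "error_medians": [0.065, 0.066, 0.063, 0.068, 0.068,
                              0.063, 0.065, 0.060, 0.068, 0.059],
            "error_iqrs": [0.025, 0.023, 0.023, 0.028, 0.024,
                           0.027, 0.023, 0.022, 0.024, 0.020],
        },
        PERFUSION_AMPLITUDE: {
            "map_medians": [0.043, 0.040, 0.040, 0.046, 0.041,
                            0.044, 0.040, 0.045, 0.044, 0.042],
            "map_iqrs": [0.035, 0.033, 0.033, 0.037, 0.034,
                         0.036, 0.034, 0.037, 0.036, 0.035],
            "error_medians": [0.021, 0.022, 0.021, 0.023, 0.021,
                              0.021, 0.021, 0.021, 0.021, 0.021],
            "error_iqrs": [0.006, 0.006, 0.005, 0.006, 0.006,
                           0.005, 0.006, 0.006, 0.006, 0.006],
        },
        PERFUSION_TIMING: {
            "map_medians": [-13.30, -44.28, -10.86, -47.53, 11.33,
                            -24.21, -49.67, -25.45, -12.93, 32.96],
            "map_iqrs": [319.46, 397.53, 410.09, 336.23, 422.12,
                         313.16, 445.30, 306.63, 329.83, 343.75],
            "error_medians": [198.73, 232.63, 228.52, 204.95, 229.55,
                              187.02, 230.81, 179.49, 189.53, 201.27],
            "error_iqrs": [209.77, 221.85, 232.49, 217.50, 236.33,
                           211.93, 237.73, 210.06, 206.17, 212.00],
        },
    },
}
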