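# lungboot

Voxel-wise statistical error maps for quantitative functional lung cine
imaging, from a **single scan**, by bootstrapping residuals.

Free-breathing, self-gated functional lung MRI condenses an acquisition into
one reconstructed pseudo-breath and one pseudo-heartbeat (20 phase images
each). Fitting the first temporal harmonic in every voxel,

    s(t) = a0 + |c1| cos(2π t / N + arg c1) + r(t),

yields three quantitative maps — ventilation V = 2·Re c1/(a0 + Re c1) in
mL air/mL lung parenchyma, perfusion amplitude |c1|/S_ref normalised to an
aortic blood ROI, and perfusion timing wrap(arg c1 − φ_ref)/(2π)·T_RR in ms.
Repeating the whole examination to learn the uncertainty of those maps is
rarely possible in patients. Instead, the residuals r(t) are randomly
permuted along the phase axis, added back to the model, and the maps are
re-estimated; over B = 2000 such replicates the per-voxel SD is an estimate
of the statistical error of each map — no second scan needed. The package
is aimed at physicists and engineers developing or quality-controlling
functional lung MRI pipelines.

The package contains

* `phantom` — a digital cine phantom with known ground truth (lung/aorta
  geometry, calibrated ventilation/perfusion fields, white noise scaling as
  1/√n_avg, repeated scans with variable breathing depth);
* `harmonic` — `FirstHarmonicModel(series).fit()` → results object with
  `a0`, `c1`, `fittedvalues`, residuals, and the map constructors;
* `funcmaps` — the three parameter maps with validity masks;
* `boot` — the bootstrap engine (`bootstrap_error_map`, `error_map_ci`);
* `repeated` — gold-standard error over repeated scans and the
  breathing-depth (mean ± SD) scan-exclusion rule;
* `metrics` — Tukey-hinge median/IQR, error CDFs, precision/accuracy of the
  median error;
* `pipeline` — the end-to-end synthetic validation experiment;
* a `lungboot` CLI (`simulate`, `maps`, `bootstrap`, `gse`, `experiment`,
  `table1-check`).

## Worked example

```python
import numpy as np
from lungboot import (BootConfig, RESPIRATORY, CARDIAC, make_phantom,
                      simulate_cine, FirstHarmonicModel, masked_median_iqr)

phantom = make_phantom(seed=1)                       # 64x64, known truth
resp = simulate_cine(phantom, RESPIRATORY, n_avg=6, seed=2)
card = simulate_cine(phantom, CARDIAC, n_avg=6, seed=3)

fit = FirstHarmonicModel(resp).fit()
vent = fit.ventilation_map()
err = fit.bootstrap_error_map("ventilation", cfg=BootConfig(B=2000, seed=4))

lung = phantom.lung_mask
print("ventilation median (IQR):", masked_median_iqr(vent, lung))
print("bootstrap error median  :", masked_median_iqr(err, lung)[0])

perf = FirstHarmonicModel(card).fit().perfusion_amplitude_map(phantom.aorta_roi)
print("perfusion amplitude med :", masked_median_iqr(perf, lung)[0])
```

prints (seed-exact):

```
ventilation median (IQR): (0.21978623224545799, 0.09654145903065103)
bootstrap error median  : 0.011658790525407638
perfusion amplitude med : 0.027864959302895714
```

i.e. a healthy-lung ventilation of ≈ 0.22 mL/mL with a single-scan
statistical error of ≈ 0.012 at six averages, and a perfusion amplitude of
≈ 0.028 of the aortic blood signal — all recovered from one simulated scan
pair and matching the phantom's ground-truth calibration.

The same from the shell:

```bash
lungboot simulate --grid 64 --n-scans 2 --n-avg 6 --seed 1 --out sim/
lungboot bootstrap --series sim/scan00_resp.nii --masks sim/masks.nii \
    --kind ventilation --B 2000 --seed 4 --out boot/
```

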