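# Methods

## Problem and model

Free-breathing, self-gated functional lung MRI reconstructs two cine series
per examination: N = 20 phase images spanning one pseudo-breath and N = 20
spanning one pseudo-heartbeat. In every voxel the signal over the
reconstructed cycle is modelled as a DC term plus a single complex harmonic,

    s(t) = a0 + |c1| cos(2π t / N + arg c1) + r(t),   t = 0 … N−1,

estimated by the temporal DFT with the normalisation a0 = bin0/N,
c1 = 2·bin1/N, so that |c1| is the physical cosine amplitude. The higher
DFT components r(t) — noise, artifacts, model inadequacy — are the
*residuals*. Three quantitative maps derive from the fit:

* **Ventilation** V = (S_exp − S_ins)/S_exp with S_exp = a0 + Re c1 and
  S_ins = a0 − Re c1, i.e. V = 2 Re c1 / (a0 + Re c1), in mL air per mL lung
  parenchyma. Phase 0 of the respiratory cycle is expiration (signal
  maximum), so Re c1 is the signed ventilation signal. Voxels with
  S_exp ≤ 0 are flagged invalid (NaN + mask) rather than clamped or zeroed:
  implausible values must stay visible. A magnitude mode (|c1| instead of
  Re c1) is available when the phase alignment of a reconstruction is
  unknown.
* **Perfusion amplitude** |c1| / S_ref, dimensionless, with S_ref the mean
  DC signal of a fully blood-filled reference ROI in the descending aorta.
  Normalising by the ROI's DC level (rather than by its own first-harmonic
  amplitude, also implemented) interprets "fully blood-filled" as the
  100%-blood signal reference; the two conventions differ only by a global
  factor.
* **Perfusion timing** wrap(arg c1 − φ_ref)/(2π) · T_RR in ms, with
  φ_ref = arg Σ_ROI c1 (the argument of the complex ROI mean, robust to
  phase wrapping inside the ROI) and the wrap interval [−T_RR/2, T_RR/2),
  half-open at the positive end (a tie at exactly +π maps to −π). The sign
  convention is declared, not physically derived: a positive value means a
  larger wrapped phase than the reference under the e^{−i2πt/N} analysis
  convention.

## Bootstrapping residuals

The statistical error of each map is estimated from a *single* scan:

1. fit the first-harmonic model voxel-wise;
2. residuals = data − model;
3. permute each voxel's N residuals along the phase axis and add them back
   to the model (synthetic series);
4. recompute the functional map;
5. repeat 3–4 B = 2000 times; the per-voxel sample SD (ddof = 1) over the
   stack is the **bootstrap error map**.

Shuffling defaults to independent per-voxel permutations; a shared-permutation
mode (one reordering for the whole image) preserves spatial noise
correlation and is kept as an option because the choice cannot be settled
from first principles. Sampling defaults to permutation without
replacement ("shuffling"); classical with-replacement residual resampling is
available. In permutation mode the temporal mean of every synthetic series
equals the original a0 *exactly* (the multiset of residuals is preserved and
a0 is carried over rather than re-summed), so all bootstrap variation enters
through c1.

Reproducibility of the error maps themselves is quantified by recomputing
the error map R = 1000 times with independent permutations and taking the
per-voxel width of the 95% confidence interval (97.5th − 2.5th percentile)
of the R error values. Since each error value is an SD over B replicates,
the CI width shrinks as 1/√B; quadrupling B halves the median width.

Implementation notes: only a0 and c1 of each synthetic series are needed, so
step 4 updates c1 directly (c1_b = c1 + Σ_t r_π(t) w_t with the DFT weights
w) instead of re-running a full FFT; the stack statistics are accumulated
streaming as deviations from the original-scan map, which is identical to
the stored-stack computation up to round-off and remains exact when the
residuals are ~machine-epsilon (a naive sum-of-squares accumulator loses
that regime to cancellation). Sub-seeds for every replicate derive from the
master seed through `numpy.random.SeedSequence` spawn keys
(`lungboot._seeds`), so runs are bit-reproducible and replicates independent.

The permutation bootstrap carries a small known downward bias: the residuals
contain N − 3 noise degrees of freedom (bins 0 and 1 are removed by the
fit), and the permutation variance of a zero-sum linear statistic scales
with Σr²/(N − 1), giving an expected SD ratio of √((N−3)/(N−1)) ≈ 0.946 at
N = 20. The observed bootstrap-to-truth median ratios of ≈ 0.92–0.94 on the
phantom match this; no inflation factor is applied because the underlying
procedure does not apply one.

## Gold standard and breathing-depth rule

With repeated scans available, the per-voxel sample SD (ddof = 1) of the
registered maps across scans is the gold-standard error (GSE). Because the
ventilation estimate scales with breathing depth, scans whose depth —
100·(A_max − A_min)/A_max from per-phase lung areas, expiration area as the
denominator — falls strictly outside mean ± SD (ddof = 1) of the scan set
are excluded from the GSE. The interval is closed: values exactly on a
bound stay in.

## Summary metrics

Medians and IQRs over the lung use Tukey hinges (quartiles = medians of the
lower/upper halves, halves sharing the middle value for odd n). This is the
only common quartile convention that reproduces the published precision
figures of the 10-scan repeatability study from their printed per-scan
inputs, which pins it. *Precision* of the median error is the hinge IQR of
the per-scan median errors; *accuracy* is the median over scans of
(GSE median − per-scan bootstrap median), sign retained. Report rounding is
half-up at the granularity of the published table; all internal computation
is full precision. Aggregate medians recomputed from the *printed* (rounded)
per-scan values can land exactly on a half-unit of the last printed digit
(e.g. the six-average perfusion-amplitude median over maps, 0.0275); the
recomputation is therefore compared at half-a-printed-unit tolerance.

## Digital phantom

The phantom provides ground truth that the estimators can be checked
against exactly. Geometry: two half-elliptical lungs (flat diaphragm line),
a circular aorta ROI between them, inside an elliptical body; all
parameterised relative to the grid (minimum 32×32, default 64×64). Fields
are smooth log-normal textures (Gaussian-filtered white noise, median-centred
over the lung) calibrated to healthy-subject lung medians: ventilation 0.22
mL/mL, perfusion amplitude 0.028, perfusion timing −82 ms at T_RR = 1000 ms.
Baselines: lung parenchyma 0.4, soft tissue 1.0, aortic blood 3.0 (arbitrary
units) — the low lung value reflects the low proton density and fast decay
that make noise the dominant error source in this application.

A voxel with ventilation v modulates as a0(1 + m cos 2πt/N) with
m = v/(2 − v), which makes the ventilation formula exact by construction;
cardiac voxels modulate with amplitude perf_amp·S_ref/a0 and phase equal to
the ground-truth phase field (the aorta itself pulses at phase 0 and is the
timing reference). Noise is additive white Gaussian with SD
σ/√n_avg, σ = 0.025 by default — the high-SNR approximation of magnitude
(Rician) noise, and the regime in which residual shuffling is exactly the
right error model. At n_avg = 6 this yields a median ventilation error of
≈ 0.012 on the phantom, the same order as in vivo values; perfusion errors
come out smaller than in vivo because a single noise level serves both
series, which is a deliberate simplification.

`depth_scale` multiplies both the ventilation modulation and the lung-area
excursion of a scan; depth_scale = 1 corresponds to the phantom's nominal
24.3% area change, so simulated breathing depths are measured on the same
percent scale as real ones. Repeated-scan sets draw depth scales from a
zero-truncated Gaussian; the default experiment uses a 2% relative spread.
That is deliberately *below* in-vivo variability (≈ 23% relative): the
repeated-scan validation isolates noise propagation — the one error source
the bootstrap is designed to estimate — so depth-induced ventilation
variance must stay negligible against it. The depth-exclusion rule is still
exercised (mean ± SD always trims the tails of a Gaussian sample), and the
in-vivo depth statistics enter the worked-example arithmetic directly.

What the phantom does not emulate: k-space sampling and reconstruction,
coil sensitivities, gating/binning errors, registration artifacts,
structured or spatially correlated ("coloured") residuals. Passing the
calibration tests therefore demonstrates correctness of the estimator under
independent white residuals — the method's stated precondition — not
robustness to artifact-dominated data.

## Validation experiments and problem sizes

* **Permutation oracle** — one voxel, N = 4: the engine at B = 20000 must
  match the SD over all 4! = 24 equally weighted permutations within 3%
  (sampling fluctuation at B = 20000 is ≈ 0.5%).
* **Monte-Carlo calibration** — 64×64 phantom, B = 2000, n_avg ∈ {6, 3, 1}:
  median bootstrap error over the lung within 15% of the per-voxel SD over
  200 freshly simulated noise realizations, for all three map kinds.
* **GSE agreement** — 10-scan synthetic set per n_avg: median GSE (after
  depth exclusion) within 15% of the single-scan median bootstrap error;
  error medians strictly increase as averaging drops 6 → 3 → 1 (expected
  √6 ≈ 2.45 ratio between the extremes).
* **CI reproducibility** — 32×32 phantom, R = 100: median CI width finite
  and halving (±0.1) when B goes 500 → 2000.

The 32×32 grid for the CI study and 200 Monte-Carlo realizations keep the
full validation suite at a few minutes on one core while leaving every
tolerance dominated by the systematic effects being tested, not by sampling
noise.

## Known limitations

* Additive-Gaussian noise only; no Rician floor, no coloured residuals.
* Single-slice 2D; no through-plane motion, no registration module (real
  repeated scans must be registered upstream; maps are accepted
  pre-aligned).
* One noise level for both respiratory and cardiac series, whereas real
  reconstructions average the two very differently.
* The perfusion-timing sign convention is declared, not validated against
  hardware phase conventions.
* The bootstrap inherits the first-harmonic model: if the model is
  inadequate (e.g. complex pulse waves in large vessels), both the map and
  its error estimate are biased — error maps flag uncertainty, they do not
  certify accuracy of the model itself.
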