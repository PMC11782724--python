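"""Phantom generator: calibration, determinism, noise statistics."""

import numpy as np
import pytest

from lungboot import CARDIAC, RESPIRATORY, make_phantom, simulate_cine, simulate_scan_set
from lungboot._seeds import rng_for
from lungboot.phantom import PhantomConfig, draw_depths, noiseless_cine


def test_ground_truth_medians_match_calibration():
    """Lung medians hit the healthy-subject values the phantom is built for."""
    ph = make_phantom(seed=1)
    lung = ph.lung_mask
    assert np.median(ph.vent_true[lung]) == pytest.approx(0.22, abs=0.02)
    assert np.median(ph.perf_amp_true[lung]) == pytest.approx(0.028, abs=0.005)
    assert np.median(ph.timing_true_ms[lung]) == pytest.approx(-82.0, abs=10.0)


def test_phantom_mask_and_range_invariants():
    ph = make_phantom(seed=3)
    assert ph.lung_mask.any()
    assert not (ph.lung_mask & ph.aorta_roi).any()
    assert not (ph.lung_mask & ~ph.body_mask).any()
    assert not (ph.aorta_roi & ~ph.body_mask).any()
    assert (ph.baseline_signal[ph.body_mask] > 0).all()
    assert (ph.baseline_signal[~ph.body_mask] == 0).all()
    v = ph.vent_true
    assert (v[ph.lung_mask] >= 0).all() and (v[ph.lung_mask] < 1).all()
    assert (v[~ph.lung_mask] == 0).all()
    assert (ph.perf_amp_true >= 0).all()
    phi = ph.perf_phase_true
    assert (phi > -np.pi - 1e-12).all() and (phi <= np.pi).all()


def test_phantom_deterministic_and_seed_sensitive():
    a = make_phantom(seed=11)
    b = make_phantom(seed=11)
    c = make_phantom(seed=12)
    for name in ("baseline_signal", "vent_true", "perf_amp_true", "perf_phase_true"):
        assert np.array_equal(getattr(a, name), getattr(b, name))
    assert not np.array_equal(a.vent_true, c.vent_true)


def test_zero_vent_scale_gives_zero_ventilation():
    ph = make_phantom(PhantomConfig(vent_scale=0.0), seed=1)
    assert (ph.vent_true == 0).all()


def test_small_grid_rejected():
    with pytest.raises(ValueError, match="32x32"):
        make_phantom(PhantomConfig(grid_shape=(16, 16)), seed=0)


def test_noiseless_series_equals_model_and_recovers_dc(quiet_phantom32):
    ph = quiet_phantom32
    s = simulate_cine(ph, RESPIRATORY, seed=0)
    clean = noiseless_cine(ph, RESPIRATORY)
    assert np.array_equal(s.data, clean)
    # phase-axis mean at every voxel equals the DC ground truth
    np.testing.assert_allclose(s.data.mean(axis=-1), ph.baseline_signal, atol=1e-12)


def test_zero_depth_scale_flattens_lung_signal(quiet_phantom32):
    s = simulate_cine(quiet_phantom32, RESPIRATORY, depth_scale=0.0, seed=0)
    lung = quiet_phantom32.lung_mask
    assert np.ptp(s.data[lung], axis=-1).max() < 1e-12


def test_noise_sd_scales_with_sqrt_averages(phantom32):
    """Empirical voxel SD ratio for n_avg 4 vs 1 is 1/2 within 5%."""
    clean = noiseless_cine(phantom32, RESPIRATORY)
    sds = {}
    for n_avg in (1, 4):
        s = simulate_cine(phantom32, RESPIRATORY, n_avg=n_avg, seed=42)
        noise = (s.data - clean)[phantom32.body_mask]  # >> 1e4 samples
        assert noise.size >= 1e4
        sds[n_avg] = noise.std()
    assert sds[4] / sds[1] == pytest.approx(0.5, rel=0.05)


def test_cardiac_depth_scale_ignored_with_warning(phantom32, caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="lungboot.phantom"):
        a = simulate_cine(phantom32, CARDIAC, depth_scale=0.5, seed=9)
    assert any("depth_scale" in r.message for r in caplog.records)
    b = simulate_cine(phantom32, CARDIAC, depth_scale=1.0, seed=9)
    assert np.array_equal(a.data, b.data)


def test_unknown_cycle_kind_rejected(phantom32):
    with pytest.raises(ValueError, match="cycle_kind"):
        simulate_cine(phantom32, "diastolic", seed=0)


class TestScanSet:
    def test_shapes_masks_and_depth_count(self, phantom32):
        ss = simulate_scan_set(phantom32, n_scans=4, depth_sd=0.05, seed=5)
        assert ss.n_scans == 4 and len(ss.depths_true) == 4
        for resp, card in ss.scans:
            assert resp.grid_shape == phantom32.grid_shape
            assert card.cycle_kind == CARDIAC and resp.cycle_kind == RESPIRATORY

    def test_zero_depth_sd_degenerate(self, phantom32):
        ss = simulate_scan_set(phantom32, n_scans=3, depth_mean=0.8, depth_sd=0.0,
                               seed=5)
        assert np.all(ss.depths_true == 0.8)

    def test_too_few_scans_rejected(self, phantom32):
        with pytest.raises(ValueError, match="2 scans"):
            simulate_scan_set(phantom32, n_scans=1, seed=0)

    def test_scans_have_independent_noise(self, phantom32):
        ss = simulate_scan_set(phantom32, n_scans=2, seed=5)
        assert not np.array_equal(ss.scans[0][0].data, ss.scans[1][0].data)

    def test_depth_sampling_distribution(self):
        """Sample mean of 1000 truncated-Gaussian draws within 3 SE of the mean."""
        d = draw_depths(rng_for(123, 3), 1000, depth_mean=0.243, depth_sd=0.056)
        assert (d >= 0).all()
        se = 0.056 / np.sqrt(1000)
        assert abs(d.mean() - 0.243) < 3 * se
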