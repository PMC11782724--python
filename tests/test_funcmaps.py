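"""Functional maps: formulas, conventions, invariances, noiseless recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungboot import (
    CARDIAC,
    RESPIRATORY,
    fit_first_harmonic,
    perfusion_amplitude_map,
    perfusion_timing_map,
    simulate_cine,
    ventilation_map,
)
from lungboot.funcmaps import wrap_phase
from lungboot.harmonic import HarmonicFitResults
from tests.conftest import make_series


def _fit(a0, c1, kind=CARDIAC, t_rr=1000.0):
    a0 = np.atleast_2d(np.asarray(a0, dtype=float))
    c1 = np.atleast_2d(np.asarray(c1, dtype=complex))
    return HarmonicFitResults(
        a0=a0, c1=c1, n_phases=20, cycle_kind=kind, cycle_duration_ms=t_rr
    )


class TestVentilation:
    def test_direct_formula(self):
        # S_exp = 1.0, S_ins = 0.8  =>  V = 0.2
        fit = _fit([[0.9]], [[0.1 + 0j]], kind=RESPIRATORY)
        pm = ventilation_map(fit)
        assert pm.values[0, 0] == pytest.approx(0.2, abs=1e-12)

    def test_zero_modulation_gives_zero(self):
        pm = ventilation_map(_fit([[1.0]], [[0j]], kind=RESPIRATORY))
        assert pm.values[0, 0] == 0.0

    def test_invalid_voxels_masked_not_zeroed(self):
        fit = _fit([[0.5, 0.1]], [[0.1 + 0j, -0.2 + 0j]], kind=RESPIRATORY)
        pm = ventilation_map(fit)
        assert pm.mask[0, 0] and not pm.mask[0, 1]
        assert np.isnan(pm.values[0, 1])

    def test_cardiac_fit_rejected(self):
        with pytest.raises(ValueError, match="respiratory"):
            ventilation_map(_fit([[1.0]], [[0j]], kind=CARDIAC))

    def test_magnitude_mode_ignores_phase(self):
        fit = _fit([[1.0]], [[0.1j]], kind=RESPIRATORY)
        assert ventilation_map(fit, mode="real").values[0, 0] == 0.0
        assert ventilation_map(fit, mode="magnitude").values[0, 0] == pytest.approx(
            0.2 / 1.1
        )


class TestPerfusion:
    roi = np.array([[False, True]])

    def test_amplitude_normalised_by_roi_dc(self):
        fit = _fit([[1.0, 4.0]], [[0.2 + 0j, 0j]])
        pm = perfusion_amplitude_map(fit, self.roi)
        assert pm.values[0, 0] == pytest.approx(0.05)
        assert pm.reference_meta["s_ref"] == 4.0

    def test_zero_harmonic_gives_zero_map(self):
        pm = perfusion_amplitude_map(_fit([[1.0, 2.0]], [[0j, 0j]]), self.roi)
        assert (pm.values == 0).all()

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            perfusion_amplitude_map(_fit([[1.0, 2.0]], [[0j, 0j]]),
                                    np.zeros((1, 2), bool))

    def test_undefined_reference_phase_rejected(self):
        with pytest.raises(ValueError, match="reference phase"):
            perfusion_timing_map(_fit([[1.0, 2.0]], [[0.1 + 0j, 0j]]), self.roi)

    @pytest.mark.parametrize(
        "dphi,expected_ms",
        [(0.0, 0.0), (np.pi / 2, 250.0), (3 * np.pi / 2, -250.0),
         (-np.pi / 4, -125.0)],
    )
    def test_timing_formula_and_wrap(self, dphi, expected_ms):
        fit = _fit([[1.0, 2.0]], [[0.1 * np.exp(1j * dphi), 0.3 + 0j]], t_rr=1000.0)
        pm = perfusion_timing_map(fit, self.roi)
        assert pm.values[0, 0] == pytest.approx(expected_ms, abs=1e-9)

    def test_timing_within_half_cycle_bounds(self):
        rng = np.random.default_rng(0)
        c1 = 0.1 * np.exp(1j * rng.uniform(-np.pi, np.pi, size=(1, 50)))
        c1[0, -1] = 0.3 + 0j
        roi = np.zeros((1, 50), bool)
        roi[0, -1] = True
        pm = perfusion_timing_map(_fit(np.ones((1, 50)), c1, t_rr=800.0), roi)
        assert (pm.values >= -400.0).all() and (pm.values < 400.0).all()

    def test_timing_antisymmetry(self):
        phis = np.array([[0.3, 0.9, -1.2, 0.0]])
        roi = np.array([[False, False, False, True]])
        pos = _fit(np.ones((1, 4)), 0.1 * np.exp(1j * phis))
        neg = _fit(np.ones((1, 4)), 0.1 * np.exp(-1j * phis))
        tp = perfusion_timing_map(pos, roi).values
        tn = perfusion_timing_map(neg, roi).values
        np.testing.assert_allclose(tn, -tp, atol=1e-9)

    @given(st.floats(1e-3, 1e3))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, k):
        """Both perfusion maps and the ventilation ratio are unchanged when
        the whole series is scaled by k > 0."""
        base = _fit([[1.0, 4.0]], [[0.2 * np.exp(0.4j), 0.5 + 0j]])
        scaled = _fit(k * base.a0, k * base.c1)
        for f in (perfusion_amplitude_map, perfusion_timing_map):
            np.testing.assert_allclose(
                f(scaled, self.roi).values, f(base, self.roi).values,
                rtol=1e-9, atol=1e-9,
            )
        vb = _fit([[1.0]], [[0.1 + 0j]], kind=RESPIRATORY)
        vs = _fit(k * vb.a0, k * vb.c1, kind=RESPIRATORY)
        np.testing.assert_allclose(
            ventilation_map(vs).values, ventilation_map(vb).values, rtol=1e-9
        )


def test_wrap_phase_interval_halfopen():
    assert wrap_phase(np.pi) == pytest.approx(-np.pi)
    assert wrap_phase(-np.pi) == pytest.approx(-np.pi)
    assert wrap_phase(0.999 * np.pi) == pytest.approx(0.999 * np.pi)


def test_noiseless_phantom_recovery(quiet_phantom32):
    """On a zero-noise phantom the full pipeline returns the ground truth to
    float tolerance (generator/estimator consistency)."""
    ph = quiet_phantom32
    lung = ph.lung_mask
    fr = fit_first_harmonic(simulate_cine(ph, RESPIRATORY, seed=0))
    fc = fit_first_harmonic(simulate_cine(ph, CARDIAC, seed=0))
    vm = ventilation_map(fr)
    am = perfusion_amplitude_map(fc, ph.aorta_roi)
    tm = perfusion_timing_map(fc, ph.aorta_roi)
    np.testing.assert_allclose(vm.values[lung], ph.vent_true[lung], atol=1e-9)
    np.testing.assert_allclose(am.values[lung], ph.perf_amp_true[lung], atol=1e-9)
    np.testing.assert_allclose(tm.values[lung], ph.timing_true_ms[lung], atol=1e-9)
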