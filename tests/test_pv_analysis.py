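import numpy as np
import pytest

from corohemo.pv_analysis import (CalibrationFactors, PVMetrics, ThermoInput,
                                  apply_calibration, calibrate_alpha,
                                  calibrate_parallel, conductance_co,
                                  loop_area, pv_metrics, thermodilution_co)
from corohemo.signal_conditioning import CycleSet
from corohemo.waveform_io import Trace


def thermo_curve(x, fs=1000.0):
    return Trace(np.asarray(x, float), fs, "°C", "thermistor")


class TestThermodilution:
    def test_rectangular_pulse_closed_form(self):
        # 0.5 degC for 6 s -> integral 3 degC*s; 10 ml * 30 degC / 3 = 100 ml/s
        fs = 1000.0
        x = np.zeros(8000)
        x[:6000] = 0.5
        co = thermodilution_co(ThermoInput(10.0, 37.0, 7.0, thermo_curve(x, fs), 1.0))
        assert co == pytest.approx(6.0, rel=1e-3)

    def test_linear_in_injectate_volume(self):
        fs = 1000.0
        x = np.zeros(8000)
        x[:6000] = 0.5
        co1 = thermodilution_co(ThermoInput(10.0, 37.0, 7.0, thermo_curve(x, fs)))
        co2 = thermodilution_co(ThermoInput(20.0, 37.0, 7.0, thermo_curve(x, fs)))
        assert co2 == pytest.approx(2 * co1, rel=1e-12)

    def test_triangular_pulse_matches_analytic_integral(self):
        # trapezoid rule is exact on a piecewise-linear curve
        fs = 250.0
        up = np.linspace(0, 0.8, 1000, endpoint=False)
        down = np.linspace(0.8, 0.0, 2001)
        x = np.concatenate([up, down, np.zeros(500)])
        integral = np.trapezoid(x, dx=1 / fs)
        expect = 15.0 * 30.0 / integral * 60 / 1000
        got = thermodilution_co(ThermoInput(15.0, 37.0, 7.0, thermo_curve(x, fs)))
        assert got == pytest.approx(expect, rel=1e-3)

    def test_curve_not_returned_to_baseline_rejected(self):
        x = np.full(1000, 0.5)
        with pytest.raises(ValueError, match="5%"):
            thermodilution_co(ThermoInput(10.0, 37.0, 7.0, thermo_curve(x)))

    def test_nonpositive_integral_rejected(self):
        x = np.zeros(1000)
        with pytest.raises(ValueError, match="integral"):
            thermodilution_co(ThermoInput(10.0, 37.0, 7.0, thermo_curve(x)))


class TestCalibration:
    def test_alpha_is_stated_ratio(self):
        assert calibrate_alpha(5.0, 4.0) == pytest.approx(1.25)
        assert calibrate_alpha(3.3, 3.3) == 1.0

    def test_alpha_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            calibrate_alpha(0.0, 4.0)
        with pytest.raises(ValueError):
            calibrate_alpha(5.0, -1.0)

    def test_parallel_volume_is_difference(self):
        assert calibrate_parallel(100.0, 130.0) == 30.0
        assert calibrate_parallel(100.0, 100.0) == 0.0

    def test_apply_identity(self):
        t = Trace(np.array([60.0, 61.0, 62.0]), 200.0, "a.u.", "v")
        out = apply_calibration(t, CalibrationFactors(1.0, 0.0))
        np.testing.assert_array_equal(out.samples, t.samples)
        assert out.unit == "ml"

    def test_apply_scale_and_offset(self):
        t = Trace(np.full(10, 60.0), 200.0, "a.u.", "v")
        out = apply_calibration(t, CalibrationFactors(2.0, 10.0))
        np.testing.assert_allclose(out.samples, 110.0)

    def test_apply_rejects_wrong_unit(self):
        t = Trace(np.full(10, 60.0), 200.0, "mmHg", "v")
        with pytest.raises(ValueError, match="unit"):
            apply_calibration(t, CalibrationFactors(1.0, 0.0))

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            CalibrationFactors(alpha=-1.0, v_parallel=0.0)


def ellipse_loop(n=400, a=35.0, b=50.0, vc=95.0, pc=60.0, phase=0.0):
    th = 2 * np.pi * np.arange(n) / n + phase
    return pc + b * np.sin(th), vc + a * np.cos(th)


class TestLoopArea:
    def test_rectangle_area(self):
        v = np.array([60.0, 130, 130, 130, 60, 60, 60, 130], dtype=float)
        # traverse the rectangle 60..130 ml x 10..110 mmHg
        v = np.array([60, 60, 60, 130, 130, 130, 130, 60], dtype=float)
        p = np.array([10, 60, 110, 110, 110, 60, 10, 10], dtype=float)
        assert loop_area(p, v) == pytest.approx(70.0 * 100.0)

    def test_ellipse_area_closed_form(self):
        p, v = ellipse_loop(n=400)
        assert loop_area(p, v) == pytest.approx(np.pi * 35.0 * 50.0, rel=0.005)

    def test_invariant_to_start_index_and_orientation(self):
        p, v = ellipse_loop(n=256)
        base = loop_area(p, v)
        assert loop_area(np.roll(p, 37), np.roll(v, 37)) == pytest.approx(base, rel=1e-12)
        assert loop_area(p[::-1], v[::-1]) == pytest.approx(base, rel=1e-12)

    def test_degenerate_loop_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            loop_area(np.zeros(5) + 1.0, np.zeros(5) + 1.0)


class TestPVMetrics:
    def make_cyclic(self, n_loops=3, n=400):
        p, v = ellipse_loop(n=n)
        P = np.tile(p, n_loops + 1)
        V = np.tile(v, n_loops + 1)
        b = np.arange(n_loops + 1) * n
        fs = 200.0
        return (Trace(P, fs, "mmHg", "p"), Trace(V, fs, "ml", "v"),
                CycleSet(b, fs))

    def test_ellipse_loop_metrics(self):
        # landmark convention: first sample inside a 2%-of-excursion band of
        # the extremum, so smooth-loop volumes sit within that band
        p, v, cyc = self.make_cyclic()
        m = pv_metrics(p, v, cyc)
        band = 0.02 * 70.0
        assert 130.0 - band <= m.edv <= 130.0
        assert 60.0 <= m.esv <= 60.0 + band
        assert m.sv == pytest.approx(70.0, abs=2 * band)
        assert m.sw == pytest.approx(np.pi * 35 * 50, rel=0.005)
        assert m.hr == pytest.approx(60.0 * 200.0 / 400.0)

    def test_co_identity_exact(self):
        p, v, cyc = self.make_cyclic()
        m = pv_metrics(p, v, cyc)
        assert m.co == m.sv * m.hr / 1000.0

    def test_length_mismatch_rejected(self):
        p, v, cyc = self.make_cyclic()
        short = Trace(v.samples[:-1], v.fs, "ml", "v")
        with pytest.raises(ValueError, match="length"):
            pv_metrics(p, short, cyc)

    def test_pvmetrics_invariants_enforced(self):
        with pytest.raises(ValueError):
            PVMetrics(edp=10, esp=100, edv=100, esv=120, sv=-20, sw=100,
                      hr=60, co=-1.2)


class TestConductanceCO:
    def test_uncalibrated_sv_times_hr(self):
        # sawtooth volume: 60 -> 130 over each cycle of 1 s at 200 Hz
        n = 200
        v = np.tile(np.linspace(60, 130, n), 4)
        cyc = CycleSet(np.arange(4) * n, fs=200.0)
        co = conductance_co(Trace(v, 200.0, "a.u.", "v"), cyc)
        assert co == pytest.approx(70.0 * 60.0 / 1000.0, rel=1e-6)
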