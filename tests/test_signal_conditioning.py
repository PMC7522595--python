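import numpy as np
import pytest

from corohemo.signal_conditioning import (CycleSet, NoCyclesError, beat_stats,
                                          detect_cycles, downsample,
                                          ensemble_average, sg_smooth)
from corohemo.waveform_io import Trace


def trace(x, fs=1000.0, unit="mmHg"):
    return Trace(np.asarray(x, float), fs, unit, "t")


class TestDownsample:
    def test_dc_level_preserved(self):
        out = downsample(trace(np.full(3000, 100.0)), 200.0)
        np.testing.assert_allclose(out.samples, 100.0, rtol=1e-9)
        assert out.fs == 200.0

    def test_factor_five_length(self):
        out = downsample(trace(np.random.default_rng(0).normal(size=3000)), 200.0)
        assert out.n == 600

    def test_sine_amplitude_within_one_percent(self):
        # 10 Hz sine, well below the 100 Hz Nyquist of the target rate
        t = np.arange(4000) / 1000.0
        out = downsample(trace(np.sin(2 * np.pi * 10 * t)), 200.0)
        t200 = np.arange(out.n) / 200.0
        ref = np.sin(2 * np.pi * 10 * t200)
        core = slice(40, out.n - 40)  # exclude filter edge transients
        amp = np.max(np.abs(out.samples[core]))
        assert abs(amp - 1.0) < 0.01
        np.testing.assert_allclose(out.samples[core], ref[core], atol=0.01)

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            downsample(trace(np.zeros(100) + 1.0), 300.0)

    def test_unit_and_label_carried(self):
        out = downsample(trace(np.full(1000, 2.0), unit="cm/s"), 200.0)
        assert out.unit == "cm/s"


def brute_force_savgol(x, window, order):
    """Independent oracle: per-window least-squares polynomial fit evaluated
    at the window centre; polynomial extrapolation of the first/last window
    at the edges."""
    half = window // 2
    n = x.size
    out = np.empty(n)
    for i in range(half, n - half):
        idx = np.arange(i - half, i + half + 1)
        coef = np.polynomial.polynomial.polyfit(idx - i, x[idx], order)
        out[i] = coef[0]
    head = np.polynomial.polynomial.polyfit(np.arange(window), x[:window], order)
    out[:half] = np.polynomial.polynomial.polyval(np.arange(half), head)
    tail = np.polynomial.polynomial.polyfit(np.arange(window), x[-window:], order)
    out[-half:] = np.polynomial.polynomial.polyval(
        np.arange(window - half, window), tail)
    return out


class TestSavitzkyGolay:
    def test_cubic_polynomial_reproduced_exactly(self):
        i = np.arange(200, dtype=float)
        x = 0.002 * i**3 - 0.4 * i**2 + 3 * i - 7
        out = sg_smooth(trace(x), 11, 3)
        np.testing.assert_allclose(out.samples, x, rtol=1e-9, atol=1e-9)

    def test_constant_unchanged(self):
        out = sg_smooth(trace(np.full(50, 42.0)), 11, 3)
        np.testing.assert_allclose(out.samples, 42.0, rtol=1e-12)

    def test_matches_brute_force_oracle_on_noise(self, rng):
        x = rng.normal(size=300)
        out = sg_smooth(trace(x), 11, 3)
        np.testing.assert_allclose(out.samples, brute_force_savgol(x, 11, 3),
                                   rtol=1e-9, atol=1e-9)

    def test_linearity(self, rng):
        x, y = rng.normal(size=(2, 256))
        a, b = 1.7, -0.3
        lhs = sg_smooth(trace(a * x + b * y), 11, 3).samples
        rhs = a * sg_smooth(trace(x), 11, 3).samples + b * sg_smooth(trace(y), 11, 3).samples
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("window,order", [(10, 3), (11, 11), (11, 12)])
    def test_invalid_parameters(self, window, order):
        with pytest.raises(ValueError):
            sg_smooth(trace(np.zeros(100) + 1.0), window, order)

    def test_length_and_fs_unchanged(self, rng):
        t = trace(rng.normal(size=123), fs=200.0)
        out = sg_smooth(t)
        assert out.n == 123 and out.fs == 200.0


def beat_template(fs=200.0, period_s=1.0, base=80.0, amp=40.0):
    """One asymmetric pressure-like beat with its minimum at sample 0."""
    n = int(round(fs * period_s))
    ph = np.arange(n) / n
    return base + amp * (np.sin(np.pi * ph) ** 2 + 0.15 * np.sin(2 * np.pi * ph))


class TestDetectCycles:
    def test_monotone_trace_has_no_cycles(self):
        with pytest.raises(NoCyclesError):
            detect_cycles(trace(np.linspace(0, 100, 400), fs=200.0))

    def test_periodic_pressure_boundaries_and_spacing(self):
        beat = beat_template()
        x = np.tile(beat, 12)  # 12 s at 1 s period
        cs = detect_cycles(trace(x, fs=200.0))
        assert cs.boundaries.size in (11, 12)
        spacing = np.diff(cs.boundaries)
        assert np.all(np.abs(spacing - 200) <= 1)

    def test_planted_minima_recovered_within_one_sample(self):
        beat = beat_template()
        x = np.tile(beat, 8)
        cs = detect_cycles(trace(x, fs=200.0))
        planted = np.arange(8) * 200 + int(np.argmin(beat))
        for b in cs.boundaries:
            assert np.min(np.abs(planted - b)) <= 1

    def test_min_period_floor_suppresses_fast_ripple(self):
        # 5 Hz ripple on top of 1 Hz beats must not create extra boundaries
        beat = beat_template()
        x = np.tile(beat, 8)
        x += 1.5 * np.sin(2 * np.pi * 5 * np.arange(x.size) / 200.0)
        cs = detect_cycles(trace(x, fs=200.0), min_period_s=0.3)
        assert np.all(np.diff(cs.boundaries) >= 0.3 * 200)


class TestEnsembleAverage:
    def test_identical_cycles_mean_equals_single_cycle(self):
        beat = beat_template()
        x = np.tile(beat, 11)
        cs = CycleSet(np.arange(11) * beat.size, fs=200.0)
        ens = ensemble_average(trace(x, fs=200.0), cs, n=10)
        assert ens.n_cycles == 10
        np.testing.assert_allclose(ens.mean_waveform, beat, rtol=1e-9)

    def test_too_few_cycles_error_reports_count(self):
        beat = beat_template()
        x = np.tile(beat, 8)
        cs = CycleSet(np.arange(8) * beat.size, fs=200.0)  # 7 cycles
        with pytest.raises(ValueError, match="7"):
            ensemble_average(trace(x, fs=200.0), cs, n=10)

    def test_units_and_fs_never_change(self):
        beat = beat_template()
        x = np.tile(beat, 11)
        cs = CycleSet(np.arange(11) * beat.size, fs=200.0)
        ens = ensemble_average(trace(x, fs=200.0, unit="cm/s"), cs, n=10)
        assert ens.unit == "cm/s" and ens.fs == 200.0

    def test_unequal_cycle_lengths_resampled_to_median(self):
        beat = beat_template()
        # cycles of length 198, 200, 202 -> median 200
        segs = [beat[:198], beat, np.concatenate([beat, beat[:2]])]
        x = np.concatenate(segs + [beat])
        b = np.cumsum([0, 198, 200, 202])
        cs = CycleSet(b, fs=200.0)
        ens = ensemble_average(trace(x, fs=200.0), cs, n=3)
        assert ens.mean_waveform.size == 200


class TestBeatStats:
    def test_simple_waveform(self):
        from corohemo.signal_conditioning import EnsembleBeat
        b = EnsembleBeat(np.array([80.0, 120.0, 100.0]), 2, 200.0, "mmHg")
        s = beat_stats(b)
        assert (s.maximum, s.minimum, s.mean) == (120.0, 80.0, 100.0)

    def test_constant_waveform(self):
        from corohemo.signal_conditioning import EnsembleBeat
        s = beat_stats(EnsembleBeat(np.full(10, 50.0), 2, 200.0, "mmHg"))
        assert s.maximum == s.minimum == s.mean == 50.0

    def test_half_sinusoid_mean_closed_form(self):
        from corohemo.signal_conditioning import EnsembleBeat
        A, B, n = 30.0, 70.0, 400
        w = B + A * np.sin(np.pi * np.arange(n) / n)
        s = beat_stats(EnsembleBeat(w, 2, 200.0, "mmHg"))
        expect = B + 2 * A / np.pi
        assert abs(s.mean - expect) / expect < 0.005
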