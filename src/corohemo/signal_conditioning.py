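"""Waveform conditioning: decimation, Savitzky-Golay smoothing, cycle
detection on pressure minima, and ensemble averaging of consecutive beats.

The conditioning chain mirrors a standard invasive-hemodynamics workflow:
1 kHz pressure/flow channels are anti-alias decimated to 200 Hz, denoised
with a Savitzky-Golay filter (window 11, polynomial order 3), segmented into
cardiac cycles at the local minima of the pressure trace, and ten consecutive
cycles are ensemble-averaged before reading off per-beat maximum / minimum /
mean values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .waveform_io import Trace

__all__ = [
    "CycleSet",
    "EnsembleBeat",
    "BeatStats",
    "downsample",
    "sg_smooth",
    "detect_cycles",
    "ensemble_average",
    "beat_stats",
    "condition_trace",
]


@dataclass
class CycleSet:
    """Cardiac-cycle boundaries: strictly increasing sample indices into a
    pressure trace, each located at a local minimum (end-diastole proxy)."""

    boundaries: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if self.boundaries.size < 2:
            raise ValueError("need >=2 boundaries to define >=1 cycle")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if not (self.fs > 0):
            raise ValueError("fs must be > 0")

    @property
    def n_cycles(self) -> int:
        return int(self.boundaries.size - 1)

    @property
    def mean_cycle_len(self) -> float:
        return float(np.mean(np.diff(self.boundaries)))


@dataclass
class EnsembleBeat:
    """Pointwise mean of several consecutive cycles, on a common length grid."""

    mean_waveform: np.ndarray
    n_cycles: int
    fs: float
    unit: str

    def __post_init__(self) -> None:
        self.mean_waveform = np.asarray(self.mean_waveform, dtype=float)
        if self.n_cycles < 2:
            raise ValueError("an ensemble needs >=2 cycles")
        if self.mean_waveform.size < 2:
            raise ValueError("empty ensemble waveform")


@dataclass
class BeatStats:
    maximum: float
    minimum: float
    mean: float

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError("require minimum <= mean <= maximum")


class NoCyclesError(ValueError):
    """Fewer than two qualifying pressure minima were found."""


def downsample(t: Trace, target_fs: float) -> Trace:
    """Anti-alias low-pass filter and decimate ``t`` to ``target_fs``.

    The source rate must be an integer multiple of the target rate; the
    signal is never resampled by interpolation.  The polyphase FIR filter
    has unit DC gain and linear-trend edge padding, so constant traces pass
    through unchanged.
    """
    if not (target_fs > 0):
        raise ValueError("target_fs must be > 0")
    ratio = t.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"source fs {t.fs} Hz is not an integer multiple of target "
            f"{target_fs} Hz (ratio {ratio})"
        )
    if q == 1:
        return t.copy_with()
    out = sps.resample_poly(t.samples, up=1, down=q, padtype="line")
    return t.copy_with(samples=out, fs=target_fs)


def sg_smooth(t: Trace, window: int = 11, order: int = 3) -> Trace:
    """Savitzky-Golay smoothing: per-window least-squares polynomial fit
    evaluated at the window centre (polynomial edge handling)."""
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if order >= window:
        raise ValueError(f"order ({order}) must be < window ({window})")
    if t.n < window:
        raise ValueError(f"trace length {t.n} shorter than window {window}")
    out = sps.savgol_filter(t.samples, window_length=window, polyorder=order,
                            mode="interp")
    return t.copy_with(samples=out)


def detect_cycles(pressure: Trace, min_period_s: float = 0.3,
                  prominence_frac: float = 0.2) -> CycleSet:
    """Locate cardiac-cycle boundaries at local minima of a pressure trace.

    Minima must be separated by at least ``min_period_s`` (a heart-rate
    ceiling; 0.3 s ~ 200 bpm) and have prominence of at least
    ``prominence_frac`` times the trace's peak-to-peak range, which rejects
    diastolic noise ripple.
    """
    if not (min_period_s > 0):
        raise ValueError("min_period_s must be > 0")
    x = pressure.samples
    ptp = float(np.max(x) - np.min(x))
    if ptp <= 0:
        raise NoCyclesError("flat pressure trace: no cycles")
    distance = max(1, int(round(min_period_s * pressure.fs)))
    idx, _ = sps.find_peaks(-x, distance=distance,
                            prominence=prominence_frac * ptp)
    if idx.size < 2:
        raise NoCyclesError(
            f"found {idx.size} qualifying pressure minima; need >=2 to "
            "define a cycle"
        )
    return CycleSet(boundaries=idx, fs=pressure.fs)


def ensemble_average(t: Trace, cycles: CycleSet, n: int = 10,
                     start: int = 0) -> EnsembleBeat:
    """Ensemble-average ``n`` consecutive cycles of ``t``.

    Cycles span ``[boundary_i, boundary_{i+1})`` (half-open; the trailing
    partial cycle is never used).  The ``n`` cycles beginning at cycle index
    ``start`` are each linearly resampled to the median cycle length, then
    averaged pointwise.
    """
    if n < 2:
        raise ValueError("need n >= 2 cycles to ensemble-average")
    avail = cycles.n_cycles - start
    if avail < n:
        raise ValueError(
            f"requested {n} cycles from cycle {start} but only "
            f"{max(avail, 0)} are available"
        )
    b = cycles.boundaries[start:start + n + 1]
    if b[-1] > t.n:
        raise ValueError("cycle boundaries extend past the end of the trace")
    lengths = np.diff(b)
    m = int(np.median(lengths))
    grid = np.arange(m) / m
    acc = np.zeros(m)
    for i in range(n):
        seg = t.samples[b[i]:b[i + 1]]
        acc += np.interp(grid, np.arange(seg.size) / seg.size, seg)
    return EnsembleBeat(mean_waveform=acc / n, n_cycles=n, fs=t.fs, unit=t.unit)


def beat_stats(b: EnsembleBeat) -> BeatStats:
    """Maximum, minimum and time-averaged mean of an ensemble beat."""
    w = b.mean_waveform
    if w.size == 0:
        raise ValueError("empty waveform")
    return BeatStats(maximum=float(np.max(w)), minimum=float(np.min(w)),
                     mean=float(np.mean(w)))


def condition_trace(raw: Trace, pressure_raw: Trace, *, target_fs: float = 200.0,
                    window: int = 11, order: int = 3, n_cycles: int = 10,
                    start_cycle: int = 0, smooth_before_average: bool = True,
                    min_period_s: float = 0.3, prominence_frac: float = 0.2,
                    ) -> tuple[EnsembleBeat, BeatStats, CycleSet]:
    """Full conditioning chain for one channel, gated on a pressure channel.

    Both the analysis channel and the gating pressure are decimated to
    ``target_fs`` and smoothed; cycles are detected on the smoothed pressure;
    the analysis channel (smoothed by default, raw if
    ``smooth_before_average=False``) is ensemble-averaged over ``n_cycles``
    consecutive cycles starting at ``start_cycle``.
    """
    p = sg_smooth(downsample(pressure_raw, target_fs), window, order)
    cycles = detect_cycles(p, min_period_s=min_period_s,
                           prominence_frac=prominence_frac)
    x = downsample(raw, target_fs)
    if smooth_before_average:
        x = sg_smooth(x, window, order)
    beat = ensemble_average(x, cycles, n=n_cycles, start=start_cycle)
    return beat, beat_stats(beat), cycles
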