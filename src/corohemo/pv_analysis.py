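"""Conductance-catheter calibration and pressure-volume loop metrics.

The conductance catheter reports a volume-proportional signal that needs two
corrections before PV-loop analysis: a dimensionless gain ``alpha`` (the
ratio of thermodilution cardiac output to the cardiac output implied by the
raw conductance signal) and a parallel-volume offset (the conductance
contribution of structures outside the blood pool, anchored to an
echocardiographic end-diastolic volume).  Calibrated volume is

    V = alpha * V_raw - V_parallel   [ml]

Per-beat metrics follow the conventions of invasive PV analysis without ECG
gating: end-diastole is the maximal-volume sample of the beat, end-systole
the minimal-volume sample, stroke work is the (unsigned) area enclosed by
the P-V loop, and cardiac output is stroke volume times heart rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_conditioning import CycleSet
from .waveform_io import Trace

__all__ = [
    "CalibrationFactors",
    "PVMetrics",
    "ThermoInput",
    "thermodilution_co",
    "calibrate_alpha",
    "calibrate_parallel",
    "apply_calibration",
    "conductance_co",
    "loop_area",
    "pv_metrics",
]


@dataclass
class CalibrationFactors:
    """Conductance gain ``alpha`` (dimensionless, > 0) and parallel-volume
    offset ``v_parallel`` (ml, subtracted after scaling)."""

    alpha: float
    v_parallel: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


@dataclass
class PVMetrics:
    """Per-condition left-ventricular metrics, averaged over the analysed beats."""

    edp: float   # end-diastolic pressure, mmHg
    esp: float   # end-systolic pressure, mmHg
    edv: float   # end-diastolic volume, ml
    esv: float   # end-systolic volume, ml
    sv: float    # stroke volume, ml
    sw: float    # stroke work (loop area), mmHg*ml
    hr: float    # heart rate, beats/min
    co: float    # native cardiac output, L/min

    def __post_init__(self) -> None:
        if self.sv < 0:
            raise ValueError(f"stroke volume must be >= 0, got {self.sv}")
        if abs(self.co - self.sv * self.hr / 1000.0) > 1e-6:
            raise ValueError("co must equal sv*hr/1000")
        if self.sw < 0:
            raise ValueError("stroke work must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k))
                for k in ("edp", "esp", "edv", "esv", "sv", "sw", "hr", "co")}


@dataclass
class ThermoInput:
    """Inputs to a Stewart-Hamilton thermodilution cardiac-output estimate."""

    injectate_volume: float      # ml of cold saline
    blood_temp: float            # degC
    injectate_temp: float        # degC
    thermistor_curve: Trace      # degC temperature deviation vs time
    computation_constant: float = 1.0  # catheter/device constant

    def __post_init__(self) -> None:
        if not (self.blood_temp > self.injectate_temp):
            raise ValueError("blood_temp must exceed injectate_temp")
        if self.injectate_volume <= 0:
            raise ValueError("injectate_volume must be > 0")


def thermodilution_co(x: ThermoInput) -> float:
    """Cardiac output (L/min) by the Stewart-Hamilton relation.

    CO = V_inj * (T_blood - T_inj) * K / integral(dT dt), with the thermistor
    washout curve integrated by the trapezoid rule.
    """
    curve = x.thermistor_curve
    dt = 1.0 / curve.fs
    integral = float(np.trapezoid(curve.samples, dx=dt))  # degC * s
    if integral <= 0:
        raise ValueError(f"thermodilution curve integral must be > 0, got {integral}")
    peak = float(np.max(curve.samples))
    tail = float(curve.samples[-1])
    if peak > 0 and tail > 0.05 * peak:
        raise ValueError(
            "thermodilution curve has not returned to <=5% of its peak; "
            "extend the recording"
        )
    co_ml_s = (x.injectate_volume * (x.blood_temp - x.injectate_temp)
               * x.computation_constant / integral)
    return co_ml_s * 60.0 / 1000.0


def calibrate_alpha(co_thermo: float, co_conductance_raw: float) -> float:
    """Gain factor: thermodilution CO over raw conductance-derived CO."""
    if co_thermo <= 0 or co_conductance_raw <= 0:
        raise ValueError("both cardiac outputs must be > 0")
    return co_thermo / co_conductance_raw


def calibrate_parallel(edv_echo: float, edv_scaled: float) -> float:
    """Parallel-volume offset: alpha-scaled conductance EDV minus echo EDV."""
    if not (np.isfinite(edv_echo) and np.isfinite(edv_scaled)):
        raise ValueError("EDV inputs must be finite")
    return edv_scaled - edv_echo


def apply_calibration(v_raw: Trace, f: CalibrationFactors) -> Trace:
    """Elementwise ``alpha * v_raw - v_parallel``; output unit is ml."""
    if v_raw.unit not in ("a.u.", "ml"):
        raise ValueError(
            f"raw conductance channel has unit {v_raw.unit!r}; expected "
            "'a.u.' (uncalibrated) or 'ml'"
        )
    return v_raw.copy_with(samples=f.alpha * v_raw.samples - f.v_parallel,
                           unit="ml")


#: Fraction of the per-cycle volume excursion used as the landmark tolerance
#: band (see _per_cycle_extrema).
_LANDMARK_TOL = 0.02


def _per_cycle_extrema(v: np.ndarray, b: np.ndarray):
    """Per-cycle end-diastolic / end-systolic sample indices of the volume
    signal.

    The volume is flat during the isovolumic phases while pressure swings by
    tens of mmHg, so a bare argmax/argmin picks an arbitrary point of that
    plateau once noise is present.  Instead, end-diastole is the first
    sample entering a small tolerance band (2% of the cycle's volume
    excursion) below the cycle maximum, and end-systole the first sample
    after end-diastole entering the band above the subsequent minimum —
    i.e. the onsets of the two plateaus.
    """
    ed_idx, es_idx = [], []
    for i in range(b.size - 1):
        seg = v[b[i]:b[i + 1]]
        tol = _LANDMARK_TOL * (np.max(seg) - np.min(seg))
        ed = int(np.flatnonzero(seg >= np.max(seg) - tol)[0])
        rest = seg[ed:]
        es = ed + int(np.flatnonzero(rest <= np.min(rest) + tol)[0])
        ed_idx.append(b[i] + ed)
        es_idx.append(b[i] + es)
    return np.array(ed_idx), np.array(es_idx)


def conductance_co(v_raw: Trace, cycles: CycleSet) -> float:
    """Cardiac output (L/min) implied by the *uncalibrated* volume channel:
    per-cycle (max - min) excursion averaged, times heart rate.  Used to
    form alpha."""
    b = cycles.boundaries
    svs = [float(np.max(v_raw.samples[b[i]:b[i + 1]])
                 - np.min(v_raw.samples[b[i]:b[i + 1]]))
           for i in range(b.size - 1)]
    hr = 60.0 * cycles.fs / cycles.mean_cycle_len
    return float(np.mean(svs)) * hr / 1000.0


def loop_area(p: np.ndarray, v: np.ndarray) -> float:
    """Unsigned area of the closed P-V polygon (shoelace formula).

    Invariant to the starting index and to traversal orientation; the loop
    is closed by joining the last point back to the first.
    """
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    if p.shape != v.shape or p.ndim != 1:
        raise ValueError("pressure and volume must be 1-D and equal length")
    if p.size < 8:
        raise ValueError(f"degenerate loop: {p.size} points (< 8)")
    return float(abs(np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p)) / 2.0)


def pv_metrics(p: Trace, v: Trace, cycles: CycleSet) -> PVMetrics:
    """Beat-averaged PV metrics over the cycles in ``cycles``.

    ``p`` and ``v`` must be aligned and share the sampling rate of the cycle
    set (cycles are detected on the LV pressure channel).  Metrics are
    computed per cycle and averaged; ``co`` is derived from the averaged
    ``sv`` and ``hr`` so the identity co = sv*hr/1000 holds exactly.
    """
    if p.n != v.n:
        raise ValueError("pressure and volume traces differ in length")
    if abs(p.fs - cycles.fs) > 1e-9 or abs(v.fs - cycles.fs) > 1e-9:
        raise ValueError("traces and cycle set must share one sampling rate")
    b = cycles.boundaries
    if b[-1] > p.n:
        raise ValueError("cycle boundaries extend past the traces")
    ed, es = _per_cycle_extrema(v.samples, b)
    sws = []
    for i in range(b.size - 1):
        sws.append(loop_area(p.samples[b[i]:b[i + 1]], v.samples[b[i]:b[i + 1]]))
    edv = float(np.mean(v.samples[ed]))
    esv = float(np.mean(v.samples[es]))
    sv = edv - esv
    hr = 60.0 * cycles.fs / cycles.mean_cycle_len
    return PVMetrics(
        edp=float(np.mean(p.samples[ed])),
        esp=float(np.mean(p.samples[es])),
        edv=edv, esv=esv, sv=sv,
        sw=float(np.mean(sws)),
        hr=hr,
        co=sv * hr / 1000.0,
    )
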