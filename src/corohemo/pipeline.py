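"""End-to-end convenience drivers combining the module stages.

These are the compositions the analysis scripts and the CLI run: condition a
recording's coronary channels to ensemble-beat statistics, and calibrate the
conductance channel then compute PV metrics, all gated on cycles detected
from the LV pressure channel.
"""

from __future__ import annotations

import numpy as np

from . import pv_analysis as pv
from . import signal_conditioning as sc
from .waveform_io import Recording

__all__ = ["condition_recording", "pv_report"]


def condition_recording(rec: Recording, channels: list[str] | None = None,
                        gate_channel: str = "lv_pressure", *,
                        target_fs: float = 200.0, window: int = 11,
                        order: int = 3, n_cycles: int = 10,
                        start_cycle: int = 0,
                        smooth_before_average: bool = True) -> dict[str, dict]:
    """Ensemble-beat statistics for each requested channel of a recording.

    Cycles are detected once on the smoothed, decimated gate (LV pressure)
    channel and reused for every analysis channel.  Returns
    ``{channel: {"max":..., "min":..., "mean":..., "n_cycles":...}}``.
    """
    if gate_channel not in rec.channels:
        raise ValueError(f"gate channel {gate_channel!r} not in recording")
    if channels is None:
        channels = [c for c in rec.channels if c != gate_channel]
    gate = sc.sg_smooth(sc.downsample(rec[gate_channel], target_fs), window, order)
    cycles = sc.detect_cycles(gate)
    out: dict[str, dict] = {}
    for ch in channels:
        x = sc.downsample(rec[ch], target_fs)
        if smooth_before_average:
            x = sc.sg_smooth(x, window, order)
        beat = sc.ensemble_average(x, cycles, n=n_cycles, start=start_cycle)
        stats = sc.beat_stats(beat)
        out[ch] = {"max": stats.maximum, "min": stats.minimum,
                   "mean": stats.mean, "unit": x.unit,
                   "n_cycles": beat.n_cycles}
    return out


def pv_report(rec: Recording, co_thermo: float, edv_echo: float, *,
              lv_pressure: str = "lv_pressure",
              conductance: str = "conductance_volume",
              target_fs: float = 200.0, window: int = 11, order: int = 3,
              n_cycles: int = 10, start_cycle: int = 0,
              ) -> tuple[pv.PVMetrics, pv.CalibrationFactors]:
    """Calibrate the conductance channel and compute PV-loop metrics.

    ``co_thermo`` is the thermodilution cardiac output (L/min) and
    ``edv_echo`` the echocardiographic end-diastolic volume (ml) used as
    calibration anchors.  Cycles come from the LV pressure channel; metrics
    are averaged over ``n_cycles`` consecutive cycles.
    """
    p = sc.sg_smooth(sc.downsample(rec[lv_pressure], target_fs), window, order)
    v_raw = sc.sg_smooth(sc.downsample(rec[conductance], target_fs), window, order)
    cycles = sc.detect_cycles(p)
    b = cycles.boundaries[start_cycle:start_cycle + n_cycles + 1]
    if b.size < n_cycles + 1:
        raise ValueError(
            f"only {cycles.n_cycles - start_cycle} cycles available; "
            f"need {n_cycles}"
        )
    window_cycles = sc.CycleSet(boundaries=b, fs=cycles.fs)

    # Calibration quantities are read from the n-cycle ensemble beat: the
    # pointwise mean suppresses the upward extreme-value bias that channel
    # noise puts on per-cycle maxima/minima.
    raw_max, raw_min = ensemble_extremes(v_raw, window_cycles, n_cycles)
    hr = 60.0 * window_cycles.fs / window_cycles.mean_cycle_len
    co_raw = (raw_max - raw_min) * hr / 1000.0
    alpha = pv.calibrate_alpha(co_thermo, co_raw)
    v_par = pv.calibrate_parallel(edv_echo, alpha * raw_max)
    factors = pv.CalibrationFactors(alpha=alpha, v_parallel=v_par)
    v = pv.apply_calibration(v_raw, factors)
    metrics = pv.pv_metrics(p, v, window_cycles)
    return metrics, factors


def ensemble_extremes(trace, cycles: sc.CycleSet, n: int) -> tuple[float, float]:
    """Max and min of the ``n``-cycle ensemble-averaged beat of a trace."""
    ens = sc.ensemble_average(trace, cycles, n=n)
    return float(np.max(ens.mean_waveform)), float(np.min(ens.mean_waveform))
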