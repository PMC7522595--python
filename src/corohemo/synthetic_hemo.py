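"""Lumped-parameter simulator of paired pump-off / maximal-support recordings
in the presence of a coronary dissection flap.

The circulation is a minimal time-varying-elastance left ventricle coupled to
a two-element Windkessel, with diode valves, a transaortic microaxial pump
modelled by a pressure-difference-clipped linear pump curve, and a coronary
branch carrying a dissection flap:

* LV: P_lv = E(t) (V_lv - V0), E(t) = e_min + (e_max - e_min) a(t) with a(t)
  a smooth two-cosine activation of period 60/hr.
* Valves: Q_in = max(0, (P_atrium - P_lv)/R_mitral),
  Q_out = max(0, (P_lv - P_ao)/R_aortic).
* Pump: Q_imp = max(0, Q_nom - k_p (P_ao - P_lv)); Q_nom is zero at P0 and
  the configured nominal flow at P8 (maximal support).
* Windkessel: C_ao dP_ao/dt = Q_out + Q_imp - (P_ao - P_venous)/R_sys - Q_cor.
* False lumen: P_false relaxes toward P_ao through the flap communication,
  quickly while filling (P_ao > P_false) and slowly while draining —
  the hematoma-confined false lumen holds its pressure, so P_false rides
  near systolic aortic pressure rather than the cycle mean.
* Flap obstruction: the true-lumen inlet resistance stiffens with the
  trans-flap gradient, R_true = R_cor_base (1 + gamma max(0, P_false -
  P_true)/10 mmHg); gamma = 0 is a small/non-obstructive flap.  The coronary
  microvascular resistance interpolates between its diastolic and systolic
  values with a(t) (systolic compression), Q_cor = (P_ao - P_venous)/(R_true
  + R_micro), and the distal true-lumen pressure is P_true = P_ao - Q_cor
  R_true (solved in closed form each step).
* Flow velocity = Q_cor / vessel_area; the conductance channel is emitted
  uncalibrated as V_raw = (V_lv + V_parallel_true)/alpha_true.

Integration is fixed-step 4th-order Runge-Kutta at the output sampling rate,
keeping runs bit-reproducible; seeded Gaussian noise is added per channel.
Ground-truth metrics are always computed from the noiseless trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .pv_analysis import PVMetrics, pv_metrics
from .signal_conditioning import BeatStats, CycleSet
from .waveform_io import Recording, Trace

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PairedSubject",
    "CH_LV_PRESSURE",
    "CH_CONDUCTANCE",
    "CH_AORTIC",
    "CH_COR_TRUE",
    "CH_COR_FALSE",
    "CH_VELOCITY",
    "simulate",
    "make_paired_cohort",
    "make_angio_traces",
]

CH_LV_PRESSURE = "lv_pressure"
CH_CONDUCTANCE = "conductance_volume"
CH_AORTIC = "aortic_pressure"
CH_COR_TRUE = "cor_true_pressure"
CH_COR_FALSE = "cor_false_pressure"
CH_VELOCITY = "cor_flow_velocity"

_UNITS = {
    CH_LV_PRESSURE: "mmHg",
    CH_CONDUCTANCE: "a.u.",
    CH_AORTIC: "mmHg",
    CH_COR_TRUE: "mmHg",
    CH_COR_FALSE: "mmHg",
    CH_VELOCITY: "cm/s",
}

_DEFAULT_NOISE = {
    CH_LV_PRESSURE: 1.0,
    CH_CONDUCTANCE: 1.0,
    CH_AORTIC: 1.0,
    CH_COR_TRUE: 1.0,
    CH_COR_FALSE: 1.0,
    CH_VELOCITY: 2.0,
}


@dataclass
class SimConfig:
    """Simulator parameters.  Units in comments; defaults approximate a
    ~50 kg pig after proximal-LAD dissection (pump off)."""

    hr: float = 71.4                 # beats/min
    e_max: float = 2.6               # mmHg/ml, end-systolic elastance
    e_min: float = 0.12              # mmHg/ml, diastolic stiffness
    v0: float = 10.0                 # ml, unstressed LV volume
    r_mitral: float = 0.12           # mmHg*s/ml
    r_aortic: float = 0.01           # mmHg*s/ml
    r_systemic: float = 1.45         # mmHg*s/ml
    c_aorta: float = 1.3             # ml/mmHg
    p_atrium: float = 24.0           # mmHg, effective filling pressure
    p_venous: float = 5.0            # mmHg
    pump_level: str = "P0"           # "P0" (off) or "P8" (maximal)
    q_nominal_p8: float = 3.1        # L/min, pump nominal flow at P8
    k_p: float = 0.005               # (L/min)/mmHg, pump curve slope
    flap_gamma: float = 0.0          # dimensionless flap severity (0 = small flap)
    r_coronary_base: float = 5.0     # mmHg*s/ml, open true-lumen inlet
    r_micro_sys: float = 110.0       # mmHg*s/ml, systolic microvascular
    r_micro_dia: float = 45.0        # mmHg*s/ml, diastolic microvascular
    tau_fill: float = 0.2            # s, false-lumen filling time constant
    tau_drain: float = 2.0           # s, false-lumen drainage time constant
    vessel_area: float = 0.028       # cm^2, mid-LAD lumen area
    alpha_true: float = 1.15         # conductance gain ground truth
    v_parallel_true: float = 25.0    # ml, parallel volume ground truth
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    seed: int = 0
    fs: float = 1000.0               # Hz
    duration_s: float = 16.0         # s (>= 12 beats required)
    animal_id: str = "sim"

    def __post_init__(self) -> None:
        if self.pump_level not in ("P0", "P8"):
            raise ValueError(f"pump_level must be 'P0' or 'P8', got {self.pump_level!r}")
        if not (self.e_max > self.e_min > 0):
            raise ValueError("require e_max > e_min > 0")
        for name in ("r_mitral", "r_aortic", "r_systemic", "r_coronary_base",
                     "r_micro_sys", "r_micro_dia"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.flap_gamma < 0:
            raise ValueError("flap_gamma must be >= 0")
        n_beats = self.duration_s * self.hr / 60.0
        if n_beats < 12:
            raise ValueError(
                f"duration_s={self.duration_s} covers only {n_beats:.1f} beats "
                "at this heart rate; need >= 12 so 10 consecutive cycles are "
                "available after settling"
            )


@dataclass
class GroundTruth:
    """True metric values from the noiseless state trajectory."""

    pv: PVMetrics
    cor_pressure: BeatStats
    cor_velocity: BeatStats
    mean_aortic_pressure: float
    mean_false_lumen_pressure: float
    mean_pump_flow_lpm: float
    total_co_lpm: float
    alpha_true: float
    v_parallel_true: float
    beat_boundaries: np.ndarray
    signals: dict[str, np.ndarray]


@njit(cache=False)
def _activation(tau, T, t_peak, t_end):
    if tau < t_peak:
        return 0.5 * (1.0 - math.cos(math.pi * tau / t_peak))
    elif tau < t_end:
        return 0.5 * (1.0 + math.cos(math.pi * (tau - t_peak) / (t_end - t_peak)))
    return 0.0


@njit(cache=False)
def _deriv(t, V, Pao, Pf, T, t_peak, t_end, e_max, e_min, v0, r_mitral,
           r_aortic, r_systemic, c_aorta, p_atrium, p_venous, qn, kp,
           gamma, r_cb, r_ms, r_md, tau_fill, tau_drain):
    a = _activation(t % T, T, t_peak, t_end)
    E = e_min + (e_max - e_min) * a
    Plv = E * (V - v0)
    Qin = (p_atrium - Plv) / r_mitral
    if Qin < 0.0:
        Qin = 0.0
    Qout = (Plv - Pao) / r_aortic
    if Qout < 0.0:
        Qout = 0.0
    Qimp = qn - kp * (Pao - Plv)
    if Qimp < 0.0:
        Qimp = 0.0
    Rm = r_md + (r_ms - r_md) * a
    # coronary branch: closed-form distal true-lumen pressure
    Q_open = (Pao - p_venous) / (r_cb + Rm)
    Pt_open = Pao - Q_open * r_cb
    if gamma <= 0.0 or Pf <= Pt_open:
        Qcor = Q_open
        Pt = Pt_open
    else:
        a2 = r_cb * gamma / 10.0
        B = r_cb + Rm + a2 * (Pf - p_venous)
        C = (Pao - p_venous) * Rm
        disc = B * B - 4.0 * a2 * C
        if disc < 0.0:
            disc = 0.0
        y = (B - math.sqrt(disc)) / (2.0 * a2)
        Pt = p_venous + y
        gap = Pf - Pt
        if gap < 0.0:
            gap = 0.0
        Rt = r_cb * (1.0 + gamma * gap / 10.0)
        Qcor = (Pao - p_venous) / (Rt + Rm)
    dV = Qin - Qout - Qimp
    dPao = (Qout + Qimp - (Pao - p_venous) / r_systemic - Qcor) / c_aorta
    tf = tau_fill if Pao > Pf else tau_drain
    dPf = (Pao - Pf) / tf
    return dV, dPao, dPf, Plv, Pt, Qcor, Qimp, Qin, Qout


@njit(cache=False)
def _integrate(n_steps, h, T, t_peak, t_end, e_max, e_min, v0, r_mitral,
               r_aortic, r_systemic, c_aorta, p_atrium, p_venous, qn, kp,
               gamma, r_cb, r_ms, r_md, tau_fill, tau_drain,
               v_init, pao_init, pf_init):
    out = np.empty((9, n_steps))
    V = v_init
    Pao = pao_init
    Pf = pf_init
    status = -1
    for i in range(n_steps):
        t = i * h
        d = _deriv(t, V, Pao, Pf, T, t_peak, t_end, e_max, e_min, v0,
                   r_mitral, r_aortic, r_systemic, c_aorta, p_atrium,
                   p_venous, qn, kp, gamma, r_cb, r_ms, r_md,
                   tau_fill, tau_drain)
        out[0, i] = V
        out[1, i] = d[3]      # P_lv
        out[2, i] = Pao
        out[3, i] = Pf
        out[4, i] = d[4]      # P_true
        out[5, i] = d[5]      # Q_cor
        out[6, i] = d[6]      # Q_imp
        out[7, i] = d[7]      # Q_in
        out[8, i] = d[8]      # Q_out
        if i == n_steps - 1:
            break
        k1 = d
        k2 = _deriv(t + 0.5 * h, V + 0.5 * h * k1[0], Pao + 0.5 * h * k1[1],
                    Pf + 0.5 * h * k1[2], T, t_peak, t_end, e_max, e_min, v0,
                    r_mitral, r_aortic, r_systemic, c_aorta, p_atrium,
                    p_venous, qn, kp, gamma, r_cb, r_ms, r_md,
                    tau_fill, tau_drain)
        k3 = _deriv(t + 0.5 * h, V + 0.5 * h * k2[0], Pao + 0.5 * h * k2[1],
                    Pf + 0.5 * h * k2[2], T, t_peak, t_end, e_max, e_min, v0,
                    r_mitral, r_aortic, r_systemic, c_aorta, p_atrium,
                    p_venous, qn, kp, gamma, r_cb, r_ms, r_md,
                    tau_fill, tau_drain)
        k4 = _deriv(t + h, V + h * k3[0], Pao + h * k3[1], Pf + h * k3[2],
                    T, t_peak, t_end, e_max, e_min, v0, r_mitral, r_aortic,
                    r_systemic, c_aorta, p_atrium, p_venous, qn, kp, gamma,
                    r_cb, r_ms, r_md, tau_fill, tau_drain)
        V += h / 6.0 * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
        Pao += h / 6.0 * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
        Pf += h / 6.0 * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
        if not (math.isfinite(V) and math.isfinite(Pao) and math.isfinite(Pf)):
            status = i
            break
    return out, status


def _beat_stats_over(x: np.ndarray, b: np.ndarray) -> BeatStats:
    """Per-beat max/min/mean of ``x`` averaged over cycles bounded by ``b``."""
    mx, mn, mean = [], [], []
    for i in range(b.size - 1):
        seg = x[b[i]:b[i + 1]]
        mx.append(np.max(seg))
        mn.append(np.min(seg))
        mean.append(np.mean(seg))
    return BeatStats(maximum=float(np.mean(mx)), minimum=float(np.mean(mn)),
                     mean=float(np.mean(mean)))


def simulate(cfg: SimConfig) -> tuple[Recording, GroundTruth]:
    """Integrate the lumped model and emit a noisy 1 kHz Recording plus the
    noiseless ground truth over 10 steady-state beats."""
    h = 1.0 / cfg.fs
    n_steps = int(round(cfg.duration_s * cfg.fs))
    T = 60.0 / cfg.hr
    qn = cfg.q_nominal_p8 * 1000.0 / 60.0 if cfg.pump_level == "P8" else 0.0
    kp = cfg.k_p * 1000.0 / 60.0

    out, status = _integrate(
        n_steps, h, T, 0.30 * T, 0.45 * T, cfg.e_max, cfg.e_min, cfg.v0,
        cfg.r_mitral, cfg.r_aortic, cfg.r_systemic, cfg.c_aorta,
        cfg.p_atrium, cfg.p_venous, qn, kp, cfg.flap_gamma,
        cfg.r_coronary_base, cfg.r_micro_sys, cfg.r_micro_dia,
        cfg.tau_fill, cfg.tau_drain, 125.0, 90.0, 90.0,
    )
    if status >= 0:
        raise RuntimeError(
            f"integration produced a non-finite state at step {status} "
            f"(t = {status * h:.3f} s); check the configuration"
        )

    V, Plv, Pao, Pf, Pt, Qcor, Qimp, Qin, Qout = out
    velocity = Qcor / cfg.vessel_area
    v_raw = (V + cfg.v_parallel_true) / cfg.alpha_true

    # exact beat boundaries from the prescribed activation period
    spb = cfg.fs * T
    n_complete = int(math.floor((n_steps - 1) / spb))
    settle = min(5, n_complete - 10)
    b = np.array([int(round(k * spb)) for k in range(settle, settle + 11)])

    cyc = CycleSet(boundaries=b, fs=cfg.fs)
    pv = pv_metrics(Trace(Plv, cfg.fs, "mmHg", CH_LV_PRESSURE),
                    Trace(V, cfg.fs, "ml", "lv_volume"), cyc)
    sl = slice(b[0], b[-1])
    mean_pump = float(np.mean(Qimp[sl])) * 60.0 / 1000.0
    truth = GroundTruth(
        pv=pv,
        cor_pressure=_beat_stats_over(Pt, b),
        cor_velocity=_beat_stats_over(velocity, b),
        mean_aortic_pressure=float(np.mean(Pao[sl])),
        mean_false_lumen_pressure=float(np.mean(Pf[sl])),
        mean_pump_flow_lpm=mean_pump,
        total_co_lpm=pv.co + mean_pump,
        alpha_true=cfg.alpha_true,
        v_parallel_true=cfg.v_parallel_true,
        beat_boundaries=b,
        signals={"V_lv": V, "P_lv": Plv, "P_ao": Pao, "P_false": Pf,
                 "P_true": Pt, "Q_cor": Qcor, "Q_imp": Qimp,
                 "Q_in": Qin, "Q_out": Qout, "velocity": velocity},
    )

    rng = np.random.default_rng(cfg.seed)
    clean = {
        CH_LV_PRESSURE: Plv,
        CH_CONDUCTANCE: v_raw,
        CH_AORTIC: Pao,
        CH_COR_TRUE: Pt,
        CH_COR_FALSE: Pf,
        CH_VELOCITY: velocity,
    }
    channels = {}
    for label in (CH_LV_PRESSURE, CH_CONDUCTANCE, CH_AORTIC, CH_COR_TRUE,
                  CH_COR_FALSE, CH_VELOCITY):
        sd = float(cfg.noise_sd.get(label, 0.0))
        x = clean[label] + (sd * rng.standard_normal(n_steps) if sd > 0 else 0.0)
        channels[label] = Trace(x, cfg.fs, _UNITS[label], label)
    rec = Recording(channels=channels, animal_id=cfg.animal_id,
                    condition=cfg.pump_level,
                    meta={"flap_gamma": f"{cfg.flap_gamma:g}",
                          "seed": str(cfg.seed)})
    return rec, truth


@dataclass
class PairedSubject:
    subject_id: str
    config_p0: SimConfig
    config_p8: SimConfig
    p0: tuple[Recording, GroundTruth]
    p8: tuple[Recording, GroundTruth]


# parameters jittered across subjects (lognormal, fraction of the base value)
_JITTERED = ("e_max", "e_min", "r_systemic", "c_aorta", "p_atrium",
             "r_micro_dia", "r_micro_sys")


def make_paired_cohort(n_subjects: int = 6, base_cfg: SimConfig | None = None,
                       inter_subject_sd: float = 0.08, seed: int = 0,
                       hr_p0: float = 71.4, hr_p8: float = 64.9,
                       ) -> list[PairedSubject]:
    """Simulate a paired P0/P8 cohort with per-subject parameter jitter.

    Per-subject parameters are drawn once (lognormal jitter of fractional SD
    ``inter_subject_sd`` around the base configuration, seeded) and held
    fixed across both pump levels; only the pump level and the heart rate
    (slower under support, a protocol observation imposed rather than
    emergent) differ within a subject.  Deterministic for a given seed.
    """
    if n_subjects < 2:
        raise ValueError("need n_subjects >= 2")
    if not (0 <= inter_subject_sd < 1):
        raise ValueError("inter_subject_sd must be in [0, 1)")
    base = base_cfg if base_cfg is not None else SimConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    subjects: list[PairedSubject] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        mult = {p: float(np.exp(inter_subject_sd * rng.standard_normal()))
                for p in _JITTERED}
        hr_mult = float(np.exp(0.5 * inter_subject_sd * rng.standard_normal()))
        noise_seeds = rng.integers(0, 2**31 - 1, size=2)
        sid = f"s{i + 1:02d}"
        overrides = {p: getattr(base, p) * mult[p] for p in _JITTERED}
        cfgs = {}
        for level, hr_c, nseed in (("P0", hr_p0, noise_seeds[0]),
                                   ("P8", hr_p8, noise_seeds[1])):
            hr = hr_c * hr_mult
            cfgs[level] = replace(
                base, pump_level=level, hr=hr, seed=int(nseed),
                animal_id=sid, noise_sd=dict(base.noise_sd),
                duration_s=max(base.duration_s, 16.5 * 60.0 / hr),
                **overrides,
            )
        subjects.append(PairedSubject(
            subject_id=sid, config_p0=cfgs["P0"], config_p8=cfgs["P8"],
            p0=simulate(cfgs["P0"]), p8=simulate(cfgs["P8"]),
        ))
    return subjects


def make_angio_traces(fill_delays: dict[str, int], frame_rate: float = 30.0,
                      n_frames: int | None = None, sigmoid_width: float = 1.5,
                      plateau: float = 1.0, noise_sd: float = 0.0,
                      seed: int | None = None,
                      ) -> tuple[dict[str, Trace], "AngioAnnotationTruth"]:
    """Per-frame opacification intensity traces with planted first-fill frames.

    Each vessel gets a sigmoid opacification curve centred on its planted
    fill frame (the curve crosses half its plateau exactly there), sampled
    at the angiographic frame rate.  Returns the traces and the ground-truth
    annotation.
    """
    from .waveform_io import AngioAnnotation

    for vessel, d in fill_delays.items():
        if d < 0 or int(d) != d:
            raise ValueError(f"vessel {vessel}: planted fill frame must be a "
                             f"non-negative integer, got {d}")
    if n_frames is None:
        n_frames = int(max(fill_delays.values())) + 60
    rng = np.random.default_rng(seed)
    frames = np.arange(n_frames, dtype=float)
    traces: dict[str, Trace] = {}
    for vessel, m in fill_delays.items():
        x = plateau / (1.0 + np.exp(-(frames - m) / sigmoid_width))
        if noise_sd > 0:
            x = np.clip(x + noise_sd * rng.standard_normal(n_frames), 0.0, None)
        traces[vessel.upper()] = Trace(x, fs=frame_rate, unit="a.u.",
                                       label=vessel.upper())
    truth = AngioAnnotation(frame_rate=frame_rate,
                            fills={v.upper(): int(d) for v, d in fill_delays.items()})
    return traces, truth
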