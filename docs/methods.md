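# Methods

## Measurement chain

### Conditioning

Raw channels are sampled at 1 kHz. The conditioning chain is:

1. **Decimation to 200 Hz.** Polyphase FIR anti-alias filtering
   (`scipy.signal.resample_poly`, linear-trend edge padding) followed by
   integer decimation. The source rate must be an integer multiple of the
   target; no interpolation-based resampling is performed, so sample values
   are never invented. The filter has unit DC gain: constant signals pass
   unchanged.
2. **Savitzky–Golay smoothing**, window 11 samples (55 ms at 200 Hz),
   polynomial order 3. The filter is the per-window least-squares polynomial
   fit evaluated at the window centre and therefore reproduces any cubic
   signal exactly; edges are handled by fitting the first/last full window
   and evaluating the polynomial there.
3. **Cycle detection** at local minima of the (smoothed, decimated) pressure
   trace. Two guards reject spurious minima: candidates must be separated by
   at least `min_period_s` (default 0.3 s, a ~200 bpm ceiling) and must have
   a prominence of at least `prominence_frac` (default 0.2) times the
   trace's peak-to-peak range. Both are configurable. A cycle spans
   `[boundary_i, boundary_{i+1})`; the trailing partial cycle is discarded.
4. **Ensemble averaging** of 10 consecutive cycles (configurable, with a
   start-cycle offset; analyses in this repository skip the first 5 cycles
   of a simulated record to clear the integrator's settling transient).
   Cycles of unequal length are linearly resampled to the median cycle
   length and averaged pointwise. By default channels are smoothed before
   averaging; a flag averages raw cycles instead.
5. **Beat statistics**: maximum, minimum and time-averaged mean of the
   ensemble beat.

### Conductance calibration and PV metrics

The conductance catheter yields a volume-proportional signal `V_raw`.
Calibration is `V = α·V_raw − V_p`, applied in that order so that α matches
a pure flow ratio independently of the offset:

* α = CO_thermo / CO_conductance. CO_thermo comes from a Stewart–Hamilton
  thermodilution integral, CO = V_inj·(T_blood − T_inj)·K / ∫ΔT dt
  (trapezoid rule; the curve must have returned to ≤5% of its peak). The
  device computation constant K defaults to 1 and is a config field.
  CO_conductance is the uncalibrated volume excursion per beat times heart
  rate; the excursion is read from the 10-cycle **ensemble-averaged** volume
  beat, because channel noise biases per-cycle maxima upward (extreme-value
  bias) and the ensemble mean suppresses that by √n.
* V_p = (α-scaled end-diastolic volume) − (echocardiographic EDV).

Per-beat landmarks: the LV volume is flat during the isovolumic phases while
pressure swings by tens of mmHg, so a bare argmax/argmin of volume picks an
arbitrary sample of the plateau once noise is present and the associated
"end-diastolic/systolic pressure" becomes meaningless. End-diastole is
therefore the first sample entering a band of 2% of the cycle's volume
excursion below the cycle maximum, and end-systole the first sample after
end-diastole entering the corresponding band above the subsequent minimum —
the onsets of the two plateaus. On smooth loops without plateaus the
landmark volumes sit within that 2% band of the true extrema.

Stroke work is the unsigned shoelace area of the closed P–V polygon,
invariant to starting index and orientation; the loop is closed by joining
the last point to the first. CO = SV·HR/1000 holds exactly by construction
(CO is derived from the beat-averaged SV and HR, not averaged per beat).

**Known limitation.** Under continuous pump drain the ventricular volume
keeps falling after ejection ends, so the min-volume plateau moves into
diastole and the reported "end-systolic pressure" at maximal support is read
at a low-pressure sample. ESP is therefore not a reliable quantity at P8
with these landmarks; none of the directional conclusions uses it.

### Delay time

DT = (LAD first-fill frame − LCX first-fill frame) / frame rate, at
30 frames/s. DT is antisymmetric under swapping the vessels and invariant
to a common frame offset; it may be negative if the LAD fills first. When
first-fill frames are read from per-frame opacification-intensity traces,
the fill frame is the first frame reaching `threshold_frac` (default 0.5)
of the plateau, the plateau being the mean of the last 10% of frames. No
mapping from DT to a visual flow grade is attempted; a grade may be attached
as metadata.

### Statistics

Summaries are mean ± SD with the n−1 denominator. The paired Student's
t-test uses t = mean(d)/(sd(d)/√n) on per-subject differences, two-sided p
from the t distribution with n−1 df. Zero-variance differences with nonzero
mean are flagged degenerate with p reported at its 0 bound. Each metric is
tested marginally, with no multiple-testing correction; subject subsets
enter the comparison explicitly.

## Simulator

A minimal lumped model chosen as the smallest system that reproduces every
directional finding of interest; it makes no claim of quantitative fidelity
to porcine physiology.

* **LV**: time-varying elastance, P_lv = E(t)(V − V0),
  E(t) = e_min + (e_max − e_min)·a(t), with a(t) a smooth two-cosine
  activation (rise to 30% of the period, fall until 45%).
* **Valves**: linear-resistance diodes from a constant effective atrial
  pressure and into the aortic Windkessel.
* **Pump**: Q_imp = max(0, Q_nom − k_p(P_ao − P_lv)); Q_nom = 0 at P0.
  Q_nom at P8 (3.1 L/min by default) was calibrated once so the
  time-averaged pump flow of the default configuration is 2.7 L/min, the
  console-reported operating point of the device at maximal support, and is
  frozen in the shipped defaults.
* **Systemic load**: two-element Windkessel (C_ao, R_sys) to a venous
  pressure.
* **Coronary branch**: microvascular resistance interpolating between its
  diastolic and systolic values with a(t) (systolic compression), in series
  with the true-lumen inlet resistance
  R_true = R_base·(1 + γ·max(0, P_false − P_true)/10 mmHg). The 10 mmHg
  normalisation is an arbitrary documented scale; γ = 0 models a small,
  non-obstructive flap. P_true solves the series-divider relation in closed
  form each step (the engaged branch is a quadratic with a guaranteed
  non-negative discriminant), keeping the integration free of inner
  iterations.
* **False lumen**: relaxes toward aortic pressure through the flap
  communication with asymmetric time constants — fast filling
  (tau_fill = 0.2 s) through the intimal tear, slow drainage
  (tau_drain = 2 s) from the hematoma-confined pouch. The asymmetry makes
  P_false ride near systolic rather than mean aortic pressure. It is what
  produces the observed sign flip: with a symmetric time constant P_false
  pins to mean aortic pressure and the quasi-static algebra makes mean
  distal pressure monotone in aortic pressure, so maximal support could
  never lower it. With the asymmetry, support (which raises aortic — and
  hence false-lumen — pressure while narrowing pulse pressure) shrinks the
  part of the cycle during which the flap is pushed open, and mean distal
  pressure falls for large γ while still rising for γ = 0.
* **Conductance channel**: emitted uncalibrated as
  V_raw = (V + V_p,true)/α_true — the exact inverse of the calibration map.
* **Integration**: fixed-step classical Runge–Kutta at the output rate
  (1 kHz), which keeps runs bit-reproducible; stability is guarded by a
  non-finite check that reports the failing step rather than adaptive
  stepping. Seeded Gaussian noise is added per channel (default SD 1 mmHg
  on pressures, 2 cm/s on velocity, 1 a.u. on conductance). Ground truth is
  always computed from the noiseless trajectory over 10 steady-state beats
  (beats 6–15 of a 16 s record).

Default hemodynamic parameters were chosen once to place the pump-off state
in the range observed after proximal-LAD dissection in a ~50 kg pig
(EDV ≈ 118 ml, SV ≈ 60 ml, SW ≈ 6300 mmHg·ml, ESP ≈ 124 mmHg, mean aortic
≈ 107 mmHg, mean distal coronary ≈ 98 mmHg, CO ≈ 4.3 L/min) and, at P8,
to unload the ventricle by roughly the observed fractions. The heart-rate
reduction under support (71.4 → 64.9 bpm) is not emergent; the paired-cohort
generator imposes it per condition.

Paired cohorts draw per-subject multipliers (lognormal, fractional SD 0.08
by default) for elastances, systemic resistance and compliance, filling
pressure and microvascular resistances, hold them fixed across both pump
levels, and derive all randomness from a single seed (identical seeds give
bit-identical cohorts).

### What the generator does and does not emulate

It reproduces: paired two-condition recordings with within-subject
consistency; the directional hemodynamic response to support (lower EDP,
EDV, SV, SW; higher aortic pressure and total output); the flap-severity
dependence of the distal coronary response; angiographic first-fill delays
as sigmoid opacification curves with planted fill frames.

It does not emulate: coronary autoregulation (so measured flow velocity
*rises* with support in the small-flap case, whereas autoregulating beds
can hold or reduce flow), baseline wander or motion artefact (noise is
additive Gaussian only; an optional drift term is out of scope), ECG
channels, respiratory modulation, arrhythmia, or ischemic changes in
contractility. Passing tests therefore demonstrate correctness of the
measurement chain and of the stated directional mechanisms, not fidelity to
any individual animal's waveforms.

## Numerical choices and problem sizes

* Decimation ratio 5 (1 kHz → 200 Hz) everywhere; analyses use 10-cycle
  ensembles after a 5-beat settling window, matching the ground-truth
  window.
* Simulated records are 16 s (~19 beats at 71 bpm); cohort records extend
  automatically to 16.5 beats when a jittered heart rate requires it.
* The directional cohort check runs 100 cohort seeds of 6 paired subjects;
  the null-calibration check of the t-test runs 2000 paired draws at n = 6.
  These sizes give Monte-Carlo standard errors well inside the asserted
  bands and run in seconds.
* Degenerate inputs fail loudly: non-finite samples name the row, too few
  cycles report the available count, loops of fewer than 8 points are
  rejected, thermodilution curves that have not washed out are rejected.
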