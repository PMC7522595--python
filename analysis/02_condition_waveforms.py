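#!/usr/bin/env python
"""Condition the cohort waveforms to ensemble-beat statistics.

Reads every recording written by 01_simulate_cohort.py, runs the standard
conditioning chain (1 kHz -> 200 Hz decimation, Savitzky-Golay window 11 /
order 3, cycle detection on LV-pressure minima, 10-cycle ensemble average
starting after a 5-beat settling window) and writes per-channel
max/min/mean beat statistics to results/beat_stats.json.
"""

import json
import pathlib

from corohemo.pipeline import condition_recording
from corohemo.waveform_io import read_recording

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    stats = {}
    for path in sorted((ROOT / "cohort").glob("s*.csv")):
        rec = read_recording(path)
        key = path.stem
        stats[key] = condition_recording(
            rec, channels=["cor_true_pressure", "cor_false_pressure",
                           "cor_flow_velocity", "aortic_pressure"],
            start_cycle=5)
        cp = stats[key]["cor_true_pressure"]
        print(f"{key}: distal coronary pressure "
              f"max {cp['max']:6.1f} / min {cp['min']:6.1f} / "
              f"mean {cp['mean']:6.1f} mmHg")

    out = ROOT / "beat_stats.json"
    out.write_text(json.dumps(stats, indent=2))
    print(f"\nwrote beat statistics for {len(stats)} recordings to {out}")


if __name__ == "__main__":
    main()
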