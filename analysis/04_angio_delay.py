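#!/usr/bin/env python
"""Angiographic flow delay times for a non-obstructive and a flow-limiting
dissection.

Synthesizes per-frame opacification-intensity traces at 30 frames/s with
planted first-fill frames (a ~8-frame LAD lag for the non-obstructive flap
at both pump levels; a 32-frame lag worsening to 76 frames under maximal
support for the flow-limiting flap), reads the fill frames back by
threshold crossing, and reports DT = (LAD fill - LCX fill)/frame rate.
Writes results/dt.json.
"""

import json
import pathlib

from corohemo.angio_flow import compute_dt, fill_frame_from_intensity
from corohemo.synthetic_hemo import make_angio_traces
from corohemo.waveform_io import AngioAnnotation

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"

SCENARIOS = {
    "small_flap_P0": {"LCX": 10, "LAD": 18},
    "small_flap_P8": {"LCX": 10, "LAD": 17},
    "flow_limiting_P0": {"LCX": 10, "LAD": 42},
    "flow_limiting_P8": {"LCX": 10, "LAD": 86},
}


def main():
    out = {}
    for name, delays in SCENARIOS.items():
        traces, _ = make_angio_traces(delays, n_frames=max(delays.values()) + 80)
        fills = {v: fill_frame_from_intensity(traces[v]) for v in traces}
        res = compute_dt(AngioAnnotation(frame_rate=30.0, fills=fills))
        out[name] = res.as_dict()
        print(f"{name:>20}: DT = {res.dt_rounded:5.2f} s "
              f"(LAD frame {res.lad_fill_frame}, LCX frame {res.lcx_fill_frame})")

    ROOT.mkdir(exist_ok=True)
    (ROOT / "dt.json").write_text(json.dumps(out, indent=2))
    print(f"\nthe flow-limiting flap prolongs DT under maximal support "
          f"({out['flow_limiting_P0']['dt_seconds_2dp']} -> "
          f"{out['flow_limiting_P8']['dt_seconds_2dp']} s); "
          f"the small flap does not")


if __name__ == "__main__":
    main()
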