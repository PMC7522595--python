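#!/usr/bin/env python
"""Paired comparison of pump-off vs maximal-support LV metrics.

Takes the six small-flap subjects' pipeline-computed PV metrics from
results/pv_metrics.json, pairs them within subject, and runs a paired
Student's t-test per metric.  Writes a Table-2-style report to
results/table_hemodynamics.tsv and prints it with mean +/- SD.
"""

import json
import pathlib

from corohemo.group_stats import compare_conditions, report_to_tsv

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
METRICS = ("edp", "esp", "edv", "esv", "sv", "sw", "hr", "co")


def main():
    pv = json.loads((ROOT / "pv_metrics.json").read_text())
    subjects = sorted({k.rsplit("_", 1)[0] for k in pv if not k.startswith("s07")})
    maps = {"P0": {}, "P8": {}}
    for cond in maps:
        for s in subjects:
            maps[cond][s] = {m: pv[f"{s}_{cond}"]["metrics"][m] for m in METRICS}

    report = compare_conditions(maps["P0"], maps["P8"], subjects)
    (ROOT / "table_hemodynamics.tsv").write_text(report_to_tsv(report))

    print(f"paired comparison over {len(subjects)} subjects "
          f"(pump off vs maximal support):\n")
    print(f"{'metric':>8} {'P0 mean±SD':>18} {'P8 mean±SD':>18} {'p':>8}")
    for m, c in report.items():
        print(f"{m:>8} {c.mean_a:10.1f} ± {c.sd_a:5.1f} "
              f"{c.mean_b:10.1f} ± {c.sd_b:5.1f} {c.p_two_sided:8.4f}")
    down = [m for m in ("edp", "edv", "sv", "sw", "hr")
            if report[m].mean_b < report[m].mean_a and report[m].p_two_sided < 0.05]
    print(f"\nsignificantly reduced under support: {', '.join(down)}")
    print(f"wrote {ROOT / 'table_hemodynamics.tsv'}")


if __name__ == "__main__":
    main()
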