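"""Paired-condition summaries and the paired Student's t-test.

Two-condition hemodynamic protocols (pump off vs maximal support, each
subject measured under both) are compared metric-by-metric with a paired
t-test on the per-subject differences; summaries are mean +/- SD with the
n-1 denominator.  No multiple-testing correction is applied: each metric is
tested marginally, as is conventional for small-animal hemodynamic tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

__all__ = ["PairedComparison", "paired_ttest", "summarize", "compare_conditions",
           "report_to_tsv", "report_to_json"]


@dataclass
class PairedComparison:
    metric_name: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_stat: float
    df: int
    p_two_sided: float
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.df != self.n - 1:
            raise ValueError("df must equal n - 1")
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def summarize(values) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of a sequence; needs n >= 2."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError(f"need >=2 values, got {x.size}")
    return float(np.mean(x)), float(np.std(x, ddof=1))


def paired_ttest(x, y, metric_name: str = "") -> PairedComparison:
    """Two-sided paired Student's t-test; pairing is by index.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y, sd with n-1 denominator,
    p from the t distribution with n-1 degrees of freedom.  If the paired
    differences have zero variance but a nonzero mean, the comparison is
    flagged degenerate and p is reported at its 0 bound.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"paired samples must be 1-D and equal length "
                         f"(got {x.shape} vs {y.shape})")
    n = x.size
    if n < 2:
        raise ValueError(f"need n >= 2 pairs, got {n}")
    d = x - y
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    degenerate = False
    if sd == 0.0:
        if md == 0.0:
            t = 0.0
            p = 1.0
        else:
            t = math.inf if md > 0 else -math.inf
            p = 0.0
            degenerate = True
    else:
        t = md / (sd / math.sqrt(n))
        p = float(2.0 * spstats.t.sf(abs(t), df=n - 1))
    ma, sa = summarize(x)
    mb, sb = summarize(y)
    return PairedComparison(
        metric_name=metric_name, mean_a=ma, sd_a=sa, mean_b=mb, sd_b=sb,
        t_stat=t, df=n - 1, p_two_sided=p, n=n, degenerate=degenerate,
    )


def compare_conditions(metrics_a: dict[str, dict[str, float]],
                       metrics_b: dict[str, dict[str, float]],
                       subjects: list[str] | None = None,
                       label_a: str = "P0", label_b: str = "P8",
                       ) -> dict[str, PairedComparison]:
    """Per-metric paired comparisons between two condition maps.

    ``metrics_a`` / ``metrics_b`` map subject id -> {metric name -> value};
    both maps must cover the same subjects and metric names.  ``subjects``
    fixes the pairing order (default: sorted ids).
    """
    if subjects is None:
        subjects = sorted(metrics_a)
    missing_a = [s for s in subjects if s not in metrics_a]
    missing_b = [s for s in subjects if s not in metrics_b]
    extra = sorted((set(metrics_a) | set(metrics_b)) - set(subjects))
    if missing_a or missing_b or extra:
        raise ValueError(
            f"subject mismatch: missing in {label_a}={missing_a}, "
            f"missing in {label_b}={missing_b}, unlisted={extra}"
        )
    metric_names = list(metrics_a[subjects[0]])
    for s in subjects:
        if set(metrics_a[s]) != set(metric_names) or set(metrics_b[s]) != set(metric_names):
            raise ValueError(f"subject {s!r}: metric names differ between subjects/conditions")
    out: dict[str, PairedComparison] = {}
    for m in metric_names:
        a = [metrics_a[s][m] for s in subjects]
        b = [metrics_b[s][m] for s in subjects]
        out[m] = paired_ttest(a, b, metric_name=m)
    return out


def report_to_tsv(report: dict[str, PairedComparison],
                  label_a: str = "P0", label_b: str = "P8") -> str:
    """Serialize a comparison report as TSV (metric, mean/sd per condition, p)."""
    lines = [f"metric\tmean_{label_a}\tsd_{label_a}\tmean_{label_b}\tsd_{label_b}\tp_value"]
    for m, c in report.items():
        lines.append(f"{m}\t{c.mean_a:.6g}\t{c.sd_a:.6g}\t{c.mean_b:.6g}"
                     f"\t{c.sd_b:.6g}\t{c.p_two_sided:.4g}")
    return "\n".join(lines) + "\n"


def report_to_json(report: dict[str, PairedComparison]) -> str:
    return json.dumps({m: vars(c) for m, c in report.items()}, indent=2)
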