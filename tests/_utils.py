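"""Shared test helpers and independent numerical oracles."""

import math

import numpy as np
from scipy import integrate

from corohemo.synthetic_hemo import SimConfig


def noiseless_config(**kw) -> SimConfig:
    cfg = SimConfig(**kw)
    cfg.noise_sd = {k: 0.0 for k in cfg.noise_sd}
    return cfg


def t_sf_numerical(t: float, df: int) -> float:
    """Upper-tail Student-t probability by quadrature of the density written
    directly from the gamma function (independent of scipy.stats.t)."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    val, _ = integrate.quad(lambda u: c * (1 + u * u / df) ** (-(df + 1) / 2),
                            t, np.inf)
    return val
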