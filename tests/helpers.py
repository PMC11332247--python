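"""Independent oracles used by the test suite.

Everything here is deliberately implemented without touching the package's
own code paths (brute-force CDF evaluation, closed-form diffusion results),
so tests compare two independent routes to the same quantity.
"""

import math

import numpy as np


def brute_force_ks(sample_a, sample_b) -> float:
    """Two-sample KS statistic by explicit CDF evaluation at every jump point."""
    a = list(sample_a)
    b = list(sample_b)
    points = sorted(set(a) | set(b))
    worst = 0.0
    for x in points:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        worst = max(worst, abs(fa - fb))
    return worst


def ddm_p_upper(a: float, z: float, v: float, sigma: float) -> float:
    """Closed-form probability of absorbing at the upper boundary.

    Constant-drift diffusion on [0, a] started at z.
    """
    if v == 0:
        return z / a
    k = 2.0 * v / sigma**2
    return (1.0 - math.exp(-k * z)) / (1.0 - math.exp(-k * a))


def ddm_mean_dt_symmetric(a: float, v: float, sigma: float) -> float:
    """Closed-form unconditional mean decision time for a symmetric start.

    Constant drift, boundaries 0 and a, start a/2, no deadline.
    """
    if v == 0:
        return (a / 2.0) * (a / 2.0) / sigma**2
    return (a / (2.0 * v)) * math.tanh(a * v / (2.0 * sigma**2))


def quantiles_inclusive(values, n=4):
    """Linear-interpolation ("type 7") quantile oracle via the stdlib."""
    import statistics
    return statistics.quantiles(values, n=n, method="inclusive")
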