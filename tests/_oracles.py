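"""Independent numerical oracles used by the tests.

These deliberately avoid the closed forms in :mod:`ebeamkin.kinetics`: the
dose-response ODEs are integrated with classic fixed-step fourth-order
Runge-Kutta, so agreement is evidence that the closed forms solve the stated
differential equations.
"""

from __future__ import annotations

import math

import numpy as np


def _rk4_segment(f, y0: float, x0: float, x1: float, max_step: float) -> float:
    """Integrate dy/dx = f(x, y) from x0 to x1 with classic RK4."""
    span = x1 - x0
    if span == 0.0:
        return y0
    n = max(int(math.ceil(span / max_step)), 1)
    h = span / n
    y, x = y0, x0
    for _ in range(n):
        k1 = f(x, y)
        k2 = f(x + 0.5 * h, y + 0.5 * h * k1)
        k3 = f(x + 0.5 * h, y + 0.5 * h * k2)
        k4 = f(x + h, y + h * k3)
        y += (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        x += h
    return y


def rk4_antibiotic(c0: float, alpha: float, doses, max_step: float = 2e-3) -> np.ndarray:
    """dC_a/dD = -alpha C_a, C_a(0) = c0, evaluated at sorted doses."""
    doses = np.asarray(doses, dtype=float)
    order = np.argsort(doses)
    out = np.empty_like(doses)
    y, x = c0, 0.0
    for idx in order:
        y = _rk4_segment(lambda _, yy: -alpha * yy, y, x, float(doses[idx]), max_step)
        x = float(doses[idx])
        out[idx] = y
    return out


def rk4_product(
    c0: float, alpha: float, beta: float, k: float, d0: float, doses, max_step: float = 2e-3
) -> np.ndarray:
    """dC_p/dD = -beta C_p + k c0 exp(-alpha D) from C_p(D0) = 0; 0 below D0."""
    doses = np.asarray(doses, dtype=float)
    order = np.argsort(doses)
    out = np.empty_like(doses)

    def f(x: float, y: float) -> float:
        return -beta * y + k * c0 * math.exp(-alpha * x)

    y, x = 0.0, d0
    for idx in order:
        d = float(doses[idx])
        if d <= d0:
            out[idx] = 0.0
            continue
        start = max(x, d0)
        y = _rk4_segment(f, y, start, d, max_step)
        x = d
        out[idx] = y
    return out


def pearson_r(x, y) -> float:
    """Textbook Pearson correlation written out longhand."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2)))
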