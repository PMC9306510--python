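"""Biexponential (difference-of-exponentials) synaptic-current kernels.

The canonical fit to an averaged postsynaptic current is

    g(t) = (exp(-t / tau_d) - exp(-t / tau_r)) / g_max ,   t >= 0,

with rise constant ``tau_r`` strictly smaller than decay constant ``tau_d``
and ``g_max`` chosen so the kernel peaks at 1.  All helpers here work in a
single time unit (use milliseconds throughout, or seconds throughout).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "peak_time",
    "biexp_kernel",
    "rise_20_80",
    "halfwidth",
    "tau_rise_for_rise_time",
]


def peak_time(tau_r: float, tau_d: float) -> float:
    """Analytic time of the kernel maximum, ln(tau_d/tau_r)/(1/tau_r - 1/tau_d)."""
    if not 0 < tau_r < tau_d:
        raise ValueError(f"need 0 < tau_r < tau_d, got {tau_r} and {tau_d}")
    return np.log(tau_d / tau_r) / (1.0 / tau_r - 1.0 / tau_d)


def _unnormalized(t, tau_r, tau_d):
    t = np.asarray(t, dtype=float)
    out = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    return np.where(t >= 0.0, out, 0.0)


def biexp_kernel(t, tau_r: float, tau_d: float):
    """Peak-normalized kernel evaluated at times ``t`` (same unit as the taus)."""
    tp = peak_time(tau_r, tau_d)
    gmax = _unnormalized(tp, tau_r, tau_d)
    return _unnormalized(t, tau_r, tau_d) / gmax


def _crossing(level: float, lo: float, hi: float, tau_r: float, tau_d: float) -> float:
    return brentq(lambda t: biexp_kernel(t, tau_r, tau_d) - level, lo, hi, xtol=1e-12)


def rise_20_80(tau_r: float, tau_d: float) -> float:
    """20%-80% rise time of the continuous kernel, by root finding."""
    tp = peak_time(tau_r, tau_d)
    t20 = _crossing(0.2, 0.0, tp, tau_r, tau_d)
    t80 = _crossing(0.8, t20, tp, tau_r, tau_d)
    return t80 - t20


def halfwidth(tau_r: float, tau_d: float) -> float:
    """Full width at half maximum of the continuous kernel."""
    tp = peak_time(tau_r, tau_d)
    left = _crossing(0.5, 0.0, tp, tau_r, tau_d)
    # decay side: bracket by extending until the kernel drops below 0.5
    hi = tp + tau_d
    while biexp_kernel(hi, tau_r, tau_d) > 0.5:
        hi += tau_d
    right = brentq(lambda t: biexp_kernel(t, tau_r, tau_d) - 0.5, tp, hi, xtol=1e-12)
    return right - left


def tau_rise_for_rise_time(rise: float, tau_d: float) -> float:
    """Invert :func:`rise_20_80`: the tau_r giving a target 20-80% rise time.

    The rise time is strictly increasing in tau_r on (0, tau_d), so the
    inverse is found by bisection.  Raises ``ValueError`` when the target is
    unreachable for the given decay constant.
    """
    if rise <= 0:
        raise ValueError("rise time must be positive")
    lo, hi = 1e-6 * tau_d, 0.999 * tau_d
    r_lo, r_hi = rise_20_80(lo, tau_d), rise_20_80(hi, tau_d)
    if not r_lo < rise < r_hi:
        raise ValueError(
            f"rise time {rise} unreachable for tau_d={tau_d} "
            f"(achievable range {r_lo:.4g}..{r_hi:.4g})"
        )
    return brentq(lambda x: rise_20_80(x, tau_d) - rise, lo, hi, xtol=1e-10)
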