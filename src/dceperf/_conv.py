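"""Exponential-kernel convolution on a (possibly nonuniform) time grid.

The tracer-kinetic forward models both reduce to integrals of the form

    I(t) = int_0^t cp(tau) * exp(-lam * (t - tau)) dtau

evaluated at the sample times. ``cp`` is treated as piecewise linear between
samples, for which the integral has an exact recursive form; this keeps the
convolution accurate at the sparse, irregular frame spacing typical of
clinical dynamic series, where naive trapezoid-of-product rules degrade.
"""

from __future__ import annotations

import numpy as np

__all__ = ["exp_conv", "cum_trapz"]


def _exp_conv_impl(t, f, lam):
    n = t.shape[0]
    out = np.zeros(n)
    if lam < 0.0:
        lam = 0.0
    acc = 0.0
    for i in range(1, n):
        dt = t[i] - t[i - 1]
        x = lam * dt
        if x > 1e-4:
            e = np.exp(-x)
            a = (1.0 - e) / lam
            # int_0^dt u * exp(-lam*(dt-u)) du
            b = dt / lam - a / lam
        else:
            # series expansions, stable as lam*dt -> 0
            e = np.exp(-x)
            a = dt * (1.0 - x / 2.0 + x * x / 6.0 - x * x * x / 24.0)
            b = dt * dt * (0.5 - x / 3.0 + x * x / 8.0 - x * x * x / 30.0)
        m = (f[i] - f[i - 1]) / dt
        seg = f[i - 1] * a + m * b
        acc = acc * e + seg
        out[i] = acc
    return out


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _exp_conv_jit = njit(cache=False)(_exp_conv_impl)

    def exp_conv(t: np.ndarray, f: np.ndarray, lam: float) -> np.ndarray:
        return _exp_conv_jit(
            np.ascontiguousarray(t, dtype=np.float64),
            np.ascontiguousarray(f, dtype=np.float64),
            float(lam),
        )

except ImportError:  # pragma: no cover

    def exp_conv(t: np.ndarray, f: np.ndarray, lam: float) -> np.ndarray:
        return _exp_conv_impl(
            np.asarray(t, dtype=np.float64),
            np.asarray(f, dtype=np.float64),
            float(lam),
        )


exp_conv.__doc__ = """Evaluate int_0^t f(tau) exp(-lam (t-tau)) dtau at each sample time.

Exact for piecewise-linear ``f``; ``lam = 0`` gives the running trapezoidal
integral. ``t`` must be increasing and the same length as ``f``.
"""


def cum_trapz(t: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Running trapezoidal integral of ``f`` over ``t``, zero at the first sample."""
    t = np.asarray(t, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    out = np.zeros_like(f)
    out[1:] = np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(t))
    return out
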