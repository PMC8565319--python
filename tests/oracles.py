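"""Independent numerical oracles used by the test suite.

These deliberately avoid the analytic expressions implemented in the
package: the reconvolution model is checked against direct numerical
convolution of the step-exponential with the Gaussian kernel, and the ODE
integrator against the matrix-exponential solution of the linearised
(pseudo-first-order) rate equations.
"""

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm

SQRT2PI = np.sqrt(2.0 * np.pi)


def convolution_oracle(times, t0, sigma, amplitudes, lifetimes, offset=0.0,
                       kernel_halfwidth=10.0):
    """Direct numerical convolution of H(t-t0) sum A_i exp(-(t-t0)/tau_i)
    with a Gaussian kernel, by adaptive quadrature per output time.

    The integration variable is the decay argument v; the interval covers
    the kernel support around t and starts exactly at the step at t0, so
    the integrand is smooth inside it.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    amplitudes = np.asarray(amplitudes, dtype=float)
    lifetimes = np.asarray(lifetimes, dtype=float)
    out = np.empty_like(times)

    def integrand(v, t):
        decay = np.sum(amplitudes * np.exp(-(v - t0) / lifetimes))
        kernel = np.exp(-((t - v) ** 2) / (2.0 * sigma**2)) / (sigma * SQRT2PI)
        return decay * kernel

    for j, t in enumerate(times):
        lo = max(t0, t - kernel_halfwidth * sigma)
        hi = t + kernel_halfwidth * sigma
        if hi <= lo:
            out[j] = offset
            continue
        val, _ = quad(integrand, lo, hi, args=(t,), limit=200, epsabs=1e-13,
                      epsrel=1e-11)
        out[j] = offset + val
    return out


def pseudo_first_order_expm(times, k1_um, k_m1, kf, sl0, p0, k2=None, k_m2=0.0):
    """Matrix-exponential solution with the complementary strand frozen at p0.

    Returns (sl, ic1, ic2, ed) arrays.  ``k2=None`` selects the two-step
    scheme (single intermediate converting at kf).
    """
    a = k1_um * p0
    if k2 is None:
        M = np.array([
            [-a, k_m1, 0.0],
            [a, -(k_m1 + kf), 0.0],
            [0.0, kf, 0.0],
        ])
        y0 = np.array([sl0, 0.0, 0.0])
        sl, ic1, ed = _propagate(M, y0, times)
        return sl, ic1, np.zeros_like(sl), ed
    M = np.array([
        [-a, k_m1, 0.0, 0.0],
        [a, -(k_m1 + k2), k_m2, 0.0],
        [0.0, k2, -(k_m2 + kf), 0.0],
        [0.0, 0.0, kf, 0.0],
    ])
    y0 = np.array([sl0, 0.0, 0.0, 0.0])
    sl, ic1, ic2, ed = _propagate(M, y0, times)
    return sl, ic1, ic2, ed


def _propagate(M, y0, times):
    cols = [expm(M * t) @ y0 for t in np.asarray(times, dtype=float)]
    return np.stack(cols, axis=1)
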