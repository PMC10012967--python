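"""Compiled right-hand side on the packed state vector.

This is the integrator's hot path: an explicit double loop over node
pairs, JIT-compiled with numba.  It must agree with
:func:`sepsisnet.model.duplex_rhs` to machine precision (asserted in the
test suite).  If numba is unavailable the pure-Python fallback is used,
which is identical code uncompiled.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def rhs_packed(
    y: np.ndarray,
    n: int,
    a: np.ndarray,
    omega1: float,
    omega2: float,
    alpha11: float,
    alpha22: float,
    alpha12: float,
    alpha21: float,
    beta: float,
    eps1: float,
    eps2: float,
    sigma: float,
) -> np.ndarray:
    """Time derivative of the packed state [phi1, phi2, k1 offdiag, k2 offdiag]."""
    dy = np.empty_like(y)
    phi1 = y[:n]
    phi2 = y[n : 2 * n]
    m = n * (n - 1)
    k1 = y[2 * n : 2 * n + m]
    k2 = y[2 * n + m :]

    s1 = np.sin(phi1)
    c1 = np.cos(phi1)
    s2 = np.sin(phi2)
    c2 = np.cos(phi2)
    sa1 = np.sin(phi1 + alpha11)
    ca1 = np.cos(phi1 + alpha11)
    sa2 = np.sin(phi2 + alpha22)
    ca2 = np.cos(phi2 + alpha22)
    sb1 = np.sin(phi1 - beta)
    cb1 = np.cos(phi1 - beta)
    sb2 = np.sin(phi2 - beta)
    cb2 = np.cos(phi2 - beta)

    inv_n = 1.0 / n
    idx = 0
    for i in range(n):
        acc1 = 0.0
        acc2 = 0.0
        for j in range(n):
            if j == i:
                continue
            kk1 = k1[idx]
            kk2 = k2[idx]
            # sin(phi_i - phi_j + alpha) via angle-sum identity
            acc1 += (a[i, j] + kk1) * (sa1[i] * c1[j] - ca1[i] * s1[j])
            acc2 += kk2 * (sa2[i] * c2[j] - ca2[i] * s2[j])
            dy[2 * n + idx] = -eps1 * (kk1 + (sb1[i] * c1[j] - cb1[i] * s1[j]))
            dy[2 * n + m + idx] = -eps2 * (kk2 + (sb2[i] * c2[j] - cb2[i] * s2[j]))
            idx += 1
        dy[i] = omega1 - inv_n * acc1 - sigma * np.sin(phi1[i] - phi2[i] + alpha12)
        dy[n + i] = omega2 - inv_n * acc2 - sigma * np.sin(phi2[i] - phi1[i] + alpha21)
    return dy
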