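"""Analytic reduction on the synchronized manifold.

Because the adaptation ODE ``kappa' = -eps*(kappa + sin(dphi - beta))`` is
linear in kappa, its solution is a convolution of the phase history with an
exponential kernel.  For a layer with all phases equal, the kernel
integrates out and each layer obeys a single scalar phase equation; the
pair of equations yields a closed-form condition for the interlayer phase
lag of the frequency-synchronized duplex state, an existence bound on the
interlayer coupling ``sigma``, and the common locked frequency.

All formulas here assume equal intralayer lags ``alpha0`` in both layers
and zero interlayer lags, and neglect the (N-1)/N finite-size factor of
the full model; comparisons against full simulations apply that factor
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad

from .exceptions import NoSynchronizedStateError, ParameterError

__all__ = [
    "SyncManifoldParams",
    "kappa_kernel",
    "reduced_sync_rhs",
    "sync_phase_lag",
    "sync_existence_bound",
    "sync_common_frequency",
]


@dataclass(frozen=True)
class SyncManifoldParams:
    """Parameters of the reduced two-phase system: common intralayer lag
    ``alpha0`` (rad), interlayer coupling ``sigma`` (>= 0), and age
    parameter ``beta`` (rad)."""

    alpha0: float = -0.28 * np.pi
    sigma: float = 1.0
    beta: float = 0.5 * np.pi

    def __post_init__(self):
        if self.sigma < 0:
            raise ParameterError("sigma", f"interlayer coupling must be >= 0, got {self.sigma}")


def kappa_kernel(
    phase_difference_history: Callable[[float], float],
    eps: float,
    beta: float,
    t: float,
    tail_cut: float = 1e-10,
) -> float:
    """Exponential-kernel representation of an adaptive weight.

    Evaluates ``kappa(t) = -eps * int_0^inf exp(-eps*s) *
    sin(dphi(t - s) - beta) ds`` by quadrature, where ``dphi`` is the
    phase-difference history (extended backward by its value at 0 for
    arguments below 0).  The integral is truncated at the lag where the
    kernel has decayed below ``tail_cut``.

    For a constant history ``d`` this returns ``-sin(d - beta)`` exactly
    (the kernel integrates to one).
    """
    if eps <= 0:
        raise ParameterError("eps", f"adaptation rate must be > 0, got {eps}")
    s_max = -np.log(tail_cut) / eps

    def hist(u: float) -> float:
        return phase_difference_history(u if u >= 0.0 else 0.0)

    def integrand(s: float) -> float:
        return np.exp(-eps * s) * np.sin(hist(t - s) - beta)

    # split at the point where the history switches to its backward
    # extension, so quad sees smooth pieces
    pieces = sorted({0.0, min(max(t, 0.0), s_max), s_max})
    total = 0.0
    for a, b in zip(pieces[:-1], pieces[1:]):
        val, err = quad(integrand, a, b, limit=200)
        if not np.isfinite(val) or err > 1e-6:
            raise ParameterError("quadrature", f"non-convergent kernel integral on [{a}, {b}]")
        total += val
    return float(-eps * total)


def reduced_sync_rhs(
    phi1: float, phi2: float, p: SyncManifoldParams
) -> tuple[float, float]:
    """Scalar phase equations of the two synchronized layers.

    With the weights integrated out, the parenchymal layer carries the
    fixed adjacency plus the adapted weight sin(beta) and the immune layer
    only the adapted weight:

        dphi1/dt = -(1 + sin beta) sin alpha0 - sigma sin(phi1 - phi2)
        dphi2/dt =      -sin beta  sin alpha0 - sigma sin(phi2 - phi1)
    """
    sb = np.sin(p.beta)
    sa = np.sin(p.alpha0)
    d1 = -(1.0 + sb) * sa - p.sigma * np.sin(phi1 - phi2)
    d2 = -sb * sa - p.sigma * np.sin(phi2 - phi1)
    return float(d1), float(d2)


def sync_existence_bound(alpha0: float) -> float:
    """Minimal interlayer coupling for the fully in-phase synchronized
    duplex state to exist: ``|sin(alpha0)| / 2``."""
    return float(np.abs(np.sin(alpha0)) / 2.0)


def sync_phase_lag(p: SyncManifoldParams) -> float:
    """Interlayer phase lag of the frequency-synchronized state.

    Equal layer frequencies require ``sin(phi1 - phi2) =
    -sin(alpha0) / (2 sigma)``; the principal arcsin branch is returned
    (the branch pi - Delta is the unstable lock).

    Raises
    ------
    NoSynchronizedStateError
        If sigma is below the existence bound |sin alpha0| / 2.
    """
    bound = sync_existence_bound(p.alpha0)
    if p.sigma < bound:
        raise NoSynchronizedStateError(
            f"no synchronized state: sigma={p.sigma} below existence bound {bound:.6g}"
        )
    if p.sigma == 0.0:
        # only reachable when sin(alpha0) == 0; the layers are decoupled
        # and any common phase works, 0 by convention
        return 0.0
    return float(np.arcsin(-np.sin(p.alpha0) / (2.0 * p.sigma)))


def sync_common_frequency(p: SyncManifoldParams) -> float:
    """Common drift of both layers on the locked manifold:
    ``-sin(alpha0) * (sin(beta) + 1/2)``.

    Obtained by substituting the phase-lag condition back into either
    scalar phase equation; raises like :func:`sync_phase_lag` when the
    locked state does not exist.
    """
    sync_phase_lag(p)  # existence check
    return float(-np.sin(p.alpha0) * (np.sin(p.beta) + 0.5))
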