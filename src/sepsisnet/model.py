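"""Core state, parameters, and right-hand side of the duplex adaptive
phase-oscillator model.

The model couples two all-to-all networks of ``N`` phase oscillators each:
layer 1 represents parenchymal cells (slow cytokine adaptation rate
``eps1``), layer 2 the innate immune layer (faster rate ``eps2``).  Within
each layer the coupling weights ``kappa`` adapt towards
``-sin(phi_i - phi_j - beta)``, where ``beta`` is the "age parameter"
selecting the plasticity rule; between the layers each node is coupled to
its counterpart with fixed strength ``sigma`` and phase lags
``alpha12``/``alpha21``.

Phases are stored as unwrapped reals (they grow without bound); reduction
modulo 2*pi is applied only for display and order parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .exceptions import DimensionError, ParameterError

__all__ = [
    "ModelParams",
    "DuplexState",
    "duplex_rhs",
    "kappa_sync_fixed_point",
    "shift_all_phases",
    "pack_state",
    "unpack_state",
    "state_size",
]


@dataclass(frozen=True, eq=False)
class ModelParams:
    """All constants of the duplex model plus the layer topology.

    Defaults are the reference parameter set used throughout the regime
    maps: ``N = 200``, ``alpha11 = alpha22 = -0.28*pi``,
    ``alpha12 = alpha21 = 0``, ``eps1 = 0.03``, ``eps2 = 0.3``,
    ``omega1 = omega2 = 0`` (co-rotating frame), with ``beta = 0.5*pi``
    and ``sigma = 1`` as the healthy reference point.

    Angles are radians; ``eps`` are rates per time unit; ``sigma`` is the
    dimensionless interlayer coupling strength.
    """

    n: int = 200
    omega1: float = 0.0
    omega2: float = 0.0
    alpha11: float = -0.28 * np.pi
    alpha22: float = -0.28 * np.pi
    alpha12: float = 0.0
    alpha21: float = 0.0
    beta: float = 0.5 * np.pi
    eps1: float = 0.03
    eps2: float = 0.3
    sigma: float = 1.0
    adjacency: Union[str, np.ndarray] = "global"

    def __post_init__(self):
        if int(self.n) != self.n or self.n < 2:
            raise ParameterError("n", f"node count must be an integer >= 2, got {self.n}")
        object.__setattr__(self, "n", int(self.n))
        # eps = 0 is permitted: it freezes the weights and recovers the
        # classical (non-adaptive) Kuramoto-Sakaguchi limit.
        if self.eps1 < 0:
            raise ParameterError("eps1", f"adaptation rate must be >= 0, got {self.eps1}")
        if self.eps2 < 0:
            raise ParameterError("eps2", f"adaptation rate must be >= 0, got {self.eps2}")
        if self.sigma < 0:
            raise ParameterError("sigma", f"interlayer coupling must be >= 0, got {self.sigma}")
        if isinstance(self.adjacency, str):
            if self.adjacency != "global":
                raise ParameterError("adjacency", f"unknown flag {self.adjacency!r}")
        else:
            a = np.asarray(self.adjacency, dtype=float)
            if a.shape != (self.n, self.n):
                raise DimensionError(
                    "adjacency", f"expected shape ({self.n}, {self.n}), got {a.shape}"
                )
            if not np.isin(a, (0.0, 1.0)).all():
                raise ParameterError("adjacency", "entries must be binary (0 or 1)")
            a = a.copy()
            np.fill_diagonal(a, 0.0)  # self-coupling excluded
            object.__setattr__(self, "adjacency", a)

    def adjacency_matrix(self) -> np.ndarray:
        """Dense N x N adjacency of the parenchymal layer (zero diagonal)."""
        if isinstance(self.adjacency, str):
            a = np.ones((self.n, self.n))
            np.fill_diagonal(a, 0.0)
            return a
        return np.asarray(self.adjacency, dtype=float)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n", "omega1", "omega2", "alpha11", "alpha22", "alpha12",
                "alpha21", "beta", "eps1", "eps2", "sigma",
            )
        }
        if isinstance(self.adjacency, str):
            d["adjacency"] = self.adjacency
        else:
            d["adjacency"] = np.asarray(self.adjacency).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        adj = d.get("adjacency", "global")
        if not isinstance(adj, str):
            d["adjacency"] = np.asarray(adj, dtype=float)
        return cls(**d)


@dataclass
class DuplexState:
    """Dynamical variables: two phase vectors and two weight matrices.

    ``phi1``/``phi2`` are length-N unwrapped phases (rad); ``kappa1`` /
    ``kappa2`` are N x N cytokine-weight matrices with zero diagonal.
    The adaptation law keeps each weight inside [-1, 1] whenever it
    starts there.
    """

    phi1: np.ndarray
    phi2: np.ndarray
    kappa1: np.ndarray
    kappa2: np.ndarray

    def __post_init__(self):
        self.phi1 = np.asarray(self.phi1, dtype=float)
        self.phi2 = np.asarray(self.phi2, dtype=float)
        self.kappa1 = np.asarray(self.kappa1, dtype=float)
        self.kappa2 = np.asarray(self.kappa2, dtype=float)
        n = self.phi1.shape[0] if self.phi1.ndim == 1 else -1
        if self.phi1.ndim != 1:
            raise DimensionError("phi1", f"expected 1-D vector, got shape {self.phi1.shape}")
        if self.phi2.shape != (n,):
            raise DimensionError("phi2", f"expected shape ({n},), got {self.phi2.shape}")
        if self.kappa1.shape != (n, n):
            raise DimensionError("kappa1", f"expected shape ({n}, {n}), got {self.kappa1.shape}")
        if self.kappa2.shape != (n, n):
            raise DimensionError("kappa2", f"expected shape ({n}, {n}), got {self.kappa2.shape}")

    @property
    def n(self) -> int:
        return self.phi1.shape[0]

    def validate_against(self, params: ModelParams) -> None:
        if self.n != params.n:
            raise DimensionError("phi1", f"state has N={self.n}, params have N={params.n}")

    def copy(self) -> "DuplexState":
        return DuplexState(
            self.phi1.copy(), self.phi2.copy(), self.kappa1.copy(), self.kappa2.copy()
        )


def kappa_sync_fixed_point(beta: float) -> float:
    """Asymptotic weight of a fully phase-synchronized layer.

    At equal phases the adaptation ODE is kappa' = -eps*(kappa - sin beta),
    so every off-diagonal weight relaxes to sin(beta): 1 for the Hebbian
    rule beta = pi/2, 0 for the causal rule beta = pi.
    """
    return float(np.sin(beta))


def shift_all_phases(state: DuplexState, c: float) -> DuplexState:
    """Add ``c`` to every phase in both layers; weights unchanged.

    The model is equivariant under this shift (in the co-rotating frame),
    which makes it a useful symmetry probe.
    """
    return DuplexState(state.phi1 + c, state.phi2 + c, state.kappa1.copy(), state.kappa2.copy())


def duplex_rhs(state: DuplexState, params: ModelParams) -> DuplexState:
    """Exact right-hand side of the coupled phase/weight ODE system.

    Returns a ``DuplexState`` holding (dphi1/dt, dphi2/dt, dkappa1/dt,
    dkappa2/dt).  Sums run over j != i and the kappa diagonals stay
    identically zero.  Vectorized via the angle-sum identity
    ``sin(phi_i - phi_j + a) = sin(phi_i + a) cos(phi_j) - cos(phi_i + a) sin(phi_j)``
    so the phase coupling reduces to matrix-vector products.
    """
    state.validate_against(params)
    n = params.n
    phi1, phi2 = state.phi1, state.phi2
    a = params.adjacency_matrix()

    s1, c1 = np.sin(phi1), np.cos(phi1)
    s2, c2 = np.sin(phi2), np.cos(phi2)

    w1 = a + state.kappa1  # diagonal is 0 + kappa_ii; kappa_ii forced 0 below
    w1 = w1.copy()
    np.fill_diagonal(w1, 0.0)
    w2 = state.kappa2.copy()
    np.fill_diagonal(w2, 0.0)

    sa1 = np.sin(phi1 + params.alpha11)
    ca1 = np.cos(phi1 + params.alpha11)
    sa2 = np.sin(phi2 + params.alpha22)
    ca2 = np.cos(phi2 + params.alpha22)

    coupling1 = (sa1 * (w1 @ c1) - ca1 * (w1 @ s1)) / n
    coupling2 = (sa2 * (w2 @ c2) - ca2 * (w2 @ s2)) / n

    dphi1 = params.omega1 - coupling1 - params.sigma * np.sin(phi1 - phi2 + params.alpha12)
    dphi2 = params.omega2 - coupling2 - params.sigma * np.sin(phi2 - phi1 + params.alpha21)

    # sin(phi_i - phi_j - beta), as outer products of per-node trig values
    sb1 = np.sin(phi1 - params.beta)
    cb1 = np.cos(phi1 - params.beta)
    sb2 = np.sin(phi2 - params.beta)
    cb2 = np.cos(phi2 - params.beta)
    sin_d1 = np.outer(sb1, c1) - np.outer(cb1, s1)
    sin_d2 = np.outer(sb2, c2) - np.outer(cb2, s2)

    dk1 = -params.eps1 * (state.kappa1 + sin_d1)
    dk2 = -params.eps2 * (state.kappa2 + sin_d2)
    np.fill_diagonal(dk1, 0.0)
    np.fill_diagonal(dk2, 0.0)

    return DuplexState(dphi1, dphi2, dk1, dk2)


# ---------------------------------------------------------------------------
# Flat-vector packing used by the integrator.
#
# Layout (documented, fixed): [phi1 (N), phi2 (N), kappa1 off-diagonals in
# row-major order skipping the diagonal (N*(N-1)), kappa2 likewise], a total
# of 2N + 2N(N-1) unknowns.
# ---------------------------------------------------------------------------

def state_size(n: int) -> int:
    """Number of packed unknowns: 2N + 2N(N-1)."""
    return 2 * n + 2 * n * (n - 1)


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def pack_state(state: DuplexState) -> np.ndarray:
    n = state.n
    mask = _offdiag_mask(n)
    return np.concatenate(
        [state.phi1, state.phi2, state.kappa1[mask], state.kappa2[mask]]
    )


def unpack_state(y: np.ndarray, n: int) -> DuplexState:
    if y.shape != (state_size(n),):
        raise DimensionError("y", f"expected shape ({state_size(n)},), got {y.shape}")
    m = n * (n - 1)
    mask = _offdiag_mask(n)
    k1 = np.zeros((n, n))
    k2 = np.zeros((n, n))
    k1[mask] = y[2 * n : 2 * n + m]
    k2[mask] = y[2 * n + m :]
    return DuplexState(y[:n].copy(), y[n : 2 * n].copy(), k1, k2)
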