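"""Analytic trajectory constructors for the state taxonomy.

Each constructor builds a :class:`~sepsisnet.integrate.Trajectory` whose
phases satisfy the defining property of a named dynamical state exactly —
no ODE integration is involved — so that measure and classifier tests are
not confounded by solver error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .exceptions import ParameterError
from .integrate import Trajectory
from .model import ModelParams, kappa_sync_fixed_point

__all__ = ["FixtureSpec", "make_fixture", "KINDS"]

KINDS = ("in-phase", "splay", "two-frequency-cluster", "antipodal", "drifting-layers")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one analytic trajectory.

    kind
        * ``in-phase``: phi_j = omega * t in both layers.
        * ``splay``: phi_j = 2*pi*j/N + omega * t (R2 identically 0).
        * ``antipodal``: half the phases at 0, half at pi, drifting at
          omega (R2 identically 1).
        * ``two-frequency-cluster``: the first ``cluster_sizes[0]`` nodes
          of layer 1 run at ``freqs[0]``, the rest at ``freqs[1]``;
          layer 2 runs in-phase at the layer-1 mean frequency.
        * ``drifting-layers``: both layers in-phase internally but at
          different frequencies ``freqs`` (no interlayer locking).
    """

    kind: str
    n: int = 200
    omega: float = 1.0
    freqs: Tuple[float, float] = (1.0, 0.8)
    cluster_sizes: Optional[Tuple[int, int]] = None
    interlayer_offset: float = 0.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ParameterError("kind", f"unknown fixture kind {self.kind!r}; known: {KINDS}")
        if self.n < 2:
            raise ParameterError("n", f"need N >= 2, got {self.n}")
        if self.kind == "two-frequency-cluster":
            sizes = self.cluster_sizes or (3 * self.n // 4, self.n - 3 * self.n // 4)
            if sum(sizes) != self.n:
                raise ParameterError("cluster_sizes", f"sizes {sizes} must sum to N={self.n}")
            object.__setattr__(self, "cluster_sizes", tuple(int(s) for s in sizes))


def make_fixture(
    spec: FixtureSpec, t_end: float = 100.0, sampling: float = 0.5
) -> Trajectory:
    """Sample the analytic trajectory on a uniform grid [0, t_end]."""
    times = np.arange(0.0, t_end + 0.5 * sampling, sampling)
    n = spec.n
    t = times[:, None]

    if spec.kind == "in-phase":
        phi1 = np.broadcast_to(spec.omega * t, (len(times), n)).copy()
        phi2 = phi1 + spec.interlayer_offset
    elif spec.kind == "splay":
        base = 2.0 * np.pi * np.arange(n) / n
        phi1 = base[None, :] + spec.omega * t
        phi2 = phi1 + spec.interlayer_offset
    elif spec.kind == "antipodal":
        base = np.where(np.arange(n) % 2 == 0, 0.0, np.pi)
        phi1 = base[None, :] + spec.omega * t
        phi2 = phi1 + spec.interlayer_offset
    elif spec.kind == "two-frequency-cluster":
        n_big, n_small = spec.cluster_sizes
        w = np.concatenate([np.full(n_big, spec.freqs[0]), np.full(n_small, spec.freqs[1])])
        phi1 = w[None, :] * t
        phi2 = np.broadcast_to(w.mean() * t, (len(times), n)).copy()
    elif spec.kind == "drifting-layers":
        phi1 = np.broadcast_to(spec.freqs[0] * t, (len(times), n)).copy()
        phi2 = np.broadcast_to(spec.freqs[1] * t, (len(times), n)).copy()
    else:  # pragma: no cover - guarded in FixtureSpec
        raise ParameterError("kind", spec.kind)

    params = ModelParams(n=n)
    k_sync = kappa_sync_fixed_point(params.beta)
    kappa = np.full((n, n), k_sync if spec.kind == "in-phase" else 0.0)
    np.fill_diagonal(kappa, 0.0)
    return Trajectory(
        times=times,
        phi1=np.ascontiguousarray(phi1, dtype=float),
        phi2=np.ascontiguousarray(phi2, dtype=float),
        params=params,
        kappa1_final=kappa.copy(),
        kappa2_final=kappa.copy(),
        meta={"fixture": spec.kind},
    )
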