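"""Time integration of the duplex system and the sampled Trajectory container.

The dynamics are slow-fast (adaptation rates down to 0.03 against phase
frequencies of order 1) but not stiff, so an adaptive explicit Runge-Kutta
scheme of order 5(4) with rtol 1e-6 / atol 1e-8 is used, sampling every 0.5
time units by default.  Phases are integrated as unwrapped reals; mean
phase velocities are later computed from endpoint differences, which
requires exactly this.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from . import _rhs
from .exceptions import DimensionError, IntegrationError
from .model import DuplexState, ModelParams, pack_state, unpack_state

__all__ = ["Trajectory", "simulate", "unwrap_check"]


@dataclass
class Trajectory:
    """Time-sampled solution.

    ``phi1``/``phi2`` have shape (S, N) with unwrapped phases; weight
    matrices are stored at the final time always, and at a configurable
    stride of sample points when ``kappa_stride`` was given to
    :func:`simulate` (a full kappa history is O(N^2) per sample).
    """

    times: np.ndarray
    phi1: np.ndarray
    phi2: np.ndarray
    params: ModelParams
    kappa1_final: np.ndarray
    kappa2_final: np.ndarray
    kappa_times: Optional[np.ndarray] = None
    kappa1_snaps: Optional[np.ndarray] = None  # (K, N, N)
    kappa2_snaps: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.phi1.shape[1]

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def final_state(self) -> DuplexState:
        return DuplexState(
            self.phi1[-1].copy(), self.phi2[-1].copy(),
            self.kappa1_final.copy(), self.kappa2_final.copy(),
        )

    # -- persistence --------------------------------------------------------

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("phi1", data=self.phi1)
            f.create_dataset("phi2", data=self.phi2)
            f.create_dataset("kappa1_final", data=self.kappa1_final)
            f.create_dataset("kappa2_final", data=self.kappa2_final)
            if self.kappa_times is not None:
                f.create_dataset("kappa_times", data=self.kappa_times)
                f.create_dataset("kappa1_snaps", data=self.kappa1_snaps)
                f.create_dataset("kappa2_snaps", data=self.kappa2_snaps)
            f.attrs["params"] = json.dumps(self.params.to_dict())
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def from_hdf5(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as f:
            kw = {}
            if "kappa_times" in f:
                kw = dict(
                    kappa_times=f["kappa_times"][:],
                    kappa1_snaps=f["kappa1_snaps"][:],
                    kappa2_snaps=f["kappa2_snaps"][:],
                )
            return cls(
                times=f["times"][:],
                phi1=f["phi1"][:],
                phi2=f["phi2"][:],
                params=ModelParams.from_dict(json.loads(f.attrs["params"])),
                kappa1_final=f["kappa1_final"][:],
                kappa2_final=f["kappa2_final"][:],
                meta=json.loads(f.attrs["meta"]),
                **kw,
            )


def simulate(
    state0: DuplexState,
    params: ModelParams,
    t_end: float,
    sampling: float = 0.5,
    *,
    t0: float = 0.0,
    method: str = "RK45",
    rtol: float = 1e-6,
    atol: float = 1e-8,
    kappa_stride: Optional[int] = None,
    seed: Optional[int] = None,
) -> Trajectory:
    """Integrate the full duplex system from ``state0`` to ``t_end``.

    Parameters
    ----------
    state0, params
        Initial state and model constants; dimensions must agree.
    t_end, sampling
        Final time and sample interval (time units).
    kappa_stride
        If given, keep full weight matrices every ``kappa_stride``-th
        sample; the final matrices are always kept.
    seed
        Recorded in ``meta`` for provenance only (the dynamics are
        deterministic).

    Raises
    ------
    IntegrationError
        On solver failure or NaN in the solution, carrying the last good
        time reached.
    """
    state0.validate_against(params)
    if t_end <= t0:
        raise IntegrationError(f"t_end ({t_end}) must exceed t0 ({t0})")
    n = params.n
    y0 = pack_state(state0)
    a = np.ascontiguousarray(params.adjacency_matrix())

    def fun(t, y):
        return _rhs.rhs_packed(
            y, n, a,
            params.omega1, params.omega2,
            params.alpha11, params.alpha22, params.alpha12, params.alpha21,
            params.beta, params.eps1, params.eps2, params.sigma,
        )

    t_eval = np.arange(t0, t_end + 0.5 * sampling, sampling)
    if t_eval[-1] > t_end:
        t_eval[-1] = t_end
    elif t_eval[-1] < t_end:
        t_eval = np.append(t_eval, t_end)

    sol = solve_ivp(
        fun, (t0, t_end), y0, method=method, rtol=rtol, atol=atol, t_eval=t_eval
    )
    last_good = float(sol.t[-1]) if sol.t.size else t0
    if not sol.success:
        raise IntegrationError(f"integrator failed: {sol.message}", last_good_time=last_good)
    if np.isnan(sol.y).any():
        first_bad = sol.t[np.isnan(sol.y).any(axis=0)][0]
        raise IntegrationError("NaN detected in solution", last_good_time=float(first_bad))

    m = n * (n - 1)
    phi1 = sol.y[:n].T.copy()
    phi2 = sol.y[n : 2 * n].T.copy()

    final = unpack_state(sol.y[:, -1].copy(), n)

    kw = {}
    if kappa_stride is not None:
        idx = np.arange(0, len(sol.t), kappa_stride)
        if idx[-1] != len(sol.t) - 1:
            idx = np.append(idx, len(sol.t) - 1)
        k1s = np.empty((len(idx), n, n))
        k2s = np.empty((len(idx), n, n))
        for k, i in enumerate(idx):
            st = unpack_state(sol.y[:, i].copy(), n)
            k1s[k] = st.kappa1
            k2s[k] = st.kappa2
        kw = dict(kappa_times=sol.t[idx].copy(), kappa1_snaps=k1s, kappa2_snaps=k2s)

    meta = {
        "method": method,
        "rtol": rtol,
        "atol": atol,
        "sampling": sampling,
        "nfev": int(sol.nfev),
        "n_steps": int(len(sol.t)),
        "seed": seed,
    }
    return Trajectory(
        times=sol.t.copy(), phi1=phi1, phi2=phi2, params=params,
        kappa1_final=final.kappa1, kappa2_final=final.kappa2, meta=meta, **kw,
    )


def unwrap_check(traj: Trajectory, guard: float = 0.9) -> bool:
    """True iff no sample-to-sample phase jump exceeds ``guard * pi``.

    A False return means the sampling is too coarse relative to the
    oscillation frequency, so endpoint-based mean phase velocities could
    alias.
    """
    for phi in (traj.phi1, traj.phi2):
        if phi.shape[0] >= 2:
            if np.abs(np.diff(phi, axis=0)).max() > guard * np.pi:
                return False
    return True
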