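"""Synchronization and pathology measures computed from a trajectory.

The taxonomy: a layer whose nodes all share one mean phase velocity is
frequency-synchronized (healthy).  Within the frequency-synchronized
states the second Kuramoto-Daido moment R2 separates antipodal states
(R2 = 1, includes in-phase; robust) from splay states (R2 = 0; vulnerable).
A layer that splits into groups with distinct mean phase velocities is a
multifrequency-cluster state — the model's pathological (septic) condition
when it occurs in the parenchyma, or persistent immune activation when it
occurs only in the immune layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import DimensionError, ParameterError
from .integrate import Trajectory

__all__ = [
    "MeasureSummary",
    "mean_phase_velocities",
    "order_parameter_R2",
    "r2_time_averaged",
    "frequency_std",
    "detect_frequency_cluster",
    "detect_splay",
    "detect_interlayer_locking",
    "classify_state",
    "summarize",
    "DELTA_FREQ",
    "SPLAY_R2_THRESHOLD",
    "LOCKING_TOL",
]

# Numerical thresholds realizing the strict equalities/inequalities of the
# state taxonomy on finite-window data.
DELTA_FREQ = 0.01  # rad/time: a node "deviates" if |<dphi_j>-mean| exceeds this
SPLAY_R2_THRESHOLD = 0.05  # time-averaged R2 below this counts as splay
LOCKING_TOL = 0.01  # rad: max std of phi1_i - phi2_i over the window


@dataclass
class MeasureSummary:
    """Per-run measures and the resulting state label.

    ``mean_phase_velocity`` has shape (2, N); tuples are indexed by layer
    (0 = parenchyma, 1 = immune).
    """

    mean_phase_velocity: np.ndarray
    layer_mean_frequency: Tuple[float, float]
    R2: Tuple[float, float]
    freq_std: Tuple[float, float]
    freq_std_normalized: Tuple[float, float]
    has_frequency_cluster: Tuple[bool, bool]
    cluster_sizes: Tuple[Tuple[int, ...], Tuple[int, ...]]
    is_splay: Tuple[bool, bool]
    interlayer_locked: bool
    locking_offsets: Optional[np.ndarray]
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "mean_phase_velocity": self.mean_phase_velocity.tolist(),
            "layer_mean_frequency": list(self.layer_mean_frequency),
            "R2": list(self.R2),
            "freq_std": list(self.freq_std),
            "freq_std_normalized": list(self.freq_std_normalized),
            "has_frequency_cluster": list(self.has_frequency_cluster),
            "cluster_sizes": [list(c) for c in self.cluster_sizes],
            "is_splay": list(self.is_splay),
            "interlayer_locked": self.interlayer_locked,
            "locking_offsets": None
            if self.locking_offsets is None
            else self.locking_offsets.tolist(),
            "label": self.label,
        }


def _window_index(traj: Trajectory, window: float) -> int:
    """Index of the sample closest to t_end - window."""
    if window <= 0:
        raise ParameterError("window", f"averaging window must be > 0, got {window}")
    if window > traj.duration + 1e-9:
        raise ParameterError(
            "window",
            f"averaging window {window} exceeds trajectory span {traj.duration}",
        )
    return int(np.argmin(np.abs(traj.times - (traj.times[-1] - window))))


def mean_phase_velocities(
    traj: Trajectory, window: float
) -> tuple[np.ndarray, np.ndarray]:
    """Endpoint mean phase velocities over the trailing ``window``.

    Returns ``(vel, mean)`` where ``vel`` has shape (2, N) with
    (phi_j(t_end) - phi_j(t_end - T)) / T per node and layer, and ``mean``
    holds the per-layer node averages (the layer frequencies).
    Phases must be unwrapped, which the integrator guarantees.
    """
    i0 = _window_index(traj, window)
    t_span = traj.times[-1] - traj.times[i0]
    vel = np.stack(
        [
            (traj.phi1[-1] - traj.phi1[i0]) / t_span,
            (traj.phi2[-1] - traj.phi2[i0]) / t_span,
        ]
    )
    return vel, vel.mean(axis=1)


def order_parameter_R2(phases: np.ndarray) -> float:
    """Second moment of the Kuramoto-Daido order parameter,
    ``|mean_j exp(2i phi_j)|`` in [0, 1]."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise DimensionError("phases", "empty phase vector")
    return float(np.abs(np.mean(np.exp(2j * phases))))


def r2_time_averaged(traj: Trajectory, window: float, layer: int) -> float:
    """Time average of R2 over the trailing ``window`` of samples."""
    i0 = _window_index(traj, window)
    phi = traj.phi1 if layer == 0 else traj.phi2
    z = np.abs(np.mean(np.exp(2j * phi[i0:]), axis=1))
    return float(z.mean())


def frequency_std(freqs: np.ndarray) -> float:
    """Population standard deviation (divisor N) of the per-node mean
    phase velocities about their layer mean."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise DimensionError("freqs", "empty frequency vector")
    return float(np.sqrt(np.mean((freqs - freqs.mean()) ** 2)))


def detect_frequency_cluster(
    freqs: np.ndarray, delta: float = DELTA_FREQ
) -> tuple[bool, List[np.ndarray]]:
    """Flag deviating frequencies and partition nodes into frequency groups.

    A layer holds a frequency cluster iff any node's mean phase velocity
    deviates from the layer mean by more than ``delta``.  The partition is
    single-linkage on the sorted frequencies: a new group starts wherever
    the gap between consecutive sorted values exceeds ``delta``.
    Returns ``(flag, groups)`` with groups as arrays of node indices.
    """
    if delta <= 0:
        raise ParameterError("delta", f"tolerance must be > 0, got {delta}")
    freqs = np.asarray(freqs, dtype=float)
    flag = bool(np.any(np.abs(freqs - freqs.mean()) > delta))
    order = np.argsort(freqs, kind="stable")
    groups: List[np.ndarray] = []
    start = 0
    fs = freqs[order]
    for k in range(1, len(fs)):
        if fs[k] - fs[k - 1] > delta:
            groups.append(np.sort(order[start:k]))
            start = k
    groups.append(np.sort(order[start:]))
    groups.sort(key=len, reverse=True)
    return flag, groups


def detect_splay(
    traj: Trajectory,
    window: float,
    layer: int,
    delta: float = DELTA_FREQ,
    r2_threshold: float = SPLAY_R2_THRESHOLD,
) -> bool:
    """True iff the layer is frequency-synchronized with time-averaged
    R2 below ``r2_threshold`` (the numerical rendering of R2 = 0)."""
    vel, _ = mean_phase_velocities(traj, window)
    clustered, _ = detect_frequency_cluster(vel[layer], delta)
    if clustered:
        return False
    return r2_time_averaged(traj, window, layer) < r2_threshold


def detect_interlayer_locking(
    traj: Trajectory, window: float, tol: float = LOCKING_TOL
) -> tuple[bool, np.ndarray]:
    """Interlayer phase locking: phi1_i(t) - phi2_i(t) ~ Delta_i.

    Locked iff the std over the trailing window of every per-node
    interlayer difference is below ``tol``.  Offsets are window means
    reduced to [0, 2*pi).
    """
    i0 = _window_index(traj, window)
    diff = traj.phi1[i0:] - traj.phi2[i0:]
    locked = bool(np.all(diff.std(axis=0) < tol))
    offsets = np.mod(diff.mean(axis=0), 2.0 * np.pi)
    return locked, offsets


def classify_state(summary: MeasureSummary) -> str:
    """Map a measure summary to one of the four state labels.

    Priority: a parenchymal frequency cluster is pathological regardless
    of the immune layer; otherwise an immune cluster with synchronized
    parenchyma is the resilient state; otherwise a splay parenchyma is
    vulnerable; otherwise healthy in-phase/antipodal synchronization.
    The mapping is total: every summary yields exactly one label.
    """
    if summary.has_frequency_cluster[0]:
        return "frequency-cluster-pathological"
    if summary.has_frequency_cluster[1]:
        return "immune-activated-parenchyma-healthy"
    if summary.is_splay[0]:
        return "splay-vulnerable"
    return "in-phase-healthy"


def summarize(
    traj: Trajectory,
    window: float,
    delta: float = DELTA_FREQ,
    r2_threshold: float = SPLAY_R2_THRESHOLD,
    locking_tol: float = LOCKING_TOL,
) -> MeasureSummary:
    """Compute all measures over the trailing ``window`` and classify."""
    vel, means = mean_phase_velocities(traj, window)
    r2 = tuple(r2_time_averaged(traj, window, layer) for layer in (0, 1))
    stds = tuple(frequency_std(vel[layer]) for layer in (0, 1))
    stds_norm = tuple(
        float(s / abs(m)) if abs(m) > 1e-12 else float("nan")
        for s, m in zip(stds, means)
    )
    flags = []
    sizes = []
    for layer in (0, 1):
        flag, groups = detect_frequency_cluster(vel[layer], delta)
        flags.append(flag)
        sizes.append(tuple(len(g) for g in groups))
    splay = tuple(
        not flags[layer]
        and r2[layer] < r2_threshold
        for layer in (0, 1)
    )
    locked, offsets = detect_interlayer_locking(traj, window, locking_tol)
    summary = MeasureSummary(
        mean_phase_velocity=vel,
        layer_mean_frequency=(float(means[0]), float(means[1])),
        R2=(float(r2[0]), float(r2[1])),
        freq_std=(float(stds[0]), float(stds[1])),
        freq_std_normalized=stds_norm,
        has_frequency_cluster=(bool(flags[0]), bool(flags[1])),
        cluster_sizes=(sizes[0], sizes[1]),
        is_splay=(bool(splay[0]), bool(splay[1])),
        interlayer_locked=locked,
        locking_offsets=offsets,
    )
    summary.label = classify_state(summary)
    return summary
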