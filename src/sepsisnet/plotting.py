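"""Diagnostic rendering: per-run panels and regime-map heat maps."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import List, Optional

import numpy as np

from .ensemble import RegimeMap
from .integrate import Trajectory
from .measures import mean_phase_velocities

__all__ = ["render_diagnostics"]


def _get_pyplot():
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        return plt
    except Exception:  # pragma: no cover
        warnings.warn("matplotlib backend unavailable; rendering skipped")
        return None


def _render_trajectory(traj: Trajectory, out_dir: Path, plt) -> List[Path]:
    """Panel set for one run: kappa heat maps, frequency profile, phase
    snapshot (nodes sorted first by frequency, then by phase) and a
    space-time phase plot."""
    window = min(traj.duration / 2.0, traj.duration)
    vel, _ = mean_phase_velocities(traj, window)
    files = []

    fig, axes = plt.subplots(2, 4, figsize=(16, 7))
    for layer, (phi, kappa) in enumerate(
        [(traj.phi1, traj.kappa1_final), (traj.phi2, traj.kappa2_final)]
    ):
        order = np.lexsort((np.mod(phi[-1], 2 * np.pi), vel[layer]))
        ax = axes[layer, 0]
        im = ax.imshow(kappa[np.ix_(order, order)], cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_title(f"$\\kappa^{{{layer + 1}}}$")
        fig.colorbar(im, ax=ax, shrink=0.8)

        ax = axes[layer, 1]
        ax.plot(vel[layer][order], ".", ms=3)
        ax.set_title(f"mean phase velocity, layer {layer + 1}")
        ax.set_xlabel("node (sorted)")

        ax = axes[layer, 2]
        ax.plot(np.mod(phi[-1][order], 2 * np.pi), ".", ms=3)
        ax.set_ylim(0, 2 * np.pi)
        ax.set_title(f"phase snapshot, layer {layer + 1}")

        ax = axes[layer, 3]
        t0 = max(0, len(traj.times) - 200)
        im = ax.imshow(
            np.mod(phi[t0:, order].T, 2 * np.pi),
            aspect="auto",
            origin="lower",
            cmap="twilight",
            extent=[traj.times[t0], traj.times[-1], 0, traj.n],
        )
        ax.set_title(f"space-time phases, layer {layer + 1}")
        ax.set_xlabel("t")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    out = out_dir / "trajectory_panels.png"
    fig.savefig(out, dpi=120)
    plt.close(fig)
    files.append(out)
    return files


def _render_map(rmap: RegimeMap, out_dir: Path, plt) -> List[Path]:
    files = []
    if rmap.table.empty:
        warnings.warn("empty regime map; nothing to render")
        return files
    for column in ("s", "f", "splay_ratio"):
        fig, axes = plt.subplots(1, 2, figsize=(11, 4))
        for layer, ax in zip((1, 2), axes):
            sub = rmap.table[rmap.table["layer"] == layer]
            if rmap.axis2_name is None:
                ax.plot(sub[rmap.axis1_name], sub[column], "o-")
                ax.set_xlabel(rmap.axis1_name)
                ax.set_ylabel(column)
            else:
                pivot = sub.pivot(
                    index=rmap.axis2_name, columns=rmap.axis1_name, values=column
                )
                im = ax.pcolormesh(
                    pivot.columns.values, pivot.index.values, pivot.values,
                    shading="nearest", cmap="inferno",
                )
                fig.colorbar(im, ax=ax)
                ax.set_xlabel(rmap.axis1_name)
                ax.set_ylabel(rmap.axis2_name)
            ax.set_title(f"{column}, layer {layer}")
        fig.tight_layout()
        out = out_dir / f"map_{column}.png"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        files.append(out)
    return files


def render_diagnostics(
    traj: Optional[Trajectory] = None,
    regime_map: Optional[RegimeMap] = None,
    out_dir="figures",
) -> List[Path]:
    """Render available diagnostics to PNG files; returns written paths.

    Missing inputs are skipped with a warning rather than raising, so a
    partial render never aborts a run.
    """
    plt = _get_pyplot()
    if plt is None:  # pragma: no cover
        return []
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: List[Path] = []
    if traj is not None:
        files += _render_trajectory(traj, out_dir, plt)
    if regime_map is not None:
        files += _render_map(regime_map, out_dir, plt)
    if not files:
        warnings.warn("render_diagnostics called with no inputs; nothing rendered")
    return files
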