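"""Seeded ensembles over parameter grids and regime-map assembly.

The system is strongly multistable: from random initial conditions the
same parameters may relax to a healthy synchronized state or to a
pathological frequency-cluster state.  Regime maps therefore report
ensemble statistics — the mean frequency-desynchronization ``s`` (Eq.-5
style average of the per-run frequency standard deviation), the
frequency-cluster ratio ``f`` (fraction of members with a cluster) and the
splay ratio — over a fixed list of member seeds that is reused at every
grid point, so that differences across the grid reflect parameters, not
initial conditions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .initial import InitialConditionSpec, generate_initial_state, spawn_member_seeds
from .integrate import simulate
from .measures import DELTA_FREQ, MeasureSummary, summarize
from .model import ModelParams

__all__ = [
    "SweepSpec",
    "RegimeMap",
    "run_ensemble",
    "aggregate_summaries",
    "sweep_grid",
    "smooth_curve",
    "SWEEPABLE",
    "FULL_SCALE",
    "DESK_SCALE",
]

SWEEPABLE = ("beta", "sigma", "alpha_inter", "C")

# Run controls.  DESK_SCALE is the default working scale (global coupling
# makes the thresholds only weakly N-dependent); FULL_SCALE matches the
# reference regime maps.
DESK_SCALE = dict(n=50, n_e=10, t_end=1000.0, window=500.0)
FULL_SCALE = dict(n=200, n_e=50, t_end=2000.0, window=1000.0)


@dataclass(frozen=True)
class SweepSpec:
    """A 1-D or 2-D parameter sweep with seeded ensembles.

    ``axis1``/``axis2`` are (name, values) pairs with names drawn from
    ``beta``, ``sigma``, ``alpha_inter`` (sets both interlayer lags) and
    ``C`` (immune perturbation size; values < 1 are read as the fraction
    C/N).  ``c_frac`` fixes C when it is not swept.
    """

    axis1: Tuple[str, Tuple[float, ...]]
    axis2: Optional[Tuple[str, Tuple[float, ...]]] = None
    n_e: int = DESK_SCALE["n_e"]
    master_seed: int = 0
    n: int = DESK_SCALE["n"]
    c_frac: float = 0.2
    t_end: float = DESK_SCALE["t_end"]
    window: float = DESK_SCALE["window"]
    sampling: float = 0.5
    delta: float = DELTA_FREQ
    base_params: Optional[ModelParams] = None
    full_scale: bool = False

    def __post_init__(self):
        for ax in (self.axis1, self.axis2):
            if ax is None:
                continue
            name, values = ax
            if name not in SWEEPABLE:
                raise ParameterError("axis", f"sweepable parameters are {SWEEPABLE}, got {name!r}")
            values = tuple(float(v) for v in values)
            if not all(np.isfinite(values)):
                raise ParameterError("axis", f"non-finite value in axis {name!r}")
        object.__setattr__(self, "axis1", (self.axis1[0], tuple(float(v) for v in self.axis1[1])))
        if self.axis2 is not None:
            object.__setattr__(
                self, "axis2", (self.axis2[0], tuple(float(v) for v in self.axis2[1]))
            )
        if self.n_e < 1:
            raise ParameterError("n_e", f"ensemble size must be >= 1, got {self.n_e}")
        if self.full_scale:
            object.__setattr__(self, "n", FULL_SCALE["n"])
            object.__setattr__(self, "n_e", FULL_SCALE["n_e"])
            object.__setattr__(self, "t_end", FULL_SCALE["t_end"])
            object.__setattr__(self, "window", FULL_SCALE["window"])

    def params(self) -> ModelParams:
        base = self.base_params or ModelParams()
        if base.n != self.n:
            base = replace(base, n=self.n)
        return base


@dataclass
class RegimeMap:
    """Gridded ensemble statistics.

    ``table`` is tidy: one row per (axis1, axis2, layer) with columns
    ``s`` (mean frequency std), ``s_norm``, ``f`` (frequency-cluster
    ratio), ``splay_ratio``, ``mean_R2``, ``n_members``, ``n_failed``.
    ``members`` holds one row per ensemble member and layer.
    """

    axis1_name: str
    axis1_values: Tuple[float, ...]
    axis2_name: Optional[str]
    axis2_values: Optional[Tuple[float, ...]]
    table: pd.DataFrame
    members: pd.DataFrame
    spec: Optional[SweepSpec] = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def curve(self, column: str = "f", layer: int = 1) -> pd.DataFrame:
        """1-D slice of an aggregate column for one layer (layer is 1-based
        in the table: 1 = parenchyma, 2 = immune)."""
        sub = self.table[self.table["layer"] == layer]
        return sub[[self.axis1_name, column]].reset_index(drop=True)


def _apply_axis(params: ModelParams, c: int, n: int, name: str, value: float):
    """Return (params, c) with one swept parameter applied."""
    if name == "beta":
        return replace(params, beta=value), c
    if name == "sigma":
        return replace(params, sigma=value), c
    if name == "alpha_inter":
        return replace(params, alpha12=value, alpha21=value), c
    if name == "C":
        c_new = int(round(value * n)) if 0 < value < 1 else int(round(value))
        return params, c_new
    raise ParameterError("axis", f"unknown sweep parameter {name!r}")


def run_ensemble(
    params: ModelParams,
    c: int,
    seeds: Sequence[int],
    t_end: float,
    window: float,
    sampling: float = 0.5,
    delta: float = DELTA_FREQ,
) -> tuple[List[Optional[MeasureSummary]], dict]:
    """One full simulate+measure per seed, plus ensemble aggregates.

    Member failures (integration errors) are recorded as ``None`` entries
    and counted in the aggregates rather than raised.  Aggregates are
    independent of the order of ``seeds``.
    """
    summaries: List[Optional[MeasureSummary]] = []
    for seed in seeds:
        ic = generate_initial_state(InitialConditionSpec(n=params.n, c=c, seed=int(seed)))
        try:
            traj = simulate(ic, params, t_end, sampling, seed=int(seed))
            summaries.append(summarize(traj, window, delta=delta))
        except Exception:
            summaries.append(None)
    return summaries, aggregate_summaries(summaries)


def aggregate_summaries(summaries: Sequence[Optional[MeasureSummary]]) -> dict:
    """Ensemble aggregates from per-member summaries.

    ``s`` per layer is the mean of the member frequency standard
    deviations; ``f`` is the fraction of members whose layer holds a
    frequency cluster; ``splay_ratio`` likewise for splay states.  Failed
    members (``None``) are excluded from means and counted in
    ``n_failed``.
    """
    ok = [s for s in summaries if s is not None]
    n_e = len(summaries)
    out: dict = {"n_members": n_e, "n_ok": len(ok), "n_failed": n_e - len(ok)}
    for layer in (0, 1):
        tag = str(layer + 1)
        if ok:
            out[f"s{tag}"] = float(np.mean([s.freq_std[layer] for s in ok]))
            norm = [
                s.freq_std_normalized[layer]
                for s in ok
                if np.isfinite(s.freq_std_normalized[layer])
            ]
            out[f"s{tag}_norm"] = float(np.mean(norm)) if norm else float("nan")
            out[f"f{tag}"] = float(
                np.mean([s.has_frequency_cluster[layer] for s in ok])
            )
            out[f"splay_ratio{tag}"] = float(np.mean([s.is_splay[layer] for s in ok]))
            out[f"mean_R2_{tag}"] = float(np.mean([s.R2[layer] for s in ok]))
        else:
            for key in ("s", "s_norm", "f", "splay_ratio", "mean_R2_"):
                out[f"{key}{tag}" if key != "mean_R2_" else f"mean_R2_{tag}"] = float("nan")
    return out


def sweep_grid(
    spec: SweepSpec,
    checkpoint_dir: Optional[Path] = None,
    progress: bool = False,
) -> RegimeMap:
    """Run the seeded ensemble at every grid cell and assemble the map.

    The identical member-seed list (from ``spawn_member_seeds``) is reused
    at every cell.  If ``checkpoint_dir`` is given, per-cell results are
    written as JSON and previously completed cells are loaded instead of
    recomputed, making partial grids resumable.
    """
    seeds = spawn_member_seeds(spec.master_seed, spec.n_e)
    base = spec.params()
    c_default = int(round(spec.c_frac * spec.n)) if 0 < spec.c_frac < 1 else int(spec.c_frac)

    axis1_name, axis1_values = spec.axis1
    axis2 = spec.axis2 or (None, (float("nan"),))
    axis2_name, axis2_values = axis2

    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    member_rows = []
    for i1, v1 in enumerate(axis1_values):
        for i2, v2 in enumerate(axis2_values):
            cell_tag = f"cell_{i1:03d}_{i2:03d}"
            ck = checkpoint_dir / f"{cell_tag}.json" if checkpoint_dir else None
            if ck is not None and ck.exists():
                payload = json.loads(ck.read_text())
            else:
                params, c = _apply_axis(base, c_default, spec.n, axis1_name, v1)
                if axis2_name is not None:
                    params, c = _apply_axis(params, c, spec.n, axis2_name, v2)
                summaries, agg = run_ensemble(
                    params, c, seeds, spec.t_end, spec.window, spec.sampling, spec.delta
                )
                payload = {
                    "agg": agg,
                    "members": [
                        None
                        if s is None
                        else {
                            "s": list(s.freq_std),
                            "f": list(s.has_frequency_cluster),
                            "splay": list(s.is_splay),
                            "R2": list(s.R2),
                            "label": s.label,
                            "seed": int(seed),
                        }
                        for s, seed in zip(summaries, seeds)
                    ],
                }
                if ck is not None:
                    ck.write_text(json.dumps(payload))
            if progress:  # pragma: no cover
                print(f"{axis1_name}={v1:g}"
                      + (f" {axis2_name}={v2:g}" if axis2_name else "")
                      + f" f1={payload['agg'].get('f1')}")
            agg = payload["agg"]
            for layer in (1, 2):
                row = {axis1_name: v1, "layer": layer}
                if axis2_name is not None:
                    row[axis2_name] = v2
                row.update(
                    s=agg[f"s{layer}"],
                    s_norm=agg[f"s{layer}_norm"],
                    f=agg[f"f{layer}"],
                    splay_ratio=agg[f"splay_ratio{layer}"],
                    mean_R2=agg[f"mean_R2_{layer}"],
                    n_members=agg["n_members"],
                    n_failed=agg["n_failed"],
                )
                rows.append(row)
            for k, mem in enumerate(payload["members"]):
                if mem is None:
                    continue
                for layer in (0, 1):
                    mrow = {
                        axis1_name: v1,
                        "member": k,
                        "seed": mem["seed"],
                        "layer": layer + 1,
                        "freq_std": mem["s"][layer],
                        "has_cluster": bool(mem["f"][layer]),
                        "is_splay": bool(mem["splay"][layer]),
                        "R2": mem["R2"][layer],
                        "label": mem["label"],
                    }
                    if axis2_name is not None:
                        mrow[axis2_name] = v2
                    member_rows.append(mrow)

    return RegimeMap(
        axis1_name=axis1_name,
        axis1_values=axis1_values,
        axis2_name=axis2_name,
        axis2_values=None if spec.axis2 is None else axis2_values,
        table=pd.DataFrame(rows),
        members=pd.DataFrame(member_rows),
        spec=spec,
    )


def first_positive(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Smallest ``x`` at which ``y`` becomes positive, or None."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    hits = np.nonzero(y > 0)[0]
    return float(x[hits[0]]) if hits.size else None


def first_sustained_exceedance(
    x: Sequence[float],
    y: Sequence[float],
    threshold: float,
    sustain: int = 2,
) -> Optional[float]:
    """Onset detection on a rising curve.

    Returns the smallest ``x[i]`` with ``y[i] > threshold`` and ``y``
    nondecreasing over the following ``sustain`` grid points (points past
    the end of the grid cannot qualify).  None if no such point exists.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    for i in range(len(x) - sustain):
        if y[i] > threshold and all(
            y[i + k + 1] >= y[i + k] - 1e-12 for k in range(sustain)
        ):
            return float(x[i])
    return None


def smooth_curve(values: Sequence[float], window: int = 4) -> np.ndarray:
    """Trailing moving average with edges truncated to available points.

    ``out[i]`` is the mean of ``values[max(0, i - window + 1) : i + 1]``.
    Series shorter than ``window`` are rejected.
    """
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ParameterError("window", f"window must be >= 1, got {window}")
    if values.ndim != 1 or len(values) < window:
        raise ParameterError(
            "values", f"need a 1-D series of length >= {window}, got shape {values.shape}"
        )
    out = np.empty_like(values)
    for i in range(len(values)):
        out[i] = values[max(0, i - window + 1) : i + 1].mean()
    return out
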