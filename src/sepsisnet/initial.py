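"""Seeded initial conditions: random phases/parenchymal weights and the
two-block immune perturbation.

The initial state models the onset of sepsis: phases in both layers and the
parenchymal cytokine weights are random (no preferred pattern), while the
immune-layer weight matrix carries a deterministic two-cluster imprint — a
small activated cluster of ``C`` nodes and the remaining ``N - C`` nodes,
with weight 1 inside each block and 0 between them.  ``C`` plays the role of
the size of the initial local infection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .model import DuplexState

__all__ = ["InitialConditionSpec", "generate_initial_state", "spawn_member_seeds"]

_MAX_SEED = 2**31


@dataclass(frozen=True)
class InitialConditionSpec:
    """Recipe for one reproducible initial state.

    phases ~ U[0, 2*pi) i.i.d. in both layers; parenchymal weights
    ~ U[-1, 1] i.i.d. off-diagonal; immune weights are the deterministic
    two-block cluster matrix with small-cluster size ``c`` (occupying the
    first ``c`` indices — the base topology is all-to-all, so the labeling
    is arbitrary and fixed for reproducibility).
    """

    n: int
    c: int
    seed: int

    def __post_init__(self):
        if int(self.n) != self.n or self.n < 2:
            raise ParameterError("n", f"node count must be an integer >= 2, got {self.n}")
        if int(self.c) != self.c:
            raise ParameterError("c", f"cluster size must be an integer, got {self.c}")
        if not (1 < self.c < self.n):
            raise ParameterError("c", f"cluster size must satisfy 1 < C < N, got C={self.c}, N={self.n}")
        if int(self.seed) != self.seed:
            raise ParameterError("seed", f"seed must be an integer, got {self.seed!r}")
        object.__setattr__(self, "n", int(self.n))
        object.__setattr__(self, "c", int(self.c))
        object.__setattr__(self, "seed", int(self.seed))


def two_block_matrix(n: int, c: int) -> np.ndarray:
    """Immune-layer weight matrix: 1 within blocks {0..c-1} and {c..n-1},
    0 between blocks and on the diagonal."""
    k = np.zeros((n, n))
    k[:c, :c] = 1.0
    k[c:, c:] = 1.0
    np.fill_diagonal(k, 0.0)
    return k


def generate_initial_state(spec: InitialConditionSpec) -> DuplexState:
    """Draw one initial state.

    RNG discipline: a single ``numpy.random.default_rng(seed)`` (PCG64);
    draw order is phi1, phi2, kappa1 (full N x N row-major, diagonal then
    zeroed).  Same spec => bitwise-identical state.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    phi1 = rng.uniform(0.0, 2.0 * np.pi, size=n)
    phi2 = rng.uniform(0.0, 2.0 * np.pi, size=n)
    kappa1 = rng.uniform(-1.0, 1.0, size=(n, n))
    np.fill_diagonal(kappa1, 0.0)
    kappa2 = two_block_matrix(n, spec.c)
    return DuplexState(phi1, phi2, kappa1, kappa2)


def spawn_member_seeds(master_seed: int, n_e: int) -> list[int]:
    """Deterministic, collision-free child seeds for an ensemble.

    The same list is reused at every grid point of a parameter sweep so
    ensembles are identical across parameters.  Seeds are < 2**31.
    """
    if int(n_e) != n_e or n_e < 1:
        raise ParameterError("n_e", f"ensemble size must be an integer >= 1, got {n_e}")
    rng = np.random.default_rng(int(master_seed))
    seeds: list[int] = []
    seen = set()
    while len(seeds) < n_e:
        s = int(rng.integers(0, _MAX_SEED))
        if s not in seen:
            seen.add(s)
            seeds.append(s)
    return seeds
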