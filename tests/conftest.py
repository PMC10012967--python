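"""Shared fixtures: brute-force RHS oracle, random states, and the
session-scoped desk-scale ensemble sweeps reused by the regime tests."""

from __future__ import annotations

import numpy as np
import pytest

from sepsisnet import DuplexState, ModelParams
from sepsisnet.ensemble import SweepSpec, sweep_grid

MASTER_SEED = 12345  # master seed for all test-suite ensembles


def rhs_brute_force(state: DuplexState, params: ModelParams):
    """Literal double-loop transcription of the coupled ODE system;
    independent of the vectorized implementation."""
    n = params.n
    a = params.adjacency_matrix()
    dphi1 = np.zeros(n)
    dphi2 = np.zeros(n)
    dk1 = np.zeros((n, n))
    dk2 = np.zeros((n, n))
    for i in range(n):
        s1 = 0.0
        s2 = 0.0
        for j in range(n):
            if j == i:
                continue
            s1 += (a[i, j] + state.kappa1[i, j]) * np.sin(
                state.phi1[i] - state.phi1[j] + params.alpha11
            )
            s2 += state.kappa2[i, j] * np.sin(
                state.phi2[i] - state.phi2[j] + params.alpha22
            )
            dk1[i, j] = -params.eps1 * (
                state.kappa1[i, j] + np.sin(state.phi1[i] - state.phi1[j] - params.beta)
            )
            dk2[i, j] = -params.eps2 * (
                state.kappa2[i, j] + np.sin(state.phi2[i] - state.phi2[j] - params.beta)
            )
        dphi1[i] = (
            params.omega1
            - s1 / n
            - params.sigma * np.sin(state.phi1[i] - state.phi2[i] + params.alpha12)
        )
        dphi2[i] = (
            params.omega2
            - s2 / n
            - params.sigma * np.sin(state.phi2[i] - state.phi1[i] + params.alpha21)
        )
    return DuplexState(dphi1, dphi2, dk1, dk2)


def random_state(n: int, seed: int) -> DuplexState:
    rng = np.random.default_rng(seed)
    k1 = rng.uniform(-1, 1, (n, n))
    k2 = rng.uniform(-1, 1, (n, n))
    np.fill_diagonal(k1, 0.0)
    np.fill_diagonal(k2, 0.0)
    return DuplexState(
        rng.uniform(0, 2 * np.pi, n), rng.uniform(0, 2 * np.pi, n), k1, k2
    )


@pytest.fixture(scope="session")
def sigma_sweep_map():
    """Interlayer-coupling sweep at beta = 0.7*pi (desk scale):
    sigma in {0.30 ... 0.70} step 0.05, N = 50, C/N = 0.2, N_E = 10."""
    spec = SweepSpec(
        axis1=("sigma", tuple(np.round(np.arange(0.30, 0.701, 0.05), 10))),
        master_seed=MASTER_SEED,
        base_params=ModelParams(n=50, beta=0.7 * np.pi),
    )
    return sweep_grid(spec)


@pytest.fixture(scope="session")
def beta_sweep_map():
    """Age-parameter sweep at sigma = 1 (desk scale):
    beta in [0.40*pi, 0.70*pi] step 0.02*pi, N = 50, C/N = 0.2, N_E = 10."""
    spec = SweepSpec(
        axis1=("beta", tuple(np.round(np.arange(0.40, 0.701, 0.02), 10) * np.pi)),
        master_seed=MASTER_SEED,
        base_params=ModelParams(n=50, sigma=1.0),
    )
    return sweep_grid(spec)


@pytest.fixture(scope="session")
def low_beta_sweep_map():
    """Supplementary low-beta points (0.30*pi ... 0.45*pi) at sigma = 1 for
    the rising-threshold ordering check."""
    spec = SweepSpec(
        axis1=("beta", tuple(np.array([0.30, 0.35, 0.40, 0.45]) * np.pi)),
        master_seed=MASTER_SEED,
        base_params=ModelParams(n=50, sigma=1.0),
    )
    return sweep_grid(spec)


@pytest.fixture(scope="session")
def decoupled_sweep_map():
    """Below the existence bound (sigma = 0.2) the parenchyma evolves
    independently of the perturbed immune layer."""
    spec = SweepSpec(
        axis1=("beta", (0.5 * np.pi, 0.7 * np.pi)),
        master_seed=MASTER_SEED,
        base_params=ModelParams(n=50, sigma=0.2),
    )
    return sweep_grid(spec)
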