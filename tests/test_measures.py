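"""Synchronization measures and state classification on analytic inputs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sepsisnet import (
    DimensionError,
    ParameterError,
    classify_state,
    detect_frequency_cluster,
    detect_interlayer_locking,
    detect_splay,
    frequency_std,
    mean_phase_velocities,
    order_parameter_R2,
    summarize,
)
from sepsisnet.fixtures import FixtureSpec, make_fixture
from sepsisnet.integrate import Trajectory
from sepsisnet.measures import r2_time_averaged
from sepsisnet.model import ModelParams


def two_cluster_traj(n=200, n_big=150, f_big=1.0, f_small=0.8, t_end=100.0):
    return make_fixture(
        FixtureSpec(
            kind="two-frequency-cluster", n=n,
            cluster_sizes=(n_big, n - n_big), freqs=(f_big, f_small),
        ),
        t_end=t_end,
    )


class TestMeanPhaseVelocities:
    def test_linear_phase(self):
        traj = make_fixture(FixtureSpec(kind="in-phase", n=10, omega=1.7))
        vel, means = mean_phase_velocities(traj, 50.0)
        assert np.allclose(vel, 1.7, atol=1e-12)
        assert np.allclose(means, 1.7, atol=1e-12)

    def test_constant_phase(self):
        traj = make_fixture(FixtureSpec(kind="in-phase", n=10, omega=0.0))
        vel, _ = mean_phase_velocities(traj, 50.0)
        assert np.allclose(vel, 0.0, atol=1e-14)

    def test_two_cluster_arithmetic(self):
        """150 nodes at 1.0 and 50 at 0.8: layer mean 0.95, the small
        cluster deviates by 0.15, the large by 0.05."""
        traj = two_cluster_traj()
        vel, means = mean_phase_velocities(traj, 50.0)
        assert np.isclose(means[0], 0.95)
        assert np.allclose(vel[0][:150], 1.0) and np.allclose(vel[0][150:], 0.8)
        assert np.sum(np.abs(vel[0] - means[0]) > 0.1) == 50

    def test_window_exceeds_span(self):
        traj = make_fixture(FixtureSpec(kind="in-phase", n=4), t_end=10.0)
        with pytest.raises(ParameterError, match="window"):
            mean_phase_velocities(traj, 100.0)


class TestOrderParameterR2:
    def test_in_phase_is_one(self):
        assert order_parameter_R2(np.full(50, 1.234)) == pytest.approx(1.0)

    def test_splay_is_zero(self):
        phases = 2 * np.pi * np.arange(200) / 200
        assert order_parameter_R2(phases) < 1e-12

    def test_antipodal_is_one(self):
        phases = np.concatenate([np.zeros(100), np.full(100, np.pi)])
        assert order_parameter_R2(phases) == pytest.approx(1.0)

    def test_empty_vector_rejected(self):
        with pytest.raises(DimensionError):
            order_parameter_R2(np.array([]))

    @given(
        c=st.floats(-10, 10, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=25, deadline=None)
    def test_shift_and_permutation_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        phases = rng.uniform(0, 2 * np.pi, 30)
        r = order_parameter_R2(phases)
        assert 0.0 <= r <= 1.0
        assert order_parameter_R2(phases + c) == pytest.approx(r, abs=1e-10)
        assert order_parameter_R2(rng.permutation(phases)) == pytest.approx(r, abs=1e-12)


class TestFrequencyStd:
    def test_uniform(self):
        assert frequency_std(np.full(7, 2.2)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        """[1, 1, 1, 2]: mean 1.25, population std sqrt(0.75/4)."""
        assert frequency_std(np.array([1.0, 1, 1, 2])) == pytest.approx(0.4330127, abs=1e-6)

    def test_two_cluster_value(self):
        """Brute-force oracle: sqrt((150*0.05^2 + 50*0.15^2)/200)."""
        traj = two_cluster_traj()
        vel, _ = mean_phase_velocities(traj, 50.0)
        expected = np.sqrt((150 * 0.05**2 + 50 * 0.15**2) / 200)
        assert frequency_std(vel[0]) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.0866025, abs=1e-6)

    @given(
        c=st.floats(-5, 5, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=25, deadline=None)
    def test_linear_scaling(self, c, seed):
        freqs = np.random.default_rng(seed).normal(1.0, 0.3, 20)
        assert frequency_std(c * freqs) == pytest.approx(
            abs(c) * frequency_std(freqs), abs=1e-9
        )


class TestFrequencyClusterDetection:
    def test_uniform_single_cluster(self):
        flag, groups = detect_frequency_cluster(np.full(10, 1.5), delta=0.01)
        assert not flag
        assert len(groups) == 1 and len(groups[0]) == 10

    def test_single_deviating_node(self):
        freqs = np.full(10, 1.0)
        freqs[3] += 0.02  # 2 * delta
        flag, groups = detect_frequency_cluster(freqs, delta=0.01)
        assert flag
        assert sorted(len(g) for g in groups) == [1, 9]
        assert groups[-1][0] == 3 or any(3 in g and len(g) == 1 for g in groups)

    def test_two_cluster_partition(self):
        traj = two_cluster_traj()
        vel, _ = mean_phase_velocities(traj, 50.0)
        flag, groups = detect_frequency_cluster(vel[0], delta=0.01)
        assert flag
        assert [len(g) for g in groups] == [150, 50]
        assert np.array_equal(groups[1], np.arange(150, 200))

    def test_invalid_delta(self):
        with pytest.raises(ParameterError, match="delta"):
            detect_frequency_cluster(np.ones(3), delta=0.0)


class TestSplayDetection:
    def test_in_phase_not_splay(self):
        traj = make_fixture(FixtureSpec(kind="in-phase", n=50))
        assert not detect_splay(traj, 50.0, layer=0)

    def test_rotating_splay(self):
        traj = make_fixture(FixtureSpec(kind="splay", n=200, omega=1.0))
        assert detect_splay(traj, 50.0, layer=0)
        assert r2_time_averaged(traj, 50.0, 0) < 1e-10

    def test_frequency_cluster_not_splay(self):
        traj = two_cluster_traj()
        assert not detect_splay(traj, 50.0, layer=0)


class TestInterlayerLocking:
    def test_constant_offset_with_jitter(self):
        """phi1 - phi2 = 0.3 + 0.001 sin(t) is locked under tolerance 0.01."""
        base = make_fixture(FixtureSpec(kind="in-phase", n=6, omega=1.0), t_end=100.0)
        traj = Trajectory(
            times=base.times,
            phi1=base.phi1 + 0.3 + 0.001 * np.sin(base.times)[:, None],
            phi2=base.phi2,
            params=base.params,
            kappa1_final=base.kappa1_final,
            kappa2_final=base.kappa2_final,
        )
        locked, offsets = detect_interlayer_locking(traj, 50.0, tol=0.01)
        assert locked
        assert np.allclose(offsets, 0.3, atol=2e-3)

    def test_drifting_layers_not_locked(self):
        traj = make_fixture(FixtureSpec(kind="drifting-layers", n=6, freqs=(1.0, 0.8)))
        locked, _ = detect_interlayer_locking(traj, 50.0)
        assert not locked


class TestClassification:
    @pytest.mark.parametrize(
        "kind, kwargs, label",
        [
            ("in-phase", {}, "in-phase-healthy"),
            ("antipodal", {}, "in-phase-healthy"),
            ("splay", {}, "splay-vulnerable"),
            ("two-frequency-cluster", {}, "frequency-cluster-pathological"),
        ],
    )
    def test_fixture_roundtrip(self, kind, kwargs, label):
        traj = make_fixture(FixtureSpec(kind=kind, n=40, **kwargs))
        assert summarize(traj, 50.0).label == label

    def test_immune_cluster_parenchyma_healthy(self):
        """Parenchyma synchronized, immune layer clustered: the resilient
        state."""
        base = make_fixture(FixtureSpec(kind="two-frequency-cluster", n=40,
                                        cluster_sizes=(30, 10)))
        swapped = Trajectory(
            times=base.times, phi1=base.phi2, phi2=base.phi1,
            params=base.params,
            kappa1_final=base.kappa1_final, kappa2_final=base.kappa2_final,
        )
        assert summarize(swapped, 50.0).label == "immune-activated-parenchyma-healthy"

    def test_classification_is_total(self):
        """Every combination of flags maps to exactly one known label."""
        labels = set()
        for kind in ("in-phase", "splay", "antipodal", "two-frequency-cluster",
                     "drifting-layers"):
            traj = make_fixture(FixtureSpec(kind=kind, n=30))
            s = summarize(traj, 50.0)
            assert s.label == classify_state(s)
            labels.add(s.label)
        assert labels <= {
            "in-phase-healthy", "splay-vulnerable",
            "frequency-cluster-pathological", "immune-activated-parenchyma-healthy",
        }

    def test_summary_serializes(self):
        import json

        s = summarize(make_fixture(FixtureSpec(kind="splay", n=12)), 50.0)
        text = json.dumps(s.to_dict())
        assert "splay-vulnerable" in text
        assert 0.0 <= s.R2[0] <= 1.0
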