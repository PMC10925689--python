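"""Epileptor dynamics: nonlinearities, drift, integration, phenomenology."""

import numpy as np
import pytest

from epiprop.connectome import Connectome
from epiprop.detection import detect_onsets
from epiprop.epileptor import (
    EpileptorParams,
    IntegrationError,
    f1,
    f2,
    interictal_state,
    network_rhs,
    simulate,
    single_node_connectome,
)


class TestNonlinearities:
    def test_f1_continuous_at_branch_point(self):
        assert f1(0.0, 1.7, 2.9) == 0.0
        assert f1(-1e-12, 0.0, 0.0) == pytest.approx(0.0, abs=1e-11)

    def test_f1_ictal_branch(self):
        # x1 = 1, x2 = 0, z = 4: (0 - 0.6*0)*1 = 0
        assert f1(1.0, 0.0, 4.0) == 0.0

    def test_f1_cubic_branch(self):
        assert f1(-1.0, 0.0, 0.0) == -4.0

    @pytest.mark.parametrize("x2, expected", [(-0.5, 0.0), (-0.25, 0.0), (0.0, 1.5)])
    def test_f2_piecewise_linear(self, x2, expected):
        assert f2(x2) == pytest.approx(expected)


class TestNetworkRhs:
    def test_single_node_zero_state(self):
        p = EpileptorParams(x0=-1.6)
        d = network_rhs(np.zeros(6), p)
        np.testing.assert_allclose(d, [3.1, 1.0, 5.12e-4, 1.5, 0.15, 0.0])

    def test_z_negative_branch_includes_z7_term(self):
        p = EpileptorParams(x0=-1.6)
        st = np.zeros(6)
        st[2] = -1.0
        d = network_rhs(st, p)
        # r * (4*(0+1.6) + 1 + 0.1) = 8e-5 * 7.5
        assert d[2] == pytest.approx(6.0e-4)

    def test_coupling_vanishes_on_synchrony_manifold(self):
        rng = np.random.default_rng(0)
        W = rng.random((5, 5))
        np.fill_diagonal(W, 0.0)
        p = EpileptorParams(x0=-1.8, K=0.7)
        base = rng.standard_normal(6)
        state = np.repeat(base[:, None], 5, axis=1)
        d_net = network_rhs(state, p, W)
        d_single = network_rhs(base, p.replace(x0=-1.8))
        for i in range(5):
            np.testing.assert_allclose(d_net[:, i], d_single, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        p = EpileptorParams()
        with pytest.raises(ValueError):
            network_rhs(np.zeros((6, 3)), p, np.zeros((4, 4)))
        with pytest.raises(ValueError):
            network_rhs(np.zeros((5, 3)), p, np.zeros((3, 3)))


class TestSimulate:
    def test_ez_node_seizes_pz_node_does_not(self):
        C = single_node_connectome()
        tr_ez = simulate(C, EpileptorParams(x0=-1.6, sigma=0.0, duration=2500, seed=0))
        tr_pz = simulate(C, EpileptorParams(x0=-2.1, sigma=0.0, duration=2500, seed=0))
        on_ez = detect_onsets(tr_ez.z, tr_ez.times)
        on_pz = detect_onsets(tr_pz.z, tr_pz.times)
        assert not np.isnan(on_ez[0])
        assert np.isnan(on_pz[0])
        # the seizure shows a fast-discharge burst in the field potential
        post = tr_ez.times > on_ez[0]
        assert np.ptp(tr_ez.lfp[0][post]) > 1.0

    def test_sigma_zero_bit_reproducible(self):
        C = single_node_connectome()
        p = EpileptorParams(x0=-1.7, sigma=0.0, duration=400, seed=1)
        a = simulate(C, p)
        b = simulate(C, p)
        np.testing.assert_array_equal(a.states, b.states)

    def test_noise_seed_reproducible_and_seed_sensitive(self):
        C = Connectome(np.zeros((2, 2)))
        p = EpileptorParams(x0=-2.1, duration=300, seed=3)
        a = simulate(C, p)
        b = simulate(C, p)
        c = simulate(C, p.replace(seed=4))
        np.testing.assert_array_equal(a.states, b.states)
        assert np.any(a.states != c.states)

    def test_uncoupled_network_equals_isolated_runs(self):
        # K = 0, no jitter: each node evolves exactly as if alone
        W = np.zeros((3, 3))
        W[1, 0] = W[2, 1] = 0.5
        x0 = np.array([-1.6, -1.9, -2.1])
        p = EpileptorParams(x0=x0, K=0.0, sigma=0.0, duration=400, seed=0, jitter=0.0)
        joint = simulate(Connectome(W), p)
        for i in range(3):
            solo = simulate(single_node_connectome(),
                            p.replace(x0=float(x0[i])))
            np.testing.assert_allclose(joint.states[:, :, i], solo.states[:, :, 0],
                                       atol=1e-12)

    def test_identical_nodes_stay_identical(self):
        p = EpileptorParams(x0=-1.6, K=0.0, sigma=0.0, duration=600, seed=0, jitter=0.0)
        tr = simulate(Connectome(np.zeros((2, 2))), p)
        np.testing.assert_array_equal(tr.states[:, :, 0], tr.states[:, :, 1])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        W = rng.random((4, 4)) * 0.3
        np.fill_diagonal(W, 0.0)
        x0 = np.array([-1.6, -2.1, -2.1, -1.9])
        p = EpileptorParams(x0=x0, sigma=0.0, duration=300, seed=0, jitter=0.0)
        tr = simulate(Connectome(W), p)
        perm = np.array([2, 0, 3, 1])
        p_perm = p.replace(x0=x0[perm])
        tr_perm = simulate(Connectome(W[np.ix_(perm, perm)]), p_perm)
        np.testing.assert_allclose(tr_perm.states, tr.states[:, :, perm], atol=1e-12)

    def test_seizure_occurrence_monotone_in_x0(self):
        C = single_node_connectome()
        seized = []
        for x0 in np.linspace(-2.2, -1.6, 7):
            tr = simulate(C, EpileptorParams(x0=float(x0), sigma=0.0,
                                             duration=2500, seed=0))
            seized.append(not np.isnan(detect_onsets(tr.z, tr.times)[0]))
        # no quiet value above a seizing value
        first_seizing = seized.index(True)
        assert all(seized[first_seizing:])
        assert not any(seized[:first_seizing])

    def test_blowup_raises_with_time(self):
        C = single_node_connectome()
        with pytest.raises(IntegrationError, match="model time"):
            simulate(C, EpileptorParams(x0=-1.6, sigma=0.0, duration=400, dt=6.0))

    def test_numpy_and_numba_paths_agree(self):
        numba = pytest.importorskip("numba")  # noqa: F841  (fallback-only envs)
        W = np.zeros((3, 3))
        W[1, 0] = 0.6
        p = EpileptorParams.for_network(3, [0], sigma=0.0025, duration=200, seed=9)
        a = simulate(Connectome(W), p, use_numba=True)
        b = simulate(Connectome(W), p, use_numba=False)
        np.testing.assert_allclose(a.states, b.states, atol=1e-10)

    def test_trajectory_invariants(self):
        C = single_node_connectome()
        tr = simulate(C, EpileptorParams(x0=-1.6, duration=200, seed=0))
        assert np.all(np.isfinite(tr.states))
        dts = np.diff(tr.times)
        np.testing.assert_allclose(dts, dts[0])
        df = tr.to_frame()
        assert set(df.columns) == {"time", "node", "x1", "y1", "z", "x2", "y2", "g", "lfp"}


class TestInterictalState:
    def test_is_equilibrium_of_the_quiet_node(self):
        p = EpileptorParams(x0=-2.1)
        st = interictal_state(p)
        d = network_rhs(st, p)
        # the fast subsystem and g are at rest; z moves on the slow scale only
        np.testing.assert_allclose(d[[0, 1, 5]], 0.0, atol=1e-9)
        assert abs(d[2]) < 1e-6

    def test_params_validation(self):
        with pytest.raises(ValueError):
            EpileptorParams(dt=0.0)
        with pytest.raises(ValueError):
            EpileptorParams(duration=10.0, warmup=15.0)
        with pytest.raises(ValueError):
            EpileptorParams(sigma=-1.0)
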