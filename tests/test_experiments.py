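"""Experiment orchestration: sweeps, thresholds, scans, FC."""

import numpy as np
import pandas as pd
import pytest

from epiprop.connectome import Connectome
from epiprop.epileptor import EpileptorParams, Trajectory, simulate
from epiprop.experiments import (
    ThresholdEstimate,
    estimate_weight_thresholds,
    evaluate_interventions,
    ez_sweep,
    fc_similarity,
    functional_connectivity,
    reduction_scan,
)
from epiprop.interventions import InterventionSpec


def small_net() -> Connectome:
    """A 4-node net: node 0 strongly drives node 1, node 3 has no output."""
    W = np.zeros((4, 4))
    W[1, 0] = 0.9
    W[2, 1] = 0.3
    W[0, 2] = 0.2
    C = Connectome(W)
    C.meta["id"] = "small4"
    return C


def fast_params(duration=1500.0) -> EpileptorParams:
    return EpileptorParams(duration=duration, sigma=0.0)


class TestEzSweep:
    def test_isolated_out_ez_is_localized(self):
        df = ez_sweep(small_net(), [3], params=fast_params())
        row = df.iloc[0]
        assert row["ez_max_out_weight"] == 0.0
        assert row["recruited_fraction"] == 0.0
        assert row["propagation_class"] == "localized"

    def test_sweep_is_deterministic(self):
        a = ez_sweep(small_net(), [0, 3], params=fast_params())
        b = ez_sweep(small_net(), [0, 3], params=fast_params())
        pd.testing.assert_frame_equal(a, b)

    def test_too_short_horizon_flags_row_and_continues(self):
        # 100 time units end before the EZ's first seizure: the detector
        # reports "EZ never seized" and the sweep flags the row
        df = ez_sweep(small_net(), [0, 3], params=fast_params(duration=100.0))
        assert df["failed"].all()
        assert (df["propagation_class"] == "failed").all()
        assert df["error"].str.contains("EZ never seized").all()

    def test_attaches_graph_measures(self):
        df = ez_sweep(small_net(), [0], params=fast_params())
        assert df.iloc[0]["ez_max_out_weight"] == 0.9
        assert 0 <= df.iloc[0]["ez_avg_shortest_path_norm"] <= 1.0


class TestThresholds:
    def test_interleaved_rows(self):
        sweep = pd.DataFrame(
            {
                "ez_max_out_weight": [0.10, 0.25, 0.30, 0.50],
                "propagation_class": ["localized", "widespread", "localized", "widespread"],
                "failed": [False] * 4,
            }
        )
        est = estimate_weight_thresholds(sweep)
        assert est == ThresholdEstimate(w_upper=0.30, w_lower=0.25,
                                        n_localized=2, n_widespread=2, n_partial=0)

    def test_perfectly_separated(self):
        sweep = pd.DataFrame(
            {
                "ez_max_out_weight": [0.1, 0.4],
                "propagation_class": ["localized", "widespread"],
                "failed": [False, False],
            }
        )
        est = estimate_weight_thresholds(sweep)
        assert est.w_upper == 0.1 and est.w_lower == 0.4

    def test_absent_regime_undefined(self):
        sweep = pd.DataFrame(
            {
                "ez_max_out_weight": [0.1, 0.2],
                "propagation_class": ["localized", "localized"],
                "failed": [False, False],
            }
        )
        est = estimate_weight_thresholds(sweep)
        assert est.w_lower is None and est.w_upper == 0.2

    def test_partial_rows_excluded_with_warning(self):
        sweep = pd.DataFrame(
            {
                "ez_max_out_weight": [0.1, 0.3, 0.5],
                "propagation_class": ["localized", "partial", "widespread"],
                "failed": [False] * 3,
            }
        )
        with pytest.warns(UserWarning, match="partial"):
            est = estimate_weight_thresholds(sweep)
        assert est.n_partial == 1


class TestEvaluateInterventions:
    def test_empty_specs_gives_baseline_only(self):
        df = evaluate_interventions(small_net(), 0, [], params=fast_params())
        assert list(df["intervention"]) == ["baseline"]
        base = ez_sweep(small_net(), [0], params=fast_params()).iloc[0]
        assert df.iloc[0]["recruited_fraction"] == base["recruited_fraction"]

    def test_removing_all_ez_output_localizes(self):
        C = small_net()
        spec = InterventionSpec(kind="remove_edges", edges=[(0, 1)])
        df = evaluate_interventions(C, 0, [spec], params=fast_params())
        assert df.iloc[1]["ez_max_out_weight"] == 0.0
        assert df.iloc[1]["propagation_class"] == "localized"


class TestReductionScan:
    def test_level_zero_matches_sweep_and_full_reduction_localizes(self):
        C = small_net()
        df, confining = reduction_scan(C, 0, [0.5, 1.0], params=fast_params())
        base = ez_sweep(C, [0], params=fast_params()).iloc[0]
        lvl0 = df[df["level"] == 0.0].iloc[0]
        assert lvl0["recruited_fraction"] == base["recruited_fraction"]
        assert lvl0["seed"] == base["seed"]
        full = df[df["level"] == 1.0].iloc[0]
        assert full["propagation_class"] == "localized"
        assert confining is not None


class TestFunctionalConnectivity:
    def _dummy_traj(self, lfp_signals: np.ndarray) -> Trajectory:
        n, s = lfp_signals.shape
        states = np.zeros((s, 6, n))
        states[:, 3, :] = lfp_signals.T  # x2 carries the signal, x1 stays 0
        params = EpileptorParams(duration=float(s), warmup=0.0)
        return Trajectory(times=np.arange(s, dtype=float) + 1.0,
                          states=states, params=params)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        fc = functional_connectivity(self._dummy_traj(rng.standard_normal((4, 500))))
        np.testing.assert_allclose(fc, fc.T)
        np.testing.assert_array_equal(np.diagonal(fc), 1.0)

    def test_identical_signals_fully_correlated(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(300)
        fc = functional_connectivity(self._dummy_traj(np.vstack([s, s])))
        assert fc[0, 1] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        fc = functional_connectivity(self._dummy_traj(rng.standard_normal((5, 10_000))))
        off = fc[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_constant_node_zeroed_with_warning(self):
        rng = np.random.default_rng(3)
        sig = rng.standard_normal((3, 400))
        sig[1] = 2.5
        with pytest.warns(UserWarning, match="constant"):
            fc = functional_connectivity(self._dummy_traj(sig))
        assert np.all(fc[1, [0, 2]] == 0.0)
        assert fc[1, 1] == 1.0

    def test_fc_similarity(self):
        rng = np.random.default_rng(4)
        A = rng.random((6, 6))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        assert fc_similarity(A, A) == pytest.approx(1.0)
        assert fc_similarity(A, -A) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            fc_similarity(A, np.zeros((3, 3)))

    def test_fc_of_simulated_run(self):
        W = np.zeros((2, 2))
        W[1, 0] = W[0, 1] = 0.4
        tr = simulate(Connectome(W), EpileptorParams(x0=-2.1, duration=400, seed=5))
        fc = functional_connectivity(tr)
        assert fc.shape == (2, 2)
        np.testing.assert_array_equal(np.diagonal(fc), 1.0)
        assert -1.0 <= fc[0, 1] <= 1.0
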