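import numpy as np
import pytest

import neurojet as nj
from neurojet.metrics import mean_sampling_period


class TestGenerateTrace:
    def test_deterministic_given_seed(self):
        cfg = nj.SyntheticTraceConfig(seed=17)
        a, b = nj.generate_trace(cfg), nj.generate_trace(cfg)
        np.testing.assert_array_equal(a.positions(), b.positions())
        assert [n.parent_id for n in a.nodes] == [n.parent_id for n in b.nodes]

    def test_zero_curvature_branches_are_straight(self):
        cfg = nj.SyntheticTraceConfig(
            n_branches=3, nodes_per_branch=(10, 15), curvature_scale=0.0,
            spatial_extent=5000.0, seed=3,
        )
        trace = nj.generate_trace(cfg)
        # every non-junction interior node continues straight (junction
        # nodes are bifurcations and carry no path angle)
        angles = nj.morphometry(trace).path_angles
        assert len(angles) > 20
        np.testing.assert_allclose(angles, 180.0, atol=1e-4)

    def test_requested_sampling_period_realized(self):
        periods = [
            mean_sampling_period(
                nj.generate_trace(nj.SyntheticTraceConfig(seed=s))
            )
            for s in range(20)
        ]
        assert abs(np.mean(periods) - 10.0) < 1.0  # within 10%

    def test_traces_are_valid_and_branchy(self):
        trace = nj.generate_trace(nj.SyntheticTraceConfig(seed=1))
        trace.validate()
        decomp = nj.decompose_branches(trace)
        assert len(decomp.branches) == 5


class TestSigmaSweep:
    def test_sigma_zero_errors_vanish(self):
        traces = [nj.generate_trace(nj.SyntheticTraceConfig(seed=s)) for s in (0, 1)]
        df = nj.run_sigma_sweep(traces, sigmas=(0.0,), seeds=(0,))
        assert (df["frechet_error"] <= 1e-9).all()
        # path angles form a continuous distribution, so their KS statistic
        # reflects real differences; quantities with point masses (e.g. the
        # 2-um segment lengths of an identity mapping) are rounding-brittle
        # under KS and are covered by the position check below instead
        assert df["ks_path_angle"].max() <= 0.02
        phi = nj.random_diffeomorphism(
            nj.diffeo_config_for([nj.center_trace(traces[0])], 0.0, 0)
        )
        gt = nj.map_trace(nj.center_trace(traces[0]), phi, "ground_truth")
        for method in ("order0", "order1"):
            mapped = nj.map_trace(nj.center_trace(traces[0]), phi, method)
            np.testing.assert_allclose(
                mapped.positions(), gt.positions(), atol=1e-6
            )

    def test_affine_transform_gives_zero_error_both_methods(self, random_affine):
        trace = nj.NeuronTrace(
            [
                nj.TraceNode(1, 1, [0, 0, 0], 1.0, -1),
                nj.TraceNode(2, 0, [9, 2, 1], 1.0, 1),
            ]
        )
        decomp, gt = nj.map_trace_branches(trace, random_affine, "ground_truth")
        for method in ("order0", "order1"):
            _, mapped = nj.map_trace_branches(trace, random_affine, method,
                                              decomposition=decomp)
            err = nj.discrete_frechet(mapped[0][0], gt[0][0])
            assert err <= 1e-9

    def test_records_reproducible_bit_identically(self):
        traces = [nj.generate_trace(nj.SyntheticTraceConfig(seed=4))]
        a = nj.run_sigma_sweep(traces, sigmas=(160.0,), seeds=(1,))
        b = nj.run_sigma_sweep(traces, sigmas=(160.0,), seeds=(1,))
        assert a.equals(b)

    def test_provenance_columns_present(self):
        traces = [nj.generate_trace(nj.SyntheticTraceConfig(seed=4))]
        df = nj.run_sigma_sweep(traces, sigmas=(80.0,), seeds=(2,))
        assert {"trace", "sigma", "diffeo_seed", "method", "frechet_error",
                "mean_sampling_period"} <= set(df.columns)
        assert set(df["method"]) == {"order0", "order1"}


class TestNodeRemoval:
    @pytest.fixture
    def straightish_trace(self):
        cfg = nj.SyntheticTraceConfig(
            n_branches=2, nodes_per_branch=(25, 30), curvature_scale=0.001,
            seed=8,
        )
        return nj.center_trace(nj.generate_trace(cfg))

    def test_identity_map_keeps_every_node_removable(self, straightish_trace):
        res = nj.run_node_removal_study(straightish_trace, nj.identity_map())
        assert res.n_candidates > 0
        assert res.fraction_order0 == 1.0
        assert res.fraction_order1 == 1.0

    def test_no_straight_nodes_flags_empty_result(self):
        # a zigzag with every path angle at 90 degrees
        pts = [[0, 0, 0], [5, 0, 0], [5, 5, 0], [10, 5, 0], [10, 10, 0]]
        nodes = [
            nj.TraceNode(i + 1, 0, p, 1.0, i if i > 0 else -1)
            for i, p in enumerate(pts)
        ]
        res = nj.run_node_removal_study(nj.NeuronTrace(nodes), nj.identity_map())
        assert res.empty
        assert res.fraction_order0 is None and res.fraction_order1 is None

    def test_first_order_wins_majority_of_seeds_at_large_sigma(
        self, straightish_trace
    ):
        """Under strong random deformations, first-order mapping keeps at
        least as many nodes sub-micron-removable as zeroth order, in the
        majority of deformation seeds."""
        wins = 0
        for seed in range(20):
            cfg = nj.diffeo_config_for([straightish_trace], 640.0, seed)
            phi = nj.random_diffeomorphism(cfg)
            res = nj.run_node_removal_study(straightish_trace, phi)
            assert not res.empty
            if res.fraction_order1 >= res.fraction_order0:
                wins += 1
        assert wins > 10
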