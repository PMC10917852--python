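import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import neurojet as nj
from neurojet.errors import BranchCorrespondenceError
from neurojet.metrics import discrete_frechet, ks_statistic


def frechet_by_coupling_enumeration(P, Q):
    """Independent oracle: explicit enumeration of all monotone couplings of
    the two point sequences (with exact pruning), no dynamic program."""
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    n, m = len(P), len(Q)
    d = np.linalg.norm(P[:, None, :] - Q[None, :, :], axis=2)
    best = [np.inf]

    def walk(i, j, cur):
        cur = max(cur, d[i, j])
        if cur >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cur
            return
        if i + 1 < n:
            walk(i + 1, j, cur)
        if j + 1 < m:
            walk(i, j + 1, cur)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cur)

    walk(0, 0, 0.0)
    return best[0]


class TestDiscreteFrechet:
    def test_equal_polylines_zero(self, rng):
        P = rng.normal(size=(9, 3))
        assert discrete_frechet(P, P.copy()) == 0.0

    def test_single_point_forces_max(self, rng):
        p = np.array([[1.0, 2.0, 3.0]])
        Q = rng.normal(size=(7, 3))
        expected = np.linalg.norm(Q - p[0], axis=1).max()
        assert discrete_frechet(p, Q) == pytest.approx(expected)
        assert discrete_frechet(Q, p) == pytest.approx(expected)

    def test_matches_enumeration_oracle_on_random_pairs(self, rng):
        for _ in range(300):
            n, m = rng.integers(1, 8, size=2)
            P = rng.uniform(-5, 5, size=(n, 3))
            Q = rng.uniform(-5, 5, size=(m, 3))
            assert discrete_frechet(P, Q) == pytest.approx(
                frechet_by_coupling_enumeration(P, Q), abs=1e-12
            )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.data())
    def test_symmetry_and_hausdorff_lower_bound(self, data):
        coords = st.floats(-100, 100, allow_nan=False)
        point = st.tuples(coords, coords, coords)
        P = np.asarray(data.draw(st.lists(point, min_size=1, max_size=7)))
        Q = np.asarray(data.draw(st.lists(point, min_size=1, max_size=7)))
        dpq = discrete_frechet(P, Q)
        assert dpq == pytest.approx(discrete_frechet(Q, P), abs=1e-12)
        d = np.linalg.norm(P[:, None, :] - Q[None, :, :], axis=2)
        hausdorff = max(d.min(axis=1).max(), d.min(axis=0).max())
        assert dpq >= hausdorff - 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            discrete_frechet(np.empty((0, 3)), np.zeros((1, 3)))


class TestTraceFrechet:
    def test_identical_traces_zero(self, y_trace):
        assert nj.trace_frechet(y_trace, y_trace) == 0.0

    def test_single_branch_perturbation(self, y_trace):
        nodes = [
            nj.TraceNode(n.id, n.structure_id, n.position.copy(), n.radius,
                         n.parent_id)
            for n in y_trace.nodes
        ]
        # small enough that the longest root-to-leaf path is unchanged
        nodes[3].position[1] += 1.0  # leaf2, on the short branch only
        perturbed = nj.NeuronTrace(nodes)
        da = nj.decompose_branches(y_trace)
        db = nj.decompose_branches(perturbed)
        expected = discrete_frechet(da.branches[1].knots, db.branches[1].knots)
        assert nj.trace_frechet(y_trace, perturbed) == pytest.approx(expected)
        assert expected == pytest.approx(1.0)

    def test_order0_vs_ground_truth_identity_map(self, y_trace):
        o0 = nj.map_trace(y_trace, nj.identity_map(), "order0")
        gt = nj.map_trace(y_trace, nj.identity_map(), "ground_truth")
        assert nj.trace_frechet(o0, gt) <= 1e-12

    def test_branch_count_mismatch_rejected(self, y_trace, straight_trace):
        with pytest.raises(BranchCorrespondenceError):
            nj.trace_frechet(y_trace, straight_trace)


class TestMorphometry:
    def test_straight_path_angle_180(self, straight_trace):
        m = nj.morphometry(straight_trace)
        np.testing.assert_allclose(m.path_angles, [180.0])

    def test_right_angle_path(self):
        nodes = [
            nj.TraceNode(1, 1, [0, 0, 0], 1.0, -1),
            nj.TraceNode(2, 3, [1, 0, 0], 1.0, 1),
            nj.TraceNode(3, 3, [1, 1, 0], 1.0, 2),
        ]
        m = nj.morphometry(nj.NeuronTrace(nodes))
        np.testing.assert_allclose(m.path_angles, [90.0])

    def test_branch_angle_at_bifurcation(self, y_trace):
        m = nj.morphometry(y_trace)
        np.testing.assert_allclose(m.branch_angles, [90.0])

    def test_semicircle_tortuosity_is_half_pi(self):
        theta = np.linspace(0, np.pi, 200)
        r = 40.0
        pts = np.stack([r * np.cos(theta), r * np.sin(theta),
                        np.zeros_like(theta)], axis=1)
        nodes = [
            nj.TraceNode(i + 1, 0, p, 1.0, i if i > 0 else -1)
            for i, p in enumerate(pts)
        ]
        m = nj.morphometry(nj.NeuronTrace(nodes))
        assert m.tortuosities[0] == pytest.approx(np.pi / 2, rel=1e-3)

    def test_segment_lengths(self, y_trace):
        m = nj.morphometry(y_trace)
        np.testing.assert_allclose(sorted(m.segment_lengths), [3, 5, 10])

    def test_rigid_motion_invariance(self, rng):
        trace = nj.generate_trace(nj.SyntheticTraceConfig(n_branches=4, seed=6))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = nj.map_trace(trace, nj.affine(q, rng.normal(size=3) * 100),
                             "order0")
        # rigid motions commute with resampling, so compare against the
        # identically resampled original
        base = nj.map_trace(trace, nj.identity_map(), "order0")
        ma, mb = nj.morphometry(base).as_dict(), nj.morphometry(moved).as_dict()
        for q_ in ma:
            np.testing.assert_allclose(ma[q_], mb[q_], atol=1e-9)


class TestKSStatistic:
    def test_identical_samples_zero(self, rng):
        a = rng.normal(size=40)
        assert ks_statistic(a, a.copy()) == 0.0

    def test_disjoint_supports_one(self):
        assert ks_statistic([1, 2, 3], [10, 11]) == 1.0

    def test_hand_value(self):
        assert ks_statistic([1, 2, 3], [1, 2, 4]) == pytest.approx(1 / 3)

    def test_matches_scipy_reference(self, rng):
        for _ in range(25):
            a = rng.normal(size=int(rng.integers(3, 60)))
            b = rng.normal(loc=0.3, size=int(rng.integers(3, 60)))
            ref = stats.ks_2samp(a, b, method="asymp").statistic
            assert ks_statistic(a, b) == pytest.approx(ref, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_statistic([], [1.0])
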