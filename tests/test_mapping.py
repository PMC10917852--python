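import numpy as np
import pytest

import neurojet as nj
from neurojet.mapping import (
    map_segment_ground_truth,
    map_segment_order0,
    map_segment_order1,
    sample_parameters,
    segment_sup_error,
)

X0 = np.zeros(3)
X1 = np.array([10.0, 0.0, 0.0])

# phi(x, y, z) = (x, y + x^2/100, z)
_PARABOLA_Q = np.zeros((3, 3, 3))
_PARABOLA_Q[1, 0, 0] = 2.0 / 100.0


@pytest.fixture
def parabola_map():
    return nj.quadratic_map(_PARABOLA_Q)


def test_sample_parameters_clamped_to_segment():
    np.testing.assert_allclose(sample_parameters(5.0), [0, 2, 4, 5])
    np.testing.assert_allclose(sample_parameters(4.0), [0, 2, 4])
    np.testing.assert_allclose(sample_parameters(1.2), [0, 1.2])
    s = sample_parameters(10.0000001)
    assert s[-1] == 10.0000001 and s[-2] == 8.0  # no degenerate final gap


def test_ground_truth_identity_samples_on_source_line():
    mc = map_segment_ground_truth(X0, np.array([5.0, 0, 0]), nj.identity_map())
    np.testing.assert_allclose(mc.params, [0, 2, 4, 5])
    np.testing.assert_allclose(mc.samples[:, 0], [0, 2, 4, 5])
    np.testing.assert_allclose(mc.samples[:, 1:], 0)


def test_ground_truth_affine_samples_collinear(random_affine):
    mc = map_segment_ground_truth(X0, X1, random_affine)
    y0, y1 = mc.samples[0], mc.samples[-1]
    for s, y in zip(mc.params, mc.samples):
        np.testing.assert_allclose(y, y0 + (s / 10.0) * (y1 - y0), atol=1e-9)


def test_ground_truth_quadratic_lies_on_parabola(parabola_map):
    mc = map_segment_ground_truth(X0, X1, parabola_map)
    np.testing.assert_allclose(mc.samples[:, 1], mc.samples[:, 0] ** 2 / 100,
                               atol=1e-12)


def test_order0_chord_gap_on_parabola_is_quarter(parabola_map):
    """Interior order-0 samples sit on the chord; the parabola-chord gap
    s(10 - s)/100 peaks at 0.25 for s = 5."""
    err = segment_sup_error(X0, X1, parabola_map, "order0", n_probe=401)
    assert err == pytest.approx(0.25, rel=1e-6)
    gt = map_segment_ground_truth(X0, X1, parabola_map)
    o0 = map_segment_order0(X0, X1, parabola_map)
    gaps = np.linalg.norm(gt.samples - o0.samples, axis=1)
    np.testing.assert_allclose(
        gaps, gt.params * (10 - gt.params) / 100, atol=1e-12
    )


def test_order1_beats_order0_on_parabola(parabola_map):
    e1 = segment_sup_error(X0, X1, parabola_map, "order1", n_probe=401)
    assert e1 < 0.25


@pytest.mark.parametrize("method", ["ground_truth", "order0", "order1"])
def test_affine_exactness_per_segment(method, random_affine):
    err = segment_sup_error(X0, X1, random_affine, method, n_probe=101)
    assert err <= 1e-9


@pytest.mark.parametrize("method", ["ground_truth", "order0", "order1"])
def test_identity_returns_source_samples(method):
    op = {
        "ground_truth": map_segment_ground_truth,
        "order0": map_segment_order0,
        "order1": map_segment_order1,
    }[method]
    mc = op(X0, X1, nj.identity_map())
    np.testing.assert_allclose(mc.samples[:, 0], mc.params, atol=1e-12)


def test_knot_exactness_all_methods(smooth_map):
    for op in (map_segment_ground_truth, map_segment_order0, map_segment_order1):
        mc = op(X0, X1, smooth_map)
        np.testing.assert_allclose(mc.samples[0], smooth_map(X0), atol=1e-9)
        np.testing.assert_allclose(mc.samples[-1], smooth_map(X1), atol=1e-9)


def test_order1_endpoint_tangents_match_jacobian(smooth_map):
    mc = map_segment_order1(X0, X1, smooth_map)
    u = (X1 - X0) / 10.0
    d = mc.spline.derivative()
    np.testing.assert_allclose(d(0.0), smooth_map.jacobian_at(X0) @ u, atol=1e-9)
    np.testing.assert_allclose(d(10.0), smooth_map.jacobian_at(X1) @ u, atol=1e-9)


def test_order1_uses_finite_differences_when_no_jacobian(smooth_map):
    bare = nj.Diffeomorphism(map=smooth_map.map, fd_step=1e-5)
    mc_fd = map_segment_order1(X0, X1, bare)
    mc = map_segment_order1(X0, X1, smooth_map)
    np.testing.assert_allclose(mc_fd.samples, mc.samples, atol=1e-3)


def test_degenerate_segment_rejected():
    from neurojet.errors import DegenerateSegmentError

    with pytest.raises(DegenerateSegmentError):
        map_segment_order0(X0, X0 + 1e-9, nj.identity_map())


class TestMapTrace:
    def test_identity_resamples_in_place(self, y_trace):
        out = nj.map_trace(y_trace, nj.identity_map(), "order0")
        # every output node lies on the original polyline structure
        decomp = nj.decompose_branches(y_trace)
        for node in out.nodes:
            dists = [
                np.abs(b.point_at(t) - node.position).max()
                for b in decomp.branches
                for t in np.linspace(0, b.arc_length, 200)
            ]
            assert min(dists) < 0.1

    def test_affine_all_orders_match_ground_truth(self, random_affine):
        trace = nj.generate_trace(nj.SyntheticTraceConfig(n_branches=3, seed=2))
        gt = nj.map_trace(trace, random_affine, "ground_truth")
        for method in ("order0", "order1"):
            mapped = nj.map_trace(trace, random_affine, method)
            np.testing.assert_allclose(
                mapped.positions(), gt.positions(), atol=1e-9
            )

    def test_mapping_commutes_with_decomposition(self, smooth_map):
        """Mapping the whole trace equals mapping each branch of the source
        decomposition, segment by segment."""
        trace = nj.generate_trace(nj.SyntheticTraceConfig(n_branches=4, seed=13))
        decomp, mapped = nj.map_trace_branches(trace, smooth_map, "order1")
        for branch, (points, knot_idx) in zip(decomp.branches, mapped):
            segs = [
                map_segment_order1(branch.knots[i], branch.knots[i + 1], smooth_map)
                for i in range(branch.n_knots - 1)
            ]
            manual = np.concatenate(
                [segs[0].samples] + [s.samples[1:] for s in segs[1:]]
            )
            np.testing.assert_array_equal(points, manual)
            np.testing.assert_allclose(
                points[knot_idx], smooth_map(branch.knots), atol=1e-9
            )
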