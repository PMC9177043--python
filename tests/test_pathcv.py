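"""Cyclic path construction, projection, reparameterization and adaptation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pathmetad.cvspace import DimensionalError, plane_space, rolling_space
from pathmetad.errors import ParameterError, StateError
from pathmetad.pathcv import (
    PathCurve,
    PathUpdateState,
    init_cyclic_path,
    project_point,
    project_points,
    projection_gradients,
    project_points_with_grad,
    read_path,
    reparameterize,
    smooth_path_cv,
    update_path,
    write_path,
)

WCF = np.array([np.cos(1.5), np.sin(1.5), -0.1])
HG = np.array([np.cos(-1.5), np.sin(-1.5), -0.1])


def dense_projection_oracle(p, path, n_dense=100_000):
    """Brute force: resample the polyline densely, take the nearest sample,
    then refine exactly on the one or two segments adjacent to it (the dense
    pitch alone limits accuracy to first order for corner-wedge points)."""
    nodes = path.nodes
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    arc = np.linspace(0.0, total, n_dense)
    idx = np.clip(np.searchsorted(cum, arc, side="right") - 1, 0, len(seg) - 1)
    t = (arc - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    pts = nodes[idx] + t[:, None] * (nodes[idx + 1] - nodes[idx])
    d = np.linalg.norm(pts - p, axis=1)
    k = int(np.argmin(d))
    best = (np.inf, 0.0)
    for j in range(max(0, idx[k] - 1), min(len(seg), idx[k] + 2)):
        a, b = nodes[j], nodes[j + 1]
        tau = np.clip((p - a) @ (b - a) / (seg[j] ** 2), 0.0, 1.0)
        q = a + tau * (b - a)
        dist = float(np.linalg.norm(p - q))
        if dist < best[0]:
            best = (dist, cum[j] + tau * seg[j])
    return -1.0 + 2.0 * best[1] / total, best[0]


class TestInitCyclicPath:
    @pytest.mark.parametrize("n_nodes", [11, 39])
    def test_closed_equidistant_on_unit_circle(self, n_nodes):
        path = init_cyclic_path(WCF, HG, n_nodes)
        assert path.n_nodes == n_nodes
        assert np.array_equal(path.nodes[0], WCF)
        assert np.array_equal(path.nodes[-1], WCF)
        # initial guess lies on the unit chi' circle at the WCF theta
        radius = path.nodes[:, 0] ** 2 + path.nodes[:, 1] ** 2
        assert np.max(np.abs(radius - 1.0)) < 1e-12
        assert np.allclose(path.nodes[:, 2], -0.1)
        seg = path.segment_lengths()
        assert np.max(np.abs(seg - seg.mean())) < 1e-6 * seg.mean()

    def test_direction_convention(self):
        # the 5' intermediate (chi' near pi) sits in the first half (s < 0)
        path = init_cyclic_path(WCF, HG, 39)
        chi = np.arctan2(path.nodes[:, 1], path.nodes[:, 0])
        k5 = np.argmin(np.abs(np.abs(chi) - np.pi))
        s5, _ = project_point(path.nodes[k5], path).s, None
        assert -1.0 < s5 < 0.0
        k3 = np.argmin(np.abs(chi))
        assert 0.0 < project_point(path.nodes[k3], path).s < 1.0

    def test_errors(self):
        with pytest.raises(DimensionalError):
            init_cyclic_path(WCF, HG[:2], 11)
        with pytest.raises(ParameterError):
            init_cyclic_path(WCF, HG, 2)


class TestProjection:
    def test_nodes_project_onto_themselves(self):
        path = init_cyclic_path(WCF, HG, 21)
        s, z = project_points(path.nodes, path)
        assert np.max(z) < 1e-9
        expected = -1.0 + 2.0 * np.arange(21) / 20
        # the duplicate anchor node ties to the first segment (lower index)
        assert np.allclose(s[:-1], expected[:-1], atol=1e-9)
        assert abs(abs(s[-1]) - 1.0) < 1e-9

    def test_anchor_maps_to_plus_minus_one(self):
        path = init_cyclic_path(WCF, HG, 11)
        assert abs(abs(project_point(WCF, path).s) - 1.0) < 1e-12

    def test_perpendicular_offset(self):
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        path = PathCurve(nodes, plane_space(), cyclic=False)
        pr = project_point([0.5, 0.3], path)
        assert pr.z == pytest.approx(0.3, abs=1e-12)

    def test_matches_dense_oracle(self, rng):
        path = init_cyclic_path(WCF, HG, 25)
        half_spacing = 1.0 / (path.n_nodes - 1)  # in s units
        pts = np.column_stack([
            rng.uniform(-1.3, 1.3, 200),
            rng.uniform(-1.3, 1.3, 200),
            rng.uniform(-1.5, 1.5, 200),
        ])
        s, z = project_points(pts, path)
        for k in range(200):
            s_ref, z_ref = dense_projection_oracle(pts[k], path)
            ds = abs((s[k] - s_ref + 1.0) % 2.0 - 1.0)
            assert ds <= half_spacing
            assert abs(z[k] - z_ref) < 1e-6

    def test_wrap_continuity_at_anchor(self):
        path = init_cyclic_path(WCF, HG, 39)
        eps = 1e-4
        chi0 = 1.5
        p_lo = np.array([np.cos(chi0 - eps), np.sin(chi0 - eps), -0.1])
        p_hi = np.array([np.cos(chi0 + eps), np.sin(chi0 + eps), -0.1])
        s_lo = project_point(p_lo, path).s
        s_hi = project_point(p_hi, path).s
        wrapped = abs((s_lo - s_hi + 1.0) % 2.0 - 1.0)
        assert wrapped < 2.0 / (path.n_nodes - 1)

    def test_empty_path_rejected(self):
        path = init_cyclic_path(WCF, HG, 11)
        bad = path.copy()
        with pytest.raises(StateError):
            bad.nodes = np.zeros((3, 3))  # degenerate: zero length
            project_points(np.array([[0.0, 0.0, 0.0]]), bad)


class TestGradients:
    def test_fd_matches_analytic_in_smooth_regions(self, rng):
        path = init_cyclic_path(WCF, HG, 15)
        pts = np.column_stack([
            rng.uniform(-1.0, 1.0, 50),
            rng.uniform(-1.0, 1.0, 50),
            rng.uniform(-1.0, 1.0, 50),
        ])
        s, z, gs, gz = project_points_with_grad(pts, path)
        for k in range(50):
            if z[k] < 1e-3:
                continue
            gs_fd, gz_fd = projection_gradients(pts[k], path)
            # skip points where the FD stencil straddles a non-smooth locus
            if np.max(np.abs(gs_fd)) > 10 or np.max(np.abs(gz_fd)) > 10:
                continue
            if np.allclose(gs[k], 0.0):  # wedge region: s locally constant
                continue
            assert np.allclose(gs_fd, gs[k], rtol=1e-3, atol=1e-4)
            assert np.allclose(gz_fd, gz[k], rtol=1e-3, atol=1e-4)

    def test_smooth_cv_gradients_match_finite_differences(self, rng):
        path = init_cyclic_path(WCF, HG, 15)
        pts = np.column_stack([
            rng.uniform(-1.0, 1.0, 30),
            rng.uniform(-1.0, 1.0, 30),
            rng.uniform(-1.0, 1.0, 30),
        ])
        s, z2, gs, gz2 = smooth_path_cv(pts, path)
        h = 1e-6
        for j in range(3):
            plus, minus = pts.copy(), pts.copy()
            plus[:, j] += h
            minus[:, j] -= h
            sp, z2p, _, _ = smooth_path_cv(plus, path)
            sm, z2m, _, _ = smooth_path_cv(minus, path)
            ds = ((sp - sm + 1.0) % 2.0 - 1.0) / (2 * h)
            dz2 = (z2p - z2m) / (2 * h)
            assert np.allclose(ds, gs[:, j], rtol=1e-4, atol=1e-5)
            assert np.allclose(dz2, gz2[:, j], rtol=1e-4, atol=1e-5)

    def test_smooth_cv_anchor_and_on_path(self):
        path = init_cyclic_path(WCF, HG, 39)
        s, z2, _, _ = smooth_path_cv(path.nodes[[0]], path)
        assert abs(abs(s[0]) - 1.0) < 1e-9
        s_n, z2_n, _, _ = smooth_path_cv(path.nodes, path)
        assert np.max(z2_n) < 5e-3  # soft-min distance stays near zero on-path


class TestReparameterize:
    def test_fixed_point(self):
        path = init_cyclic_path(WCF, HG, 21)
        out = reparameterize(path)
        assert np.allclose(out.nodes, path.nodes, atol=1e-12)

    def test_clustered_circle_nodes_redistributed(self):
        ang = np.concatenate([np.linspace(0, np.pi, 17), np.linspace(np.pi, 2 * np.pi, 4)[1:]])
        nodes = np.column_stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)])
        nodes[-1] = nodes[0]
        path = PathCurve(nodes, rolling_space(), cyclic=True)
        out = reparameterize(path)
        seg = out.segment_lengths()
        assert np.max(np.abs(seg - seg.mean())) < 1e-6 * seg.mean()
        # nodes stay near the circle (bounded by the sagitta of the coarsest
        # input chord, which spans 60 degrees on the sparse half)
        r = np.sqrt(out.nodes[:, 0] ** 2 + out.nodes[:, 1] ** 2)
        assert np.all(r > 1.0 - (1.0 - np.cos(np.pi / 6)) - 1e-9)

    def test_length_preserved_on_random_path(self, rng):
        # a smooth helix with small random perturbations
        u = np.linspace(0, 2 * np.pi, 20)
        nodes = np.column_stack([np.cos(u), np.sin(u), 0.3 * u])
        nodes += rng.normal(0, 0.02, nodes.shape)
        path = PathCurve(nodes, rolling_space(), cyclic=False)
        out = reparameterize(path)
        assert out.total_length() == pytest.approx(path.total_length(), rel=0.01)

    def test_degenerate_path_rejected(self):
        nodes = np.tile([0.3, 0.4, 0.0], (5, 1))
        path = PathCurve(nodes, rolling_space())
        with pytest.raises(StateError):
            reparameterize(path)


class TestUpdatePath:
    def test_no_samples_returns_path(self):
        path = init_cyclic_path(WCF, HG, 11)
        state = PathUpdateState(11, 3)
        out = update_path(path, [], state)
        assert out is path

    def test_on_node_samples_leave_path_unchanged(self):
        path = init_cyclic_path(WCF, HG, 11)
        state = PathUpdateState(11, 3)
        samples = (path.nodes.copy(), np.zeros(11))
        out = update_path(path, samples, state)
        assert np.allclose(out.nodes, path.nodes, atol=1e-12)

    def test_monotone_pull_toward_constant_offset(self):
        nodes = np.column_stack([np.linspace(0, 4, 9), np.zeros(9)])
        path = PathCurve(nodes, plane_space(), cyclic=False)
        state = PathUpdateState(9, 2)
        v = np.array([0.0, 0.4])
        samples = nodes + v
        out1 = update_path(path, (samples, np.zeros(9)), state)
        d1 = out1.nodes[1:-1, 1]
        assert np.all(d1 > 0)
        out2 = update_path(out1, (samples, np.ones(9)), state)
        d2 = out2.nodes[1:-1, 1]
        assert np.all(d2 >= d1 - 1e-12)

    def test_endpoint_pinning_bit_exact(self):
        path = init_cyclic_path(WCF, HG, 11)
        state = PathUpdateState(11, 3)
        rng = np.random.default_rng(1)
        for k in range(5):
            pts = path.nodes + rng.normal(0, 0.05, path.nodes.shape)
            path = update_path(path, (pts, np.full(len(pts), float(k))), state)
        assert np.array_equal(path.nodes[0], WCF)
        assert np.array_equal(path.nodes[-1], WCF)

    def test_fading_memory_weight_halves_per_half_life(self):
        state = PathUpdateState(5, 2, half_life=20.0)
        assert state.sample_weight(20.0) == pytest.approx(0.5)
        assert state.sample_weight(40.0) == pytest.approx(0.25)
        # two-sample configuration: doubling a sample's age halves its
        # accumulated weight relative to a fresh sample
        nodes = np.column_stack([np.linspace(0, 4, 5), np.zeros(5)])
        for age, expected in ((20.0, 0.5), (40.0, 0.25)):
            path = PathCurve(nodes.copy(), plane_space(), cyclic=False)
            st_ = PathUpdateState(5, 2, half_life=20.0)
            pts = np.array([[2.0, 0.3], [2.0, 0.3]])
            update_path(path, (pts, np.array([0.0, age])), st_)
            w = st_.weight_sum[st_.weight_sum > 0]
            assert w[0] == pytest.approx(1.0 + 2.0 ** (-age / 20.0))

    def test_infinite_half_life_never_decays(self):
        state = PathUpdateState(5, 2, half_life=np.inf)
        assert state.sample_weight(1e9) == 1.0
        assert state.decay_factor(1e9) == 1.0


class TestPathFiles:
    def test_round_trip_bit_exact(self, tmp_path):
        path = init_cyclic_path(WCF, HG, 11, mechanism="inside")
        f1 = tmp_path / "PATH.1"
        f2 = tmp_path / "PATH.2"
        write_path(path, f1)
        back = read_path(f1)
        assert back.cyclic == path.cyclic
        assert back.mechanism == path.mechanism
        assert back.space.names == path.space.names
        write_path(back, f2)
        assert f1.read_bytes() == f2.read_bytes()
        assert np.array_equal(back.nodes, path.nodes)


@given(st.floats(-1.0, 1.0), st.floats(-1.0, 1.0), st.floats(-1.0, 1.0))
def test_projection_s_in_range_z_nonnegative(x, y, t):
    path = init_cyclic_path(WCF, HG, 11)
    pr = project_point(np.array([x, y, t]), path)
    assert -1.0 <= pr.s <= 1.0
    assert pr.z >= 0.0
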