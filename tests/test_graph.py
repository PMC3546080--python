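import numpy as np
import pytest

from sbpquant import (
    Calibration,
    build_graph,
    classify_pixels,
    count_nodes,
    edge_length,
    export_edge_list,
    prune_spurs,
    skeletonize,
)
from sbpquant.skeleton import SkeletonImage

from .conftest import make_image


def as_skel(mask, pitch=1.0):
    return SkeletonImage(skeleton=np.asarray(mask, bool), pixel_pitch_um=pitch)


def t_shape(size=25):
    """Three 10-px arms meeting at an interior point, clear of the border."""
    m = np.zeros((size, size), bool)
    c = size // 2
    m[c, c - 10 : c + 11] = True  # horizontal bar
    m[c : c + 11, c] = True  # downward arm
    return m


def y_shape(size=25):
    """One straight arm up, two diagonal arms down: the only pixel
    with three 8-neighbours is the fork itself."""
    m = np.zeros((size, size), bool)
    c = size // 2
    m[c - 10 : c + 1, c] = True
    for k in range(1, 10):
        m[c + k, c - k] = True
        m[c + k, c + k] = True
    return m


def x_shape(size=25):
    m = np.zeros((size, size), bool)
    c = size // 2
    for k in range(-9, 10):
        m[c + k, c + k] = True
        m[c + k, c - k] = True
    return m


def plus_shape(size=25):
    m = np.zeros((size, size), bool)
    c = size // 2
    m[c, c - 9 : c + 10] = True
    m[c - 9 : c + 10, c] = True
    return m


def closed_ring(size=25):
    """Thin closed loop: the skeleton of a circular annulus."""
    from sbpquant.skeleton import thin_mask

    rr, cc = np.indices((size, size))
    c = size // 2
    d2 = (rr - c) ** 2 + (cc - c) ** 2
    return thin_mask((d2 >= 36) & (d2 <= 81))


class TestClassifyPixels:
    def test_interior_line(self):
        m = np.zeros((9, 20), bool)
        m[4, 3:15] = True
        kinds = classify_pixels(as_skel(m))
        ends = [p for p, (k, _) in kinds.items() if k == "end"]
        assert sorted(ends) == [(4, 3), (4, 14)]
        assert all(k == "path" for p, (k, _) in kinds.items() if p not in ends)
        assert not any(border for _, border in kinds.values())

    def test_y_fork_has_single_junction_pixel(self):
        kinds = classify_pixels(as_skel(y_shape()))
        junctions = [p for p, (k, _) in kinds.items() if k == "junction"]
        ends = [p for p, (k, _) in kinds.items() if k == "end"]
        assert junctions == [(12, 12)] and len(ends) == 3

    def test_t_bar_junction_cluster(self):
        # an orthogonal T thickens the fork to a small 8-connected
        # cluster of >=3-neighbour pixels; all of them are junctions
        kinds = classify_pixels(as_skel(t_shape()))
        junctions = [p for p, (k, _) in kinds.items() if k == "junction"]
        ends = [p for p, (k, _) in kinds.items() if k == "end"]
        assert 1 <= len(junctions) <= 4 and len(ends) == 3

    def test_full_width_line_border_tagged(self):
        m = np.zeros((9, 12), bool)
        m[4, :] = True
        kinds = classify_pixels(as_skel(m))
        assert kinds[(4, 0)] == ("end", True)
        assert kinds[(4, 11)] == ("end", True)
        interior_ends = [p for p, (k, b) in kinds.items() if k == "end" and not b]
        assert interior_ends == []

    def test_isolated_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert classify_pixels(as_skel(m))[(2, 2)] == ("isolated", False)


class TestBuildGraph:
    def test_t_shape_topology(self):
        g = build_graph(as_skel(t_shape()))
        assert count_nodes(g, "branch") == 1
        assert count_nodes(g, "endpoint") == 3
        assert count_nodes(g, "connectivity") == 0
        assert len(g.edges) == 3

    @pytest.mark.parametrize("shape", [x_shape, plus_shape])
    def test_cross_shapes_cluster_to_one_branch(self, shape):
        g = build_graph(as_skel(shape()))
        assert count_nodes(g, "branch") == 1
        assert count_nodes(g, "endpoint") == 4
        assert len(g.edges) == 4

    def test_two_disjoint_lines(self):
        m = np.zeros((11, 30), bool)
        m[3, 5:25] = True
        m[8, 5:25] = True
        g = build_graph(as_skel(m))
        assert g.n_components == 2
        assert count_nodes(g, "endpoint") == 4
        assert count_nodes(g, "branch") == 0
        assert len(g.edges) == 2

    def test_closed_loop_is_single_cycle_edge(self):
        g = build_graph(as_skel(closed_ring()))
        assert count_nodes(g, "endpoint") == 0
        assert count_nodes(g, "branch") == 0
        assert count_nodes(g, "connectivity") == 0
        assert len(g.edges) == 1
        e = g.edges[0]
        assert e.u == e.v  # self-loop anchored on the loop node

    def test_full_width_line_connectivity_points(self):
        m = np.zeros((9, 20), bool)
        m[4, :] = True
        g = build_graph(as_skel(m))
        assert count_nodes(g, "connectivity") == 2
        assert count_nodes(g, "endpoint") == 0
        assert len(g.edges) == 1

    def test_unknown_kind_rejected(self):
        g = build_graph(as_skel(t_shape()))
        with pytest.raises(ValueError, match="unknown node kind"):
            count_nodes(g, "nonsense")

    def test_handshake_identity_on_phantoms(self, small_phantoms):
        for img, _ in small_phantoms:
            g = build_graph(prune_spurs(skeletonize(img)))
            degrees = sum(g.degree(n.id) for n in g.nodes)
            assert degrees == 2 * len(g.edges)

    def test_pixel_conservation(self, small_phantoms):
        for img, _ in small_phantoms:
            skel = prune_spurs(skeletonize(img))
            g = build_graph(skel)
            covered = set()
            for n in g.nodes:
                covered |= set(n.pixels)
            for e in g.edges:
                covered |= set(e.pixel_path)
            assert covered == {tuple(p) for p in np.argwhere(skel.skeleton)}

    def test_graph_components_match_skeleton_components(self, small_phantoms):
        for img, _ in small_phantoms:
            skel = skeletonize(img)
            g = build_graph(skel)
            import scipy.ndimage as ndi

            assert g.n_components == ndi.label(skel.skeleton, np.ones((3, 3), bool))[1]

    def test_rotation_preserves_counts_and_length(self, small_phantoms):
        for img, _ in small_phantoms:
            skel = prune_spurs(skeletonize(img))
            g0 = build_graph(skel)
            rot = SkeletonImage(
                skeleton=np.ascontiguousarray(np.rot90(skel.skeleton)),
                pixel_pitch_um=skel.pixel_pitch_um,
            )
            g1 = build_graph(rot)
            for kind in ("branch", "endpoint", "connectivity"):
                assert count_nodes(g0, kind) == count_nodes(g1, kind)
            assert len(g0.edges) == len(g1.edges)
            assert g0.total_length_um == pytest.approx(g1.total_length_um, abs=1e-9)


class TestEdgeLength:
    PITCH = 400.0 / 384.0

    def test_horizontal_chain(self):
        m = np.zeros((5, 60), bool)
        m[2, 5:55] = True  # 50 px, 49 steps
        g = build_graph(as_skel(m, pitch=self.PITCH))
        assert edge_length(g.edges[0], self.PITCH) == pytest.approx(49 * self.PITCH)
        assert edge_length(g.edges[0], self.PITCH) == pytest.approx(51.04, abs=0.01)

    def test_diagonal_chain(self):
        m = np.zeros((60, 60), bool)
        for k in range(50):
            m[k + 2, k + 2] = True
        g = build_graph(as_skel(m, pitch=self.PITCH))
        assert edge_length(g.edges[0], self.PITCH) == pytest.approx(49 * np.sqrt(2) * self.PITCH)
        assert edge_length(g.edges[0], self.PITCH) == pytest.approx(72.19, abs=0.01)

    def test_mixed_path_matches_step_sum_oracle(self):
        m = np.zeros((30, 30), bool)
        path = [(5, 5)]
        for dr, dc in [(0, 1)] * 6 + [(1, 1)] * 5 + [(1, 0)] * 4 + [(1, -1)] * 3:
            r, c = path[-1]
            path.append((r + dr, c + dc))
        for r, c in path:
            m[r, c] = True
        g = build_graph(as_skel(m))
        expected = sum(
            np.hypot(r1 - r0, c1 - c0) for (r0, c0), (r1, c1) in zip(path, path[1:])
        )
        assert edge_length(g.edges[0], 1.0) == pytest.approx(expected)

    def test_calibration_object_accepted(self):
        m = np.zeros((5, 12), bool)
        m[2, 3:9] = True
        g = build_graph(as_skel(m, pitch=2.0))
        cal = Calibration.from_pitch(2.0, 12, 5)
        assert edge_length(g.edges[0], cal) == pytest.approx(5 * 2.0)


class TestPruning:
    def test_short_spur_removed(self):
        m = t_shape()
        # 2-px whisker rising off the horizontal bar
        m[11, 5] = m[10, 5] = True
        skel = prune_spurs(as_skel(m), min_segment_um=3.0)
        g = build_graph(skel)
        # whisker gone: back to the plain T topology
        assert count_nodes(g, "branch") == 1
        assert count_nodes(g, "endpoint") == 3
        assert len(g.edges) == 3

    def test_long_segments_survive(self):
        skel = prune_spurs(as_skel(t_shape()), min_segment_um=3.0)
        g = build_graph(skel)
        assert len(g.edges) == 3

    def test_isolated_pixels_dropped(self):
        m = np.zeros((11, 11), bool)
        m[5, 2:9] = True
        m[1, 1] = True
        skel = prune_spurs(as_skel(m))
        assert not skel.skeleton[1, 1]
        assert skel.skeleton[5, 2:9].all()

    def test_border_stubs_not_pruned(self):
        m = np.zeros((9, 20), bool)
        m[4, :] = True
        skel = prune_spurs(as_skel(m), min_segment_um=5.0)
        g = build_graph(skel)
        assert count_nodes(g, "connectivity") == 2


def test_export_edge_list_format(tmp_path):
    g = build_graph(as_skel(t_shape()))
    out = tmp_path / "graph.txt"
    export_edge_list(g, out)
    lines = out.read_text().strip().splitlines()
    node_lines = [l for l in lines if l.startswith("node ")]
    edge_lines = [l for l in lines if l.startswith("edge ")]
    assert len(node_lines) == len(g.nodes) and len(edge_lines) == 3
    assert node_lines[0].split()[2] in ("branch", "endpoint", "connectivity")
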