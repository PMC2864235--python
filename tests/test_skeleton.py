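"""Medial-axis skeletons, branch graphs and the two pruning criteria."""

import networkx as nx
import numpy as np
import pytest
from skimage.draw import disk as sk_disk

from skelopod.boundary import curve_from_polygon, extract_boundary
from skelopod.errors import DegenerateShape
from skelopod.skeleton import (PruningConfig, Skeleton, build_graph, prune,
                               prune_far_branches, prune_short_branches,
                               skeletonize)


def rect_medial_axis_distance(ys, xs):
    """Distance of points to the analytic medial axis of the 41x11 rect
    occupying rows 10..20, cols 10..50 (midline plus 45-degree corner
    segments)."""
    ys, xs = np.asarray(ys, float), np.asarray(xs, float)
    d_mid = np.hypot(np.maximum(0, np.abs(xs - 30) - 15), ys - 15)
    dists = [d_mid]
    for cy, cx, my, mx in [(10, 10, 15, 15), (20, 10, 15, 15),
                           (10, 50, 15, 45), (20, 50, 15, 45)]:
        t = np.clip(((ys - my) * (cy - my) + (xs - mx) * (cx - mx))
                    / ((cy - my) ** 2 + (cx - mx) ** 2), 0, 1)
        dists.append(np.hypot(ys - (my + t * (cy - my)),
                              xs - (mx + t * (cx - mx))))
    return np.min(dists, axis=0)


class TestSkeletonize:
    def test_rectangle_matches_analytic_medial_axis(self):
        m = np.zeros((31, 61), bool)
        m[10:21, 10:51] = True
        skel = skeletonize(m)
        pix = skel.pixels
        assert len(pix) > 0
        assert rect_medial_axis_distance(pix[:, 0], pix[:, 1]).max() <= 1.0
        # the horizontal midline segment is present
        mid = pix[pix[:, 0] == 15]
        assert mid[:, 1].min() <= 16 and mid[:, 1].max() >= 44

    def test_disk_collapses_to_center(self):
        m = np.zeros((51, 51), bool)
        rr, cc = sk_disk((25, 25), 20.5)
        m[rr, cc] = True
        pix = skeletonize(m).pixels
        assert np.hypot(pix[:, 0] - 25, pix[:, 1] - 25).max() <= 2.0

    def test_t_shape_graph_after_spur_removal(self):
        m = np.zeros((40, 40), bool)
        m[10:15, 5:36] = True
        m[10:31, 18:23] = True
        skel = prune_short_branches(skeletonize(m),
                                    PruningConfig(p_threshold=6,
                                                  prdist_threshold=100))
        kinds = sorted(d["kind"] for _, d in skel.graph.nodes(data=True))
        assert kinds == ["junction", "terminal", "terminal", "terminal"]
        assert len(skel.outer_branches()) == 3

    def test_tiny_mask_degenerate(self):
        m = np.zeros((10, 10), bool)
        m[4, 4:6] = True
        with pytest.raises(DegenerateShape):
            skeletonize(m)


class TestBuildGraph:
    def test_straight_line(self):
        m = np.zeros((10, 30), bool)
        m[5, 5:25] = True
        g = build_graph(m)
        assert g.number_of_nodes() == 2
        assert g.number_of_edges() == 1
        (_, _, d), = g.edges(data=True)
        assert d["length"] == pytest.approx(19.0)

    def test_diagonal_metric(self):
        m = np.zeros((20, 20), bool)
        for i in range(10):
            m[5 + i, 5 + i] = True
        (_, _, d), = build_graph(m).edges(data=True)
        assert d["length"] == pytest.approx(9 * np.sqrt(2))

    def test_y_three_outer_branches_one_root(self):
        m = np.zeros((40, 40), bool)
        m[20, 5:21] = True       # west arm
        m[20, 20:36] = True      # east arm
        m[5:21, 20] = True       # north arm
        g = build_graph(m)
        skel = Skeleton(g, m.shape)
        branches = skel.outer_branches()
        assert len(branches) == 3
        assert len({b.root for b in branches}) == 1


def _root_with_arms(armspecs, inner=20):
    """Graph with a junction at (50,50), an inner edge, and given arms.

    armspecs: list of (length, direction) with direction in {N,S,E,W}.
    """
    g = nx.MultiGraph()
    g.add_node(0, pos=(50, 50), kind="junction")
    path = np.stack([np.full(inner + 1, 50), np.arange(50, 50 - inner - 1, -1)],
                    axis=1)
    g.add_node(1, pos=(50, 50 - inner), kind="terminal")
    g.add_edge(0, 1, path=path, endpoints=(0, 1), length=float(inner))
    vecs = {"N": (-1, 0), "S": (1, 0), "E": (0, 1), "NE": (-1, 1)}
    for i, (length, dirn) in enumerate(armspecs, start=2):
        dr, dc = vecs[dirn]
        n = int(length)
        pts = np.array([(50 + dr * k, 50 + dc * k) for k in range(n + 1)])
        g.add_node(i, pos=tuple(pts[-1]), kind="terminal")
        g.add_edge(0, i, path=pts, endpoints=(0, i), length=float(length))
    return Skeleton(g, (100, 100))


class TestPruneShort:
    CFG = PruningConfig(p_threshold=10, prdist_threshold=100, r=1.5)

    def test_independent_short_branch_removed(self):
        # ring of two inner edges plus one short arm: the arm shares its
        # root with no other outer branch, so it is simply removed
        g = nx.MultiGraph()
        g.add_node(0, pos=(50, 50), kind="junction")
        g.add_node(1, pos=(50, 30), kind="junction")
        up = np.array([(48 - abs(k - 10) // 2, 50 - k) for k in range(21)])
        dn = np.array([(52 + abs(k - 10) // 2, 50 - k) for k in range(21)])
        up[0] = up[-1] = dn[0] = dn[-1] = (50, 50)
        up[-1] = dn[-1] = (50, 30)
        g.add_edge(0, 1, path=up, endpoints=(0, 1), length=22.0)
        g.add_edge(0, 1, path=dn, endpoints=(0, 1), length=22.0)
        arm = np.array([(50 - k, 50) for k in range(6)])
        g.add_node(2, pos=(45, 50), kind="terminal")
        g.add_edge(0, 2, path=arm, endpoints=(0, 2), length=5.0)
        skel = Skeleton(g, (100, 100))
        assert len(skel.outer_branches()) == 1
        out = prune_short_branches(skel, self.CFG)
        assert len(out.outer_branches()) == 0

    def test_siblings_combined_with_averaged_terminal(self):
        skel = _root_with_arms([(5, "N"), (6, "E")])
        out = prune_short_branches(skel, self.CFG)
        terminals = {tuple(out.graph.nodes[b.terminal]["pos"])
                     for b in out.outer_branches()}
        # midpoint of (45,50) and (50,56) -> (47.5,53) -> rounded (48,53)
        assert (48, 53) in terminals
        assert (45, 50) not in terminals and (50, 56) not in terminals

    def test_dominant_sibling_kept_shorter_removed(self):
        skel = _root_with_arms([(4, "N"), (15, "E")])
        out = prune_short_branches(skel, self.CFG)
        terminals = {tuple(out.graph.nodes[b.terminal]["pos"])
                     for b in out.outer_branches()}
        assert (50, 65) in terminals
        assert (46, 50) not in terminals

    def test_combined_branch_geometry_near_parallel_arms(self):
        # nearly parallel sibling arms: combined branch starts at the
        # root and is no shorter than the shorter arm
        skel = _root_with_arms([(6, "N"), (8, "NE")])
        out = prune_short_branches(skel, self.CFG)
        branches = out.outer_branches()
        lengths = sorted(b.length for b in branches)
        combined = [b for b in branches
                    if tuple(out.graph.nodes[b.root]["pos"]) == (50, 50)
                    or b.isolated]
        assert combined
        assert max(lengths) >= 6

    def test_idempotent_and_monotone(self):
        skel = _root_with_arms([(5, "N"), (6, "E"), (4, "S")])
        once = prune_short_branches(skel, self.CFG)
        twice = prune_short_branches(once, self.CFG)
        assert len(twice.outer_branches()) == len(once.outer_branches())
        assert (len(once.outer_branches())
                <= len(skel.outer_branches()))


class TestPruneFar:
    def test_near_terminal_kept_far_removed(self):
        # square cell boundary; two branches from a central root, one
        # ending 3 px from the membrane (kept) and one 12 px (removed)
        m = np.zeros((60, 60), bool)
        m[10:51, 10:51] = True
        curve = curve_from_polygon(extract_boundary(m))
        g = nx.MultiGraph()
        g.add_node(0, pos=(30, 30), kind="junction")
        g.add_node(1, pos=(30, 47), kind="terminal")   # 3 px from col 50
        g.add_node(2, pos=(30, 22), kind="terminal")   # 12 px from col 10
        g.add_node(3, pos=(12, 30), kind="terminal")   # keeps root a junction
        for node, (r, c) in [(1, (30, 47)), (2, (30, 22)), (3, (12, 30))]:
            if c != 30:
                cols = np.arange(30, c + (1 if c > 30 else -1),
                                 1 if c > 30 else -1)
                path = np.stack([np.full_like(cols, 30), cols], axis=1)
            else:
                rows = np.arange(30, r - 1, -1)
                path = np.stack([rows, np.full_like(rows, 30)], axis=1)
            g.add_edge(0, node, path=path, endpoints=(0, node),
                       length=float(len(path) - 1))
        skel = Skeleton(g, m.shape)
        cfg = PruningConfig(p_threshold=1e-6, prdist_threshold=8, r=1.5)
        out = prune_far_branches(skel, curve, cfg)
        kept = {tuple(d["pos"]) for _, d in out.graph.nodes(data=True)}
        assert (30, 47) in kept      # 3 px away: kept
        assert (30, 22) not in kept  # 12 px away: removed

    def test_round_cell_may_become_empty_flagged(self):
        m = np.zeros((51, 51), bool)
        rr, cc = sk_disk((25, 25), 20.5)
        m[rr, cc] = True
        skel = skeletonize(m)
        curve = curve_from_polygon(extract_boundary(m))
        cfg = PruningConfig.from_body_length(curve.body_length)
        out = prune(skel, curve, cfg)
        # everything is locally round: no branch survives, no error
        assert out.is_empty
        assert out.empty_flag


class TestPruningConfig:
    def test_table_scaling(self):
        cfg = PruningConfig.from_body_length(60.0)
        assert cfg.p_threshold == pytest.approx(6.0)
        assert cfg.prdist_threshold == pytest.approx(10.0)
        assert cfg.r == 1.5

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            PruningConfig(p_threshold=0, prdist_threshold=1)
        with pytest.raises(ValueError):
            PruningConfig(p_threshold=1, prdist_threshold=1, r=1.0)
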