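"""Medial-axis skeletons of cell shapes and branch pruning.

The skeleton (medial axis) of a cell mask is the locus of centers of
maximal inscribed balls; wherever the membrane protrudes, the skeleton
grows a branch.  We compute it as the ridge of the Euclidean distance
transform with topology-preserving thinning (equivalent to a grassfire
simulation), convert the one-pixel-wide pixel set into a graph of
junctions, terminals and branch paths, and prune it with two criteria so
that each pseudopod maps onto exactly one *outer branch*:

1. **Short branches** (shorter than ``p_threshold``) are removed when
   independent, or merged with / removed in favour of a sibling branch
   sharing the same root, depending on the length ratio ``r``.
   Combining replaces the two branches with a straight branch from the
   shared root to the average of the two old terminals, which keeps the
   approximate centre line of the underlying pseudopod.
2. **Far branches**, whose free terminal lies farther than
   ``prdist_threshold`` from the membrane, sit in locally flat (low
   curvature) parts of the cell where no pseudopodial activity is
   expected, and are removed.

Pruning iterates to a fixed point (``single_pass=True`` restricts each
criterion to one sweep).  A skeleton may legitimately end up empty — a
perfectly round cell has no significant branches; this is flagged, not
an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.draw import line as draw_line
from skimage.morphology import medial_axis

from .boundary import BoundaryCurve
from .errors import DegenerateShape
from .segmentation import SegmentedFrame

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class PruningConfig:
    """Pruning thresholds (pixels) resolved for one frame.

    Defaults follow the standard scaling: ``p_threshold`` is 1/10 of the
    cell body length, ``prdist_threshold`` 1/6 of the body length, and
    the combine/delete ratio ``r`` is 1.5.
    """

    p_threshold: float
    prdist_threshold: float
    r: float = 1.5

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.prdist_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.r <= 1:
            raise ValueError("r must be > 1")

    @classmethod
    def from_body_length(cls, body_length: float, r: float = 1.5,
                         p_factor: float = 0.1,
                         prdist_factor: float = 1.0 / 6.0) -> "PruningConfig":
        return cls(p_threshold=p_factor * body_length,
                   prdist_threshold=prdist_factor * body_length, r=r)


@dataclass
class Branch:
    """One outer branch: path runs from the root to the free terminal."""

    root: int
    terminal: int
    path: np.ndarray  # (n, 2) pixel coordinates, root first
    length: float
    edge: tuple  # (u, v, key) in the underlying graph
    isolated: bool = False  # both endpoints free (lone segment skeleton)


@dataclass
class Skeleton:
    """Pruned medial-axis graph of one frame.

    Nodes carry ``pos`` (row, col) and ``kind`` (terminal/junction);
    edges carry ``path`` (pixel polyline), ``endpoints`` (orientation of
    the stored path) and ``length`` (arc length, diagonal steps √2).
    """

    graph: nx.MultiGraph
    shape: tuple[int, int]
    frame_index: int = 0
    empty_flag: bool = field(default=False)

    @property
    def pixels(self) -> np.ndarray:
        """All skeleton pixels as an (n, 2) integer array."""
        pts = []
        for _, _, d in self.graph.edges(data=True):
            pts.append(np.asarray(d["path"]))
        for _, d in self.graph.nodes(data=True):
            pts.append(np.asarray([d["pos"]]))
        if not pts:
            return np.empty((0, 2), dtype=int)
        return np.unique(np.vstack(pts).astype(int), axis=0)

    @property
    def is_empty(self) -> bool:
        return self.graph.number_of_edges() == 0

    def outer_branches(self, both_orientations: bool = False) -> list[Branch]:
        """Enumerate outer branches (edges with a free, degree-1 terminal).

        A lone-segment skeleton (both endpoints free) is reported once
        with an arbitrary but deterministic root, or twice (one per
        orientation) when ``both_orientations`` is set, as needed for
        activity detection where either end may point at an activity.
        """
        g = self.graph
        out: list[Branch] = []
        for u, v, k, d in sorted(g.edges(keys=True, data=True),
                                 key=lambda e: (e[3]["endpoints"], e[2])):
            du, dv = g.degree(u), g.degree(v)
            path = oriented_path(d, u)
            if du == 1 and dv == 1 and u != v:
                out.append(Branch(u, v, path, d["length"], (u, v, k), True))
                if both_orientations:
                    out.append(Branch(v, u, path[::-1], d["length"],
                                      (u, v, k), True))
            elif dv == 1 and du > 1:
                out.append(Branch(u, v, path, d["length"], (u, v, k)))
            elif du == 1 and dv > 1:
                out.append(Branch(v, u, path[::-1], d["length"], (u, v, k)))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, b in enumerate(self.outer_branches()):
            rp = self.graph.nodes[b.root]["pos"]
            tp = self.graph.nodes[b.terminal]["pos"]
            rows.append({"frame": self.frame_index, "branch_id": i,
                         "root_x": rp[1], "root_y": rp[0],
                         "terminal_x": tp[1], "terminal_y": tp[0],
                         "length_px": b.length})
        return pd.DataFrame(rows, columns=["frame", "branch_id", "root_x",
                                           "root_y", "terminal_x",
                                           "terminal_y", "length_px"])


def oriented_path(edge_data: dict, start_node: int) -> np.ndarray:
    """Return the edge's pixel path oriented to start at start_node."""
    path = np.asarray(edge_data["path"])
    if edge_data["endpoints"][0] == start_node:
        return path
    return path[::-1]


def _path_length(path: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    d = np.diff(np.asarray(path, dtype=float), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def skeletonize(frame: SegmentedFrame | np.ndarray,
                frame_index: int | None = None) -> Skeleton:
    """Medial-axis skeleton of a mask, as a branch graph.

    Computed as the distance-transform ridge with topology-preserving
    thinning; mask topology (components, holes) is preserved.

    Raises
    ------
    DegenerateShape
        for masks smaller than 8 pixels.
    """
    if isinstance(frame, SegmentedFrame):
        mask = frame.mask
        idx = frame.frame_index if frame_index is None else frame_index
    else:
        mask = np.asarray(frame, bool)
        idx = frame_index or 0
    if mask.sum() < 8:
        raise DegenerateShape(f"mask has {int(mask.sum())} px (< 8)")
    # fixed rng: the thinning's pixel-order tie-breaking must be
    # reproducible for identical inputs
    skel_mask = medial_axis(mask, rng=0)
    graph = build_graph(skel_mask)
    return Skeleton(graph=graph, shape=mask.shape, frame_index=idx)


def build_graph(skel_mask: np.ndarray) -> nx.MultiGraph:
    """Convert a one-pixel-wide skeleton into a junction/terminal graph.

    Degree-1 pixels become terminal nodes; 8-connected clusters of
    degree>=3 pixels are merged into single junction nodes; the pixel
    chains between them become edges whose length counts diagonal steps
    as sqrt(2).
    """
    pts = {tuple(p) for p in np.argwhere(np.asarray(skel_mask, bool))}
    g = nx.MultiGraph()
    if not pts:
        return g

    def nbrs(p):
        return [(p[0] + dr, p[1] + dc) for dr, dc in _OFFSETS
                if (p[0] + dr, p[1] + dc) in pts]

    deg = {p: len(nbrs(p)) for p in pts}
    junction_px = {p for p, d in deg.items() if d >= 3}
    terminal_px = {p for p, d in deg.items() if d <= 1}

    pixel2node: dict[tuple, int] = {}
    node_id = 0
    # cluster adjacent junction pixels into one node
    remaining = set(junction_px)
    while remaining:
        seed = min(remaining)
        cluster = {seed}
        stack = [seed]
        while stack:
            cur = stack.pop()
            for q in nbrs(cur):
                if q in remaining and q not in cluster:
                    cluster.add(q)
                    stack.append(q)
        remaining -= cluster
        centroid = np.mean(np.array(sorted(cluster)), axis=0)
        anchor = min(cluster, key=lambda p: (np.hypot(p[0] - centroid[0],
                                                      p[1] - centroid[1]), p))
        g.add_node(node_id, pos=anchor, kind="junction")
        for p in cluster:
            pixel2node[p] = node_id
        node_id += 1
    for p in sorted(terminal_px):
        g.add_node(node_id, pos=p, kind="terminal")
        pixel2node[p] = node_id
        node_id += 1

    if not pixel2node:  # pure cycle: anchor one node on it
        seed = min(pts)
        g.add_node(node_id, pos=seed, kind="junction")
        pixel2node[seed] = node_id
        node_id += 1

    visited: set[tuple] = set()
    seen_direct: set[frozenset] = set()
    for n in sorted(g.nodes):
        anchors = sorted(p for p, nid in pixel2node.items() if nid == n)
        for p in anchors:
            for q in sorted(nbrs(p)):
                if q in pixel2node:
                    m = pixel2node[q]
                    if m == n:
                        continue
                    key = frozenset((p, q))
                    if key in seen_direct:
                        continue
                    seen_direct.add(key)
                    path = np.array([p, q])
                    g.add_edge(n, m, path=path, endpoints=(n, m),
                               length=_path_length(path))
                elif q not in visited:
                    path = [p, q]
                    visited.add(q)
                    prev, cur = p, q
                    while cur not in pixel2node:
                        cands = [x for x in sorted(nbrs(cur))
                                 if x != prev and x not in visited]
                        node_c = [x for x in sorted(nbrs(cur))
                                  if x != prev and x in pixel2node]
                        if node_c:
                            cur, prev = node_c[0], cur
                            path.append(cur)
                            break
                        if not cands:
                            break  # dead end inside a consumed loop
                        visited.add(cands[0])
                        prev, cur = cur, cands[0]
                        path.append(cur)
                    if cur in pixel2node:
                        m = pixel2node[cur]
                        arr = np.array(path)
                        g.add_edge(n, m, path=arr, endpoints=(n, m),
                                   length=_path_length(arr))
    _simplify(g)
    return g


def _simplify(g: nx.MultiGraph) -> None:
    """Splice through ex-junction degree-2 nodes; fix node kinds; drop orphans."""
    changed = True
    while changed:
        changed = False
        for n in sorted(g.nodes):
            d = g.degree(n)
            if d == 0 and g.number_of_nodes() > 1:
                g.remove_node(n)
                changed = True
                break
            if d == 1 and g.nodes[n]["kind"] != "terminal":
                g.nodes[n]["kind"] = "terminal"
            if d == 2 and g.nodes[n]["kind"] == "junction":
                edges = list(g.edges(n, keys=True, data=True))
                if len(edges) != 2:  # self-loop counts double; leave it
                    continue
                (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
                a = v1 if u1 == n else u1
                b = v2 if u2 == n else u2
                p1 = oriented_path(d1, a)  # a ... n
                p2 = oriented_path(d2, n)  # n ... b
                path = np.vstack([p1, p2[1:]])
                g.remove_edge(u1, v1, k1)
                g.remove_edge(u2, v2, k2)
                g.remove_node(n)
                g.add_edge(a, b, path=path, endpoints=(a, b),
                           length=_path_length(path))
                changed = True
                break


def _remove_branch(g: nx.MultiGraph, b: Branch) -> None:
    u, v, k = b.edge
    if g.has_edge(u, v, k):
        g.remove_edge(u, v, k)
    if b.terminal in g and g.degree(b.terminal) == 0:
        g.remove_node(b.terminal)
    if b.isolated and b.root in g and g.degree(b.root) == 0:
        g.remove_node(b.root)
    _simplify(g)


def _branch_key(g: nx.MultiGraph, b: Branch) -> tuple:
    return (b.length, tuple(g.nodes[b.terminal]["pos"]))


def prune_short_branches(skel: Skeleton, cfg: PruningConfig,
                         single_pass: bool = False) -> Skeleton:
    """Remove or combine outer branches shorter than ``p_threshold``.

    A short branch with no sibling at its root is removed.  A short
    branch with siblings is compared to the shortest of them: if the
    longer of the pair is under ``r`` times the shorter, or itself under
    ``p_threshold``, the pair is combined into a straight branch from
    the root to the midpoint of the two old terminals; otherwise the
    shorter is removed.  More than two siblings are handled sequentially
    by repetition.  Iterates to a fixed point unless ``single_pass``.
    """
    g = skel.graph.copy()
    max_rounds = 1 if single_pass else 10 * max(1, g.number_of_edges())
    for _ in range(max_rounds):
        branches = skel_branches = Skeleton(g, skel.shape,
                                            skel.frame_index).outer_branches()
        shorts = sorted((b for b in branches if b.length < cfg.p_threshold),
                        key=lambda b: _branch_key(g, b))
        if not shorts:
            break
        b = shorts[0]
        if b.isolated:
            _remove_branch(g, b)
            continue
        siblings = [s for s in skel_branches
                    if s.root == b.root and s.edge != b.edge]
        if not siblings:
            _remove_branch(g, b)
            continue
        s = min(siblings, key=lambda x: _branch_key(g, x))
        b1, b2 = (b, s) if b.length <= s.length else (s, b)
        if b2.length < cfg.r * b1.length or b2.length < cfg.p_threshold:
            _combine(g, b1, b2)
        else:
            _remove_branch(g, b1)
    empty = g.number_of_edges() == 0
    return Skeleton(g, skel.shape, skel.frame_index, empty_flag=empty)


def _combine(g: nx.MultiGraph, b1: Branch, b2: Branch) -> None:
    """Replace two sibling branches by root -> averaged-terminal."""
    root = b1.root
    t1 = np.asarray(g.nodes[b1.terminal]["pos"], dtype=float)
    t2 = np.asarray(g.nodes[b2.terminal]["pos"], dtype=float)
    new_t = np.round((t1 + t2) / 2.0).astype(int)
    rp = np.asarray(g.nodes[root]["pos"], dtype=int)
    for b in (b1, b2):
        u, v, k = b.edge
        if g.has_edge(u, v, k):
            g.remove_edge(u, v, k)
        if b.terminal in g and g.degree(b.terminal) == 0:
            g.remove_node(b.terminal)
    rr, cc = draw_line(rp[0], rp[1], new_t[0], new_t[1])
    path = np.stack([rr, cc], axis=1)
    nid = max(g.nodes) + 1 if g.number_of_nodes() else 0
    g.add_node(nid, pos=(int(new_t[0]), int(new_t[1])), kind="terminal")
    g.add_edge(root, nid, path=path, endpoints=(root, nid),
               length=_path_length(path))
    _simplify(g)


def prune_far_branches(skel: Skeleton, curve: BoundaryCurve,
                       cfg: PruningConfig) -> Skeleton:
    """Remove outer branches whose free terminal is far from the membrane.

    The terminal of an outer branch is the centre of the maximal ball
    touching the local boundary, so its distance to the membrane is the
    local radius of curvature: a large distance means a locally flat
    boundary where no protrusion or retraction is expected.  All outer
    branches with terminal-to-membrane distance above
    ``prdist_threshold`` are removed.  The skeleton may become empty
    (flagged, not an error).
    """
    g = skel.graph.copy()
    tree = cKDTree(curve.samples[:-1])
    changed = True
    while changed:
        changed = False
        for b in Skeleton(g, skel.shape, skel.frame_index).outer_branches():
            tp = np.asarray(g.nodes[b.terminal]["pos"], dtype=float)
            dist, _ = tree.query(tp)
            if dist > cfg.prdist_threshold:
                _remove_branch(g, b)
                changed = True
                break
    empty = g.number_of_edges() == 0
    return Skeleton(g, skel.shape, skel.frame_index, empty_flag=empty)


def prune(skel: Skeleton, curve: BoundaryCurve, cfg: PruningConfig,
          single_pass: bool = False) -> Skeleton:
    """Full pruning: short branches, far branches, final short pass."""
    out = prune_short_branches(skel, cfg, single_pass=single_pass)
    out = prune_far_branches(out, curve, cfg)
    out = prune_short_branches(out, cfg, single_pass=single_pass)
    out.empty_flag = out.is_empty
    return out
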