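"""Skeleton-to-graph conversion and topological analysis.

The one-pixel-wide medial axis is converted into a graph whose nodes
are typed anatomical landmarks and whose edges are the nerve segments
("single nerve fibres") between them:

* **branch** — a maximal 8-connected cluster of skeleton pixels with
  three or more skeleton neighbours (a fibre bifurcation);
* **endpoint** — a terminal pixel (one neighbour) in the image
  interior: a true nerve ending;
* **connectivity** — a terminal pixel on the outermost pixel row or
  column: a fibre entering or leaving the imaged field;
* internally also **loop** (anchor of a closed fibre loop, degree 2)
  and **isolated** (a single stray skeleton pixel, degree 0).

Edge lengths are chain-code lengths: one pixel pitch per orthogonal
step, √2 pitches per diagonal step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .image_io import Calibration
from .skeleton import SkeletonImage, thin_mask

SQRT2 = sqrt(2.0)

#: Public node kinds; ``loop`` and ``isolated`` are implementation
#: detail kinds that never contribute to the reported counts.
NODE_KINDS = ("branch", "endpoint", "connectivity", "loop", "isolated")

#: Default minimum traced-segment length in µm; shorter terminal spurs
#: are treated as thinning artefacts and pruned.
DEFAULT_MIN_SEGMENT_UM = 2.0

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class SBPNode:
    id: int
    kind: str  # one of NODE_KINDS
    position: tuple[int, int]  # representative (row, col)
    pixels: frozenset[tuple[int, int]] = field(default_factory=frozenset)


@dataclass
class SBPEdge:
    """A traced nerve segment between two nodes.

    ``pixel_path`` runs from a pixel of node ``u`` to a pixel of node
    ``v`` inclusive; interior pixels all have exactly two skeleton
    neighbours.
    """

    id: int
    u: int
    v: int
    pixel_path: list[tuple[int, int]]
    n_orthogonal_steps: int
    n_diagonal_steps: int

    @property
    def length_px(self) -> float:
        return self.n_orthogonal_steps + SQRT2 * self.n_diagonal_steps


@dataclass
class SBPGraph:
    nodes: list[SBPNode]
    edges: list[SBPEdge]
    pixel_pitch_um: float
    n_components: int

    def degree(self, node_id: int) -> int:
        d = 0
        for e in self.edges:
            if e.u == node_id:
                d += 1
            if e.v == node_id:
                d += 1
        return d

    def count_nodes(self, kind: str) -> int:
        return count_nodes(self, kind)

    @property
    def total_length_um(self) -> float:
        return sum(e.length_px for e in self.edges) * self.pixel_pitch_um


def neighbor_counts(skeleton: np.ndarray) -> np.ndarray:
    """8-neighbour count of every pixel, restricted to the skeleton."""
    counts = ndi.convolve(skeleton.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")
    return np.where(skeleton, counts, 0)


def classify_pixels(skel: SkeletonImage) -> dict[tuple[int, int], tuple[str, bool]]:
    """Classify each skeleton pixel by its 8-neighbour count.

    Returns a map ``(row, col) -> (kind, on_border)`` with kind in
    ``{"end", "path", "junction", "isolated"}`` (1, 2, >=3 and 0
    neighbours respectively); ``on_border`` flags end and path pixels
    lying on the outermost pixel row or column.
    """
    s = skel.skeleton
    counts = neighbor_counts(s)
    h, w = s.shape
    out: dict[tuple[int, int], tuple[str, bool]] = {}
    for r, c in np.argwhere(s):
        n = counts[r, c]
        kind = "isolated" if n == 0 else "end" if n == 1 else "path" if n == 2 else "junction"
        on_border = kind in ("end", "path") and (r in (0, h - 1) or c in (0, w - 1))
        out[(int(r), int(c))] = (kind, on_border)
    return out


def _chain_steps(path: list[tuple[int, int]]) -> tuple[int, int]:
    ortho = diag = 0
    for (r0, c0), (r1, c1) in zip(path, path[1:]):
        if r0 != r1 and c0 != c1:
            diag += 1
        else:
            ortho += 1
    return ortho, diag


def build_graph(skel: SkeletonImage) -> SBPGraph:
    """Convert a thin skeleton into a typed-node, weighted-edge graph.

    Adjacent junction pixels are merged into single branch nodes;
    edges are traced along runs of two-neighbour path pixels; closed
    loops with no landmark become self-loop edges anchored at a
    degree-2 loop node.  Node and edge ordering is deterministic
    (raster order of representative pixels).
    """
    s = skel.skeleton
    h, w = s.shape
    counts = neighbor_counts(s)
    is_junction = counts >= 3
    is_end = counts == 1
    is_isolated = (counts == 0) & s
    is_path = (counts == 2) & s

    node_id_of: dict[tuple[int, int], int] = {}
    nodes: list[SBPNode] = []

    # branch nodes: 8-connected clusters of junction pixels
    jl, n_j = ndi.label(is_junction, structure=np.ones((3, 3), bool))
    cluster_pixels: dict[int, list[tuple[int, int]]] = {k: [] for k in range(1, n_j + 1)}
    for r, c in np.argwhere(is_junction):
        cluster_pixels[jl[r, c]].append((int(r), int(c)))
    for k in sorted(cluster_pixels, key=lambda k: min(cluster_pixels[k])):
        pix = sorted(cluster_pixels[k])
        nid = len(nodes)
        nodes.append(SBPNode(id=nid, kind="branch", position=pix[0], pixels=frozenset(pix)))
        for p in pix:
            node_id_of[p] = nid

    # terminal nodes: endpoints in the interior, connectivity points on the border band
    for r, c in map(tuple, np.argwhere(is_end)):
        on_border = r in (0, h - 1) or c in (0, w - 1)
        nid = len(nodes)
        kind = "connectivity" if on_border else "endpoint"
        p = (int(r), int(c))
        nodes.append(SBPNode(id=nid, kind=kind, position=p, pixels=frozenset([p])))
        node_id_of[p] = nid

    # stray single pixels
    for r, c in map(tuple, np.argwhere(is_isolated)):
        nid = len(nodes)
        p = (int(r), int(c))
        nodes.append(SBPNode(id=nid, kind="isolated", position=p, pixels=frozenset([p])))
        node_id_of[p] = nid

    edges: list[SBPEdge] = []
    visited_path = np.zeros_like(s, dtype=bool)
    direct_linked: set[tuple[int, int]] = set()

    def neighbors(r: int, c: int):
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and s[rr, cc]:
                yield rr, cc

    def add_edge(u: int, v: int, path: list[tuple[int, int]]) -> None:
        ortho, diag = _chain_steps(path)
        edges.append(
            SBPEdge(
                id=len(edges), u=u, v=v, pixel_path=path,
                n_orthogonal_steps=ortho, n_diagonal_steps=diag,
            )
        )

    # trace edges outward from every node pixel, in raster order
    for node in nodes:
        for p in sorted(node.pixels):
            for q in sorted(neighbors(*p)):
                if q in node_id_of:
                    other = node_id_of[q]
                    if other == node.id:
                        continue  # intra-cluster adjacency
                    key = (min(node.id, other), max(node.id, other))
                    if key in direct_linked:
                        continue
                    direct_linked.add(key)
                    add_edge(node.id, other, [p, q])
                    continue
                if visited_path[q]:
                    continue
                # walk along the run of 2-neighbour path pixels
                path = [p, q]
                visited_path[q] = True
                prev, cur = p, q
                while cur not in node_id_of:
                    nxts = [x for x in neighbors(*cur) if x != prev]
                    if len(nxts) != 1:
                        raise RuntimeError(
                            f"non-thin skeleton: path pixel {cur} has "
                            f"{len(nxts) + 1} neighbours"
                        )
                    prev, cur = cur, nxts[0]
                    if cur not in node_id_of:
                        visited_path[cur] = True
                    path.append(cur)
                add_edge(node.id, node_id_of[cur], path)

    # remaining unvisited path pixels form closed loops with no landmark
    leftover = is_path & ~visited_path
    if leftover.any():
        for r, c in map(tuple, np.argwhere(leftover)):
            if visited_path[r, c]:
                continue
            anchor = (int(r), int(c))
            nid = len(nodes)
            nodes.append(SBPNode(id=nid, kind="loop", position=anchor, pixels=frozenset([anchor])))
            node_id_of[anchor] = nid
            visited_path[r, c] = True
            nbrs = sorted(neighbors(r, c))
            path = [anchor]
            prev, cur = anchor, nbrs[0]
            while cur != anchor:
                visited_path[cur] = True
                path.append(cur)
                nxts = [x for x in neighbors(*cur) if x != prev]
                if len(nxts) != 1:
                    raise RuntimeError(f"malformed loop at {cur}")
                prev, cur = cur, nxts[0]
            path.append(anchor)
            add_edge(nid, nid, path)

    _, n_components = ndi.label(s, structure=np.ones((3, 3), bool))
    return SBPGraph(
        nodes=nodes, edges=edges,
        pixel_pitch_um=skel.pixel_pitch_um,
        n_components=int(n_components),
    )


def count_nodes(g: SBPGraph, kind: str) -> int:
    """Number of nodes of one kind (branch / endpoint / connectivity)."""
    if kind not in NODE_KINDS:
        raise ValueError(f"unknown node kind {kind!r}; expected one of {NODE_KINDS}")
    return sum(1 for n in g.nodes if n.kind == kind)


def edge_length(e: SBPEdge, cal: Calibration | float) -> float:
    """Chain-code length of a segment in µm.

    ``(#orthogonal steps + √2 · #diagonal steps) · pixel pitch``.
    """
    pitch = cal.pixel_pitch_um if isinstance(cal, Calibration) else float(cal)
    return e.length_px * pitch


def prune_spurs(skel: SkeletonImage, min_segment_um: float = DEFAULT_MIN_SEGMENT_UM) -> SkeletonImage:
    """Remove terminal spurs shorter than ``min_segment_um`` and stray pixels.

    Thinning leaves one-to-two-pixel side whiskers at junctions and
    stray isolated pixels; segments below the threshold that end in an
    interior endpoint are deleted (junction clusters are kept) and the
    skeleton is returned for re-analysis.  Single isolated pixels are
    always dropped: they have no measurable length.
    """
    g = build_graph(skel)
    out = skel.skeleton.copy()
    thresh_px = min_segment_um / skel.pixel_pitch_um
    kind_of = {n.id: n.kind for n in g.nodes}
    degree = {n.id: 0 for n in g.nodes}
    for e in g.edges:
        degree[e.u] += 1
        degree[e.v] += 1
    nodes_by_id = {n.id: n for n in g.nodes}
    for e in g.edges:
        if e.length_px >= thresh_px:
            continue
        tips = {nid for nid in (e.u, e.v) if kind_of[nid] == "endpoint" and degree[nid] == 1}
        if not tips:
            continue
        # drop the whisker: interior pixels plus free tips, keeping the
        # pixels of any anchoring junction/border node
        keep = {p for nid in (e.u, e.v) if nid not in tips for p in nodes_by_id[nid].pixels}
        for p in e.pixel_path:
            if p not in keep:
                out[p] = False
    for n in g.nodes:
        if n.kind == "isolated":
            for p in n.pixels:
                out[p] = False
    # a pruned junction may leave a one-pixel nub on an otherwise
    # straight run; a final thinning pass flattens it
    out = thin_mask(out)
    return SkeletonImage(skeleton=out, pixel_pitch_um=skel.pixel_pitch_um, parent=skel.parent)


def export_edge_list(g: SBPGraph, path: str | Path) -> None:
    """Write a plain-text dump of the graph for debugging.

    Node lines: ``node <id> <kind> <row> <col>``; edge lines:
    ``edge <id> <node_u> <node_v> <length_um>``.
    """
    with open(path, "w") as fh:
        for n in g.nodes:
            fh.write(f"node {n.id} {n.kind} {n.position[0]} {n.position[1]}\n")
        for e in g.edges:
            fh.write(f"edge {e.id} {e.u} {e.v} {edge_length(e, g.pixel_pitch_um):.4f}\n")
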