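"""Skeleton-graph construction and vascular network topology features.

Skeleton pixels are classified by their neighbor count under *m-adjacency*
(mixed adjacency from digital topology): orthogonal neighbors always count,
while a diagonal neighbor counts only when neither of the two pixels that
would complete the corner is set — a diagonal link that parallels an
orthogonal path is redundant and would otherwise inflate the degree of
pixels next to junctions.  One m-neighbor makes an endpoint, two a slab
(interior of a segment), three or more a branch pixel.  Adjacent branch
pixels are merged into a single branch node (thinning can emit multi-pixel
junction clusters).  Segments are traced from node pixels through slab
pixels to the next node; centerline length sums unit steps for orthogonal
moves and sqrt(2) for (m-valid) diagonal moves, times the pixel size.

A connected component with no branch node is an *isolated* segment group —
vasculature disconnected from any branching network; its total
area-normalized centerline length is a fragmentation surrogate.  The
*branching interval* is the mean centerline length of segments whose both
ends are branch nodes, i.e. the typical centerline distance between adjacent
junctions.

Degenerate cases: an isolated single pixel becomes a lone endpoint-kind node
with no segments; a closed slab-only loop (no junction anywhere) is anchored
at an arbitrary pixel by a degenerate endpoint-kind node and recorded as one
self-loop segment, so a ring still counts as isolated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .rf_preprocessing import ValidationError
from .vessel_segmentation import SkeletonMask

__all__ = [
    "m_degree",
    "m_neighbors",
    "SkeletonNode",
    "SkeletonSegment",
    "SkeletonGraph",
    "TopologyFeatures",
    "build_skeleton_graph",
    "topology_features",
    "roi_area",
    "graph_to_networkx",
]

SQRT2 = math.sqrt(2.0)
_EIGHT = np.ones((3, 3), dtype=int)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

ENDPOINT = "endpoint"
BRANCH_NODE = "branch_node"


@dataclass(frozen=True)
class SkeletonNode:
    row: int
    col: int
    kind: str  # ENDPOINT or BRANCH_NODE
    pixels: tuple[tuple[int, int], ...]  # merged junction cluster (1 px for endpoints)


@dataclass(frozen=True)
class SkeletonSegment:
    node_a: int
    node_b: int
    length_um: float
    pixel_path: tuple[tuple[int, int], ...]
    component: int


@dataclass(frozen=True)
class SkeletonGraph:
    nodes: list[SkeletonNode]
    segments: list[SkeletonSegment]
    n_components: int
    is_isolated: np.ndarray  # bool per component: contains no branch node
    pixel_size_um: float
    node_component: np.ndarray  # component id per node

    @property
    def n_endpoints(self) -> int:
        return sum(1 for n in self.nodes if n.kind == ENDPOINT)

    @property
    def n_branch_nodes(self) -> int:
        return sum(1 for n in self.nodes if n.kind == BRANCH_NODE)

    @property
    def total_length_um(self) -> float:
        return sum(s.length_um for s in self.segments)

    @property
    def isolated_length_um(self) -> float:
        return sum(s.length_um for s in self.segments if self.is_isolated[s.component])


@dataclass(frozen=True)
class TopologyFeatures:
    """Area-normalized topology features; NaN branching interval = undefined."""

    n_branches_per_mm2: float
    total_branch_length_mm_per_mm2: float
    normalized_isolated_branch_length: float  # um of isolated centerline per um^2
    branching_interval_um: float
    n_branch_nodes_per_mm2: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def _check_thin(skel: np.ndarray) -> None:
    if (skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]).any():
        raise ValidationError("skeleton not thin: fully set 2x2 block present")


def _shifted(s: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """s translated by (-dr, -dc) with zero fill: out[r, c] = s[r+dr, c+dc]."""
    out = np.zeros_like(s)
    rows, cols = s.shape
    rs = slice(max(dr, 0), rows + min(dr, 0))
    cs = slice(max(dc, 0), cols + min(dc, 0))
    rd = slice(max(-dr, 0), rows + min(-dr, 0))
    cd = slice(max(-dc, 0), cols + min(-dc, 0))
    out[rd, cd] = s[rs, cs]
    return out


def m_degree(s: np.ndarray) -> np.ndarray:
    """Per-pixel neighbor count under m-adjacency (vectorized).

    A diagonal neighbor is counted only if neither corner-completing
    orthogonal pixel is set; orthogonal neighbors always count.
    """
    deg = np.zeros(s.shape, dtype=np.int64)
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        deg += _shifted(s, dr, dc)
    for dr, dc in ((-1, -1), (-1, 1), (1, -1), (1, 1)):
        valid = _shifted(s, dr, dc) & ~_shifted(s, dr, 0) & ~_shifted(s, 0, dc)
        deg += valid
    return deg


def m_neighbors(s: np.ndarray, p: tuple[int, int]) -> list[tuple[int, int]]:
    """m-adjacent skeleton neighbors of pixel p, in fixed scan order."""
    r, c = p
    rows, cols = s.shape

    def on(rr: int, cc: int) -> bool:
        return 0 <= rr < rows and 0 <= cc < cols and s[rr, cc]

    out = []
    for dr, dc in _OFFSETS:
        rr, cc = r + dr, c + dc
        if not on(rr, cc):
            continue
        if dr != 0 and dc != 0 and (on(r + dr, c) or on(r, c + dc)):
            continue  # redundant diagonal
        out.append((rr, cc))
    return out


def _step_um(a: tuple[int, int], b: tuple[int, int], px: float) -> float:
    return (SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0) * px


def build_skeleton_graph(skel: SkeletonMask) -> SkeletonGraph:
    """Classify pixels, merge junction clusters, and trace all segments."""
    s = skel.mask
    px = skel.pixel_size_um
    _check_thin(s)

    neigh = m_degree(s)
    branch_px = s & (neigh >= 3)
    slab_px = s & (neigh == 2)
    end_px = s & (neigh <= 1)  # includes isolated single pixels

    comp_labels, n_components = ndimage.label(s, structure=_EIGHT)
    branch_labels, n_branch_clusters = ndimage.label(branch_px, structure=_EIGHT)

    nodes: list[SkeletonNode] = []
    node_of_pixel: dict[tuple[int, int], int] = {}
    # one node per junction cluster, positioned at the cluster's first pixel
    cluster_pixels: dict[int, list[tuple[int, int]]] = {}
    for r, c in zip(*np.nonzero(branch_px)):
        cluster_pixels.setdefault(branch_labels[r, c], []).append((int(r), int(c)))
    for lbl in range(1, n_branch_clusters + 1):
        pix = tuple(sorted(cluster_pixels[lbl]))
        idx = len(nodes)
        nodes.append(SkeletonNode(pix[0][0], pix[0][1], BRANCH_NODE, pix))
        for p in pix:
            node_of_pixel[p] = idx
    for r, c in zip(*np.nonzero(end_px)):
        p = (int(r), int(c))
        node_of_pixel[p] = len(nodes)
        nodes.append(SkeletonNode(p[0], p[1], ENDPOINT, (p,)))

    def neighbors(p: tuple[int, int]) -> list[tuple[int, int]]:
        return m_neighbors(s, p)

    segments: list[SkeletonSegment] = []
    visited_slab = np.zeros_like(s)
    direct_pairs: set[frozenset[tuple[int, int]]] = set()

    def add_segment(path: list[tuple[int, int]]) -> None:
        length = sum(_step_um(path[i], path[i + 1], px) for i in range(len(path) - 1))
        segments.append(
            SkeletonSegment(
                node_a=node_of_pixel[path[0]],
                node_b=node_of_pixel[path[-1]],
                length_um=length,
                pixel_path=tuple(path),
                component=int(comp_labels[path[0]]) - 1,
            )
        )

    for start, start_node in list(node_of_pixel.items()):
        for q in neighbors(start):
            if q in node_of_pixel:
                # direct node-to-node adjacency (no slab in between)
                if node_of_pixel[q] != start_node:
                    key = frozenset((start, q))
                    if key not in direct_pairs:
                        direct_pairs.add(key)
                        add_segment([start, q])
                continue
            if visited_slab[q]:
                continue
            # walk through slab pixels until the next node pixel
            path = [start, q]
            visited_slab[q] = True
            prev, cur = start, q
            while True:
                nxt = [p for p in neighbors(cur) if p != prev]
                # at a diagonal corner both the previous slab and the next may
                # be adjacent; prefer an unvisited slab, else a node pixel
                step = None
                for p in nxt:
                    if p in node_of_pixel:
                        step = p
                        break
                for p in nxt:
                    if p not in node_of_pixel and not visited_slab[p]:
                        step = p
                        break
                if step is None:
                    break  # dead end inside slabs (shouldn't happen on thin skeletons)
                path.append(step)
                if step in node_of_pixel:
                    break
                visited_slab[step] = True
                prev, cur = cur, step
            if path[-1] in node_of_pixel:
                add_segment(path)

    # pure slab cycles: loops never reached from any node
    for r, c in zip(*np.nonzero(slab_px & ~visited_slab)):
        p = (int(r), int(c))
        if visited_slab[p]:
            continue
        # anchor the cycle with a degenerate endpoint-kind node
        anchor_idx = len(nodes)
        nodes.append(SkeletonNode(p[0], p[1], ENDPOINT, (p,)))
        node_of_pixel[p] = anchor_idx
        visited_slab[p] = True
        path = [p]
        prev, cur = None, p
        while True:
            nxt = [q for q in neighbors(cur) if q != prev and (q == p or not visited_slab[q])]
            if not nxt:
                break
            step = nxt[0]
            path.append(step)
            if step == p:
                break
            visited_slab[step] = True
            prev, cur = cur, step
        if path[-1] != p:
            path.append(p)  # close the loop for length accounting
        add_segment(path)

    is_isolated = np.ones(n_components, dtype=bool)
    node_component = np.zeros(len(nodes), dtype=np.int64)
    for i, node in enumerate(nodes):
        comp = int(comp_labels[node.row, node.col]) - 1
        node_component[i] = comp
        if node.kind == BRANCH_NODE:
            is_isolated[comp] = False

    return SkeletonGraph(
        nodes=nodes,
        segments=segments,
        n_components=n_components,
        is_isolated=is_isolated,
        pixel_size_um=px,
        node_component=node_component,
    )


def topology_features(graph: SkeletonGraph, roi_area_um2: float) -> TopologyFeatures:
    """Normalize counts/lengths by ROI area; average junction-to-junction spans.

    The branching interval averages only segments whose *both* endpoints are
    branch nodes.  When no such segment exists it is recorded as NaN with a
    warning; downstream analyses treat the image as missing for that feature.
    """
    if roi_area_um2 <= 0:
        raise ValidationError("roi_area_um2 must be positive")
    area_mm2 = roi_area_um2 / 1e6
    bb_lengths = [
        seg.length_um
        for seg in graph.segments
        if graph.nodes[seg.node_a].kind == BRANCH_NODE
        and graph.nodes[seg.node_b].kind == BRANCH_NODE
    ]
    if bb_lengths:
        interval = float(np.mean(bb_lengths))
    else:
        warnings.warn(
            "no branch-to-branch segment: branching_interval is undefined "
            "for this image",
            stacklevel=2,
        )
        interval = float("nan")
    return TopologyFeatures(
        n_branches_per_mm2=len(graph.segments) / area_mm2,
        total_branch_length_mm_per_mm2=(graph.total_length_um / 1e3) / area_mm2,
        normalized_isolated_branch_length=graph.isolated_length_um / roi_area_um2,
        branching_interval_um=interval,
        n_branch_nodes_per_mm2=graph.n_branch_nodes / area_mm2,
    )


def roi_area(shape: tuple[int, int], pixel_size_um: float) -> float:
    """ROI area in um^2: rows x cols x pixel_size^2."""
    rows, cols = shape
    if rows <= 0 or cols <= 0 or pixel_size_um <= 0:
        raise ValidationError("shape and pixel size must be positive")
    return rows * cols * pixel_size_um**2


def graph_to_networkx(graph: SkeletonGraph):
    """Export as a networkx MultiGraph (for GraphML or further analysis)."""
    import networkx as nx

    g = nx.MultiGraph()
    for i, node in enumerate(graph.nodes):
        g.add_node(i, row=node.row, col=node.col, kind=node.kind)
    for seg in graph.segments:
        g.add_edge(seg.node_a, seg.node_b, length_um=seg.length_um)
    return g
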