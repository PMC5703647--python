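"""Parsing of 1-pixel-wide skeletonized segmentation frames.

Vertices are skeleton pixels with three or more skeleton neighbors
(adjacent vertex pixels clustered to one vertex at their centroid);
junctions are 8-connected pixel chains walked from vertex to vertex.
Chains that end at the image border or at a free end are border-flagged
and excluded from downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve, label

__all__ = [
    "SkeletonVertex",
    "Junction",
    "FrameGraph",
    "parse_skeleton",
    "junction_length_px",
]

_NEIGH_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SkeletonVertex:
    id: int
    pos: tuple[float, float]  # (row, col) centroid of the vertex cluster
    pixels: list[tuple[int, int]]
    junctions: list[int] = field(default_factory=list)


@dataclass
class Junction:
    """One junction within a single frame."""

    id: int
    chain: list[tuple[int, int]]  # ordered pixels, vertex to vertex
    v1: int  # vertex id (-1 if open/border end)
    v2: int
    border: bool = False

    @property
    def length_px(self) -> float:
        return junction_length_px(self.chain)

    @property
    def midpoint(self) -> tuple[float, float]:
        arr = np.asarray(self.chain, dtype=float)
        return tuple(arr[len(arr) // 2]) if len(arr) else (np.nan, np.nan)


@dataclass
class FrameGraph:
    """Vertices + junctions of one parsed frame."""

    vertices: list[SkeletonVertex]
    junctions: list[Junction]
    shape: tuple[int, int]

    def interior_junctions(self) -> list[Junction]:
        return [j for j in self.junctions if not j.border]


def junction_length_px(chain) -> float:
    """Length of a pixel chain by the block rule: the chain is cut at
    every change of step direction and the Euclidean distances between
    consecutive cut points (block endpoints) are summed.

    Equals the endpoint distance for straight runs, so curvy chains are
    never overestimated beyond the per-pixel-step sum.
    """
    pts = np.asarray(chain, dtype=float)
    if len(pts) < 2:
        return 0.0
    steps = np.diff(pts, axis=0)
    turn = np.any(np.diff(steps, axis=0) != 0, axis=1)
    nodes = np.concatenate([[True], turn, [True]])
    block_pts = pts[nodes]
    return float(np.linalg.norm(np.diff(block_pts, axis=0), axis=1).sum())


def parse_skeleton(image: np.ndarray) -> FrameGraph:
    """Decompose a skeleton image into vertices and junction chains.

    Every skeleton pixel is visited exactly once: it belongs either to a
    vertex cluster or to exactly one junction chain.
    """
    mask = np.asarray(image) > 0
    h, w = mask.shape
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    ncount = convolve(mask.astype(int), kernel, mode="constant")
    vertex_px = mask & (ncount >= 3)

    # cluster adjacent vertex pixels
    lab, n_vert = label(vertex_px, structure=np.ones((3, 3), dtype=int))
    vertices: list[SkeletonVertex] = []
    vert_of_pixel: dict[tuple[int, int], int] = {}
    for vid in range(1, n_vert + 1):
        rr, cc = np.nonzero(lab == vid)
        pix = list(zip(rr.tolist(), cc.tolist()))
        vertices.append(
            SkeletonVertex(
                id=vid - 1, pos=(float(rr.mean()), float(cc.mean())), pixels=pix
            )
        )
        for p in pix:
            vert_of_pixel[p] = vid - 1

    chain_mask = mask & ~vertex_px
    visited = np.zeros_like(mask)
    junctions: list[Junction] = []

    def neighbors(r: int, c: int):
        for dr, dc in _NEIGH_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                yield rr, cc

    def touching_vertex(r: int, c: int) -> int:
        for rr, cc in neighbors(r, c):
            if (rr, cc) in vert_of_pixel:
                return vert_of_pixel[(rr, cc)]
        return -1

    comp_lab, n_comp = label(chain_mask, structure=np.ones((3, 3), dtype=int))
    for comp in range(1, n_comp + 1):
        rr, cc = np.nonzero(comp_lab == comp)
        pix = set(zip(rr.tolist(), cc.tolist()))
        # chain endpoints: pixels with <= 1 neighbor inside the component
        ends = [
            p
            for p in pix
            if sum((q in pix) for q in neighbors(*p)) <= 1
        ]
        if not ends:  # isolated loop without vertices: flag as border-like
            start = min(pix)
        else:
            start = min(ends)
        # walk the chain
        chain = [start]
        seen = {start}
        cur = start
        while True:
            nxt = [q for q in neighbors(*cur) if q in pix and q not in seen]
            if not nxt:
                break
            # prefer 4-connected continuation for stable ordering
            nxt.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
            cur = nxt[0]
            chain.append(cur)
            seen.add(cur)
        v_start = touching_vertex(*chain[0])
        v_end = touching_vertex(*chain[-1])
        # any pixel on the image border marks a junction truncated by
        # the field of view
        on_border = any(
            r in (0, h - 1) or c in (0, w - 1) for r, c in chain
        )
        # a chain with both ends on one vertex is a corner artifact, not
        # an interface between two cells
        border = v_start < 0 or v_end < 0 or on_border or v_start == v_end
        jid = len(junctions)
        junctions.append(
            Junction(id=jid, chain=chain, v1=v_start, v2=v_end, border=border)
        )
        for v in (v_start, v_end):
            if v >= 0:
                vertices[v].junctions.append(jid)

    return FrameGraph(vertices=vertices, junctions=junctions, shape=(h, w))
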