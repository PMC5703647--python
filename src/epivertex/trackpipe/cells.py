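"""Cell (face) detection from parsed skeleton frames.

Faces of the junction graph are found by ordered traversal: from each
directed junction the walk continues with the next junction clockwise
around the reached vertex, until it returns to the start.  Each
interior face is found exactly once; the outer face (negative
orientation) is discarded, as are faces touching border junctions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import FrameGraph

__all__ = ["FrameCell", "detect_cells"]


@dataclass
class FrameCell:
    id: int
    junction_ids: list[int]
    vertex_ids: list[int]
    centroid: tuple[float, float]  # (row, col)
    area: float  # px^2
    perimeter: float  # px


def detect_cells(frame: FrameGraph) -> list[FrameCell]:
    """Identify interior faces of the parsed junction graph."""
    # directed half-junction bookkeeping: (junction, orientation) where
    # orientation 0 walks v1 -> v2
    vpos = {v.id: np.asarray(v.pos) for v in frame.vertices}

    def angle_at(vid: int, jid: int) -> float:
        """Direction of junction jid leaving vertex vid."""
        j = frame.junctions[jid]
        other = j.v2 if j.v1 == vid else j.v1
        if j.chain:
            # aim at a nearby chain pixel for curved junctions
            p0 = vpos[vid]
            ref = j.chain[0] if j.v1 == vid else j.chain[-1]
            d = np.asarray(ref, float) - p0
            if np.linalg.norm(d) < 1e-9 and other >= 0:
                d = vpos[other] - p0
        elif other >= 0:
            d = vpos[other] - vpos[vid]
        else:
            return 0.0
        return float(np.arctan2(d[1], d[0]))  # (row, col) frame

    # sorted rotation of junctions around each vertex
    rotation: dict[int, list[int]] = {}
    for v in frame.vertices:
        rotation[v.id] = sorted(set(v.junctions), key=lambda j: angle_at(v.id, j))

    # a vertex with fewer than 3 registered junctions near the border
    # lost an arm to clipping; faces through it would close around a
    # truncated polygon.  Interior degree-2 vertices (e.g. a micro-stub
    # absorbed into a four-fold cluster) are harmless pass-throughs.
    h, w = frame.shape
    suspect = set()
    for v in frame.vertices:
        if len(set(v.junctions)) >= 3:
            continue
        near_border = any(
            r <= 1 or r >= h - 2 or c <= 1 or c >= w - 2 for r, c in v.pixels
        )
        touches_border_junction = any(
            frame.junctions[j].border for j in v.junctions
        )
        if near_border or touches_border_junction:
            suspect.add(v.id)

    def next_directed(jid: int, arriving_at: int) -> tuple[int, int]:
        """From junction jid arriving at vertex, take the next junction
        in clockwise rotation; returns (junction, departing vertex)."""
        rot = rotation[arriving_at]
        i = rot.index(jid)
        nxt = rot[(i + 1) % len(rot)]
        return nxt, arriving_at

    visited: set[tuple[int, int]] = set()
    cells: list[FrameCell] = []
    for j0 in frame.junctions:
        if j0.border:
            continue
        for start_dir in (0, 1):
            key0 = (j0.id, start_dir)
            if key0 in visited:
                continue
            path: list[tuple[int, int]] = []
            jid, depart = j0.id, (j0.v1 if start_dir == 0 else j0.v2)
            ok = True
            while True:
                j = frame.junctions[jid]
                arrive = j.v2 if depart == j.v1 else j.v1
                key = (jid, 0 if depart == j.v1 else 1)
                if key in visited:
                    ok = False
                    break
                visited.add(key)
                path.append((jid, depart))
                if j.border or arrive < 0:
                    ok = False
                    break
                jid, depart = next_directed(jid, arrive)
                if (jid, depart) == (j0.id, j0.v1 if start_dir == 0 else j0.v2):
                    break
                if len(path) > 200:
                    ok = False
                    break
            if not ok or len(path) < 3:
                continue
            vids = [depart for _, depart in path]
            if any(v in suspect for v in vids):
                continue
            pts = np.array([vpos[v] for v in vids])
            # shoelace in (row, col); outer face has opposite sign
            r, c = pts[:, 0], pts[:, 1]
            area = 0.5 * float(
                np.dot(c, np.roll(r, -1)) - np.dot(np.roll(c, -1), r)
            )
            if area <= 0:
                continue
            perim = sum(frame.junctions[j].length_px for j, _ in path)
            cross = c * np.roll(r, -1) - np.roll(c, -1) * r
            cr = float(((r + np.roll(r, -1)) * cross).sum() / (6 * area))
            cc_ = float(((c + np.roll(c, -1)) * cross).sum() / (6 * area))
            cells.append(
                FrameCell(
                    id=len(cells),
                    junction_ids=[j for j, _ in path],
                    vertex_ids=vids,
                    centroid=(cr, cc_),
                    area=abs(area),
                    perimeter=perim,
                )
            )
    return cells
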