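"""Polygonal tissue mesh on a periodic (toroidal) box.

The mesh stores vertices, edges and cells explicitly.  Every edge is
interior (two incident cells); cell boundaries are stored as
counterclockwise vertex cycles.  Vertex/edge/cell counts are conserved
by the T1 flip operation, so all arrays are fixed-size after
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi, cKDTree

__all__ = [
    "Box",
    "Tissue",
    "T1Record",
    "TopologyError",
    "build_honeycomb",
    "build_voronoi",
    "tissue_from_cell_polygons",
]


class TopologyError(ValueError):
    """Raised when a mesh violates its structural invariants."""


@dataclass(frozen=True)
class Box:
    """Periodic rectangular domain with origin at the lower-left corner."""

    width: float
    height: float
    periodic: bool = True

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("box dimensions must be positive")

    @property
    def size(self) -> np.ndarray:
        return np.array([self.width, self.height])

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        """Map positions into [0, W) x [0, H)."""
        return np.mod(pos, self.size)

    def delta(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Minimum-image displacement b - a."""
        d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
        d -= self.size * np.round(d / self.size)
        return d


@dataclass
class T1Record:
    """Bookkeeping for one T1 flip: which cells lost/gained the edge."""

    edge_id: int
    quartet: tuple[int, int, int, int]
    losing: tuple[int, int]
    gaining: tuple[int, int]


class Tissue:
    """Vertex-model mesh: positions, edge connectivity, cell cycles.

    Parameters
    ----------
    positions : (V, 2) float array of vertex coordinates.
    edges : (E, 2) int array of vertex indices.
    edge_cells : (E, 2) int array, ``[cell_left, cell_right]`` where
        *left* is the cell on the left when traversing ``v1 -> v2``.
    cells : list of int lists, counterclockwise vertex cycles.
    box : periodic domain.
    preferred_areas : optional (F,) array of target areas.
    """

    def __init__(
        self,
        positions: np.ndarray,
        edges: np.ndarray,
        edge_cells: np.ndarray,
        cells: list[list[int]],
        box: Box,
        preferred_areas: np.ndarray | None = None,
    ) -> None:
        self.positions = np.asarray(positions, dtype=float).copy()
        self.edges = np.asarray(edges, dtype=np.int64).copy()
        self.edge_cells = np.asarray(edge_cells, dtype=np.int64).copy()
        self.cells = [list(map(int, c)) for c in cells]
        self.box = box
        if preferred_areas is None:
            preferred_areas = np.full(len(self.cells), np.nan)
        self.preferred_areas = np.asarray(preferred_areas, dtype=float).copy()
        self._topology_version = 0
        self._flat_cache: dict | None = None

    # ------------------------------------------------------------------
    # basic counts
    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def topology_version(self) -> int:
        return self._topology_version

    def copy(self) -> "Tissue":
        return Tissue(
            self.positions,
            self.edges,
            self.edge_cells,
            self.cells,
            self.box,
            self.preferred_areas,
        )

    # ------------------------------------------------------------------
    # geometry
    def edge_vectors(self) -> np.ndarray:
        """Minimum-image vectors v1 -> v2 for every edge."""
        p = self.positions
        return self.box.delta(p[self.edges[:, 0]], p[self.edges[:, 1]])

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.edge_vectors(), axis=1)

    def edge_length(self, edge_id: int) -> float:
        if not 0 <= edge_id < self.n_edges:
            raise KeyError(f"unknown edge id {edge_id}")
        v1, v2 = self.edges[edge_id]
        return float(
            np.linalg.norm(self.box.delta(self.positions[v1], self.positions[v2]))
        )

    def edge_midpoints(self) -> np.ndarray:
        p = self.positions
        a = p[self.edges[:, 0]]
        return self.box.wrap(a + 0.5 * self.box.delta(a, p[self.edges[:, 1]]))

    def unwrapped_cycle(self, cell_id: int) -> np.ndarray:
        """Cycle coordinates unwrapped by accumulating minimum-image steps."""
        cyc = self.cells[cell_id]
        p = self.positions[cyc]
        steps = self.box.delta(p[:-1], p[1:]) if len(p) > 1 else np.zeros((0, 2))
        return np.vstack([p[0], p[0] + np.cumsum(steps, axis=0)])

    def cell_area(self, cell_id: int) -> float:
        if not 0 <= cell_id < self.n_cells:
            raise KeyError(f"unknown cell id {cell_id}")
        return float(_shoelace(self.unwrapped_cycle(cell_id)))

    def cell_areas(self) -> np.ndarray:
        flat = self._flat()
        p = self.positions[flat["vid"]]
        # unwrap each cycle around its first vertex via cumulative min-image steps
        d = self.box.delta(p[flat["prev_in_run"]], p)
        d[flat["is_first"]] = 0.0
        xy = np.zeros_like(p)
        np.cumsum(d[:, 0], out=xy[:, 0])
        np.cumsum(d[:, 1], out=xy[:, 1])
        # subtract the running offset accumulated before each cycle start
        starts = flat["ptr"][:-1]
        base = xy[starts] - p[starts] - d[starts]
        xy -= np.repeat(base, flat["counts"], axis=0)
        nxt = flat["next"]
        cross = xy[:, 0] * xy[nxt, 1] - xy[nxt, 0] * xy[:, 1]
        return 0.5 * np.bincount(flat["cell"], weights=cross, minlength=self.n_cells)

    def cell_centroid(self, cell_id: int) -> np.ndarray:
        """Center of area (polygon centroid), wrapped into the box."""
        xy = self.unwrapped_cycle(cell_id)
        x, y = xy[:, 0], xy[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * cross.sum()
        cx = ((x + xn) * cross).sum() / (6 * a)
        cy = ((y + yn) * cross).sum() / (6 * a)
        return self.box.wrap(np.array([cx, cy]))

    def cell_sides(self) -> np.ndarray:
        return np.array([len(c) for c in self.cells])

    # ------------------------------------------------------------------
    # flattened cycle indexing (rebuilt lazily after topology changes)
    def _flat(self) -> dict:
        if self._flat_cache is not None and self._flat_cache["version"] == self._topology_version:
            return self._flat_cache
        counts = np.array([len(c) for c in self.cells], dtype=np.int64)
        ptr = np.concatenate([[0], np.cumsum(counts)])
        vid = np.fromiter(
            (v for c in self.cells for v in c), dtype=np.int64, count=ptr[-1]
        )
        cell = np.repeat(np.arange(self.n_cells), counts)
        idx = np.arange(ptr[-1])
        nxt = idx + 1
        prv = idx - 1
        for k in range(self.n_cells):
            nxt[ptr[k + 1] - 1] = ptr[k]
            prv[ptr[k]] = ptr[k + 1] - 1
        is_first = np.zeros(ptr[-1], dtype=bool)
        is_first[ptr[:-1]] = True
        prev_in_run = np.maximum(idx - 1, 0)
        self._flat_cache = {
            "version": self._topology_version,
            "vid": vid,
            "cell": cell,
            "next": nxt,
            "prev": prv,
            "ptr": ptr,
            "counts": counts,
            "is_first": is_first,
            "prev_in_run": prev_in_run,
        }
        return self._flat_cache

    def vertex_edges(self) -> list[list[int]]:
        """Edge ids incident to each vertex (cached per topology version)."""
        cache = getattr(self, "_incidence_cache", None)
        if cache is not None and cache[0] == self._topology_version:
            return cache[1]
        out: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for e, (a, b) in enumerate(self.edges):
            out[a].append(e)
            out[b].append(e)
        self._incidence_cache = (self._topology_version, out)
        return out

    def vertex_cells(self) -> list[list[int]]:
        """Cell ids whose cycle contains each vertex (cached)."""
        cache = getattr(self, "_vcell_cache", None)
        if cache is not None and cache[0] == self._topology_version:
            return cache[1]
        out: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for cid, cyc in enumerate(self.cells):
            for v in cyc:
                out[v].append(cid)
        self._vcell_cache = (self._topology_version, out)
        return out

    def vertex_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=np.int64)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    # ------------------------------------------------------------------
    # validation
    def validate_topology(self) -> list[str]:
        """Return a list of violation messages; empty means valid."""
        report: list[str] = []
        V, E, F = self.n_vertices, self.n_edges, self.n_cells
        if V - E + F != 0:
            report.append(f"Euler characteristic V-E+F = {V - E + F}, expected 0")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            report.append("self-loop edge present")
        if E and (self.edges.min() < 0 or self.edges.max() >= V):
            report.append("edge references unknown vertex")
        deg = self.vertex_degrees()
        bad = np.flatnonzero(deg != 3)
        if bad.size:
            report.append(f"{bad.size} vertices with degree != 3 (e.g. {bad[:5].tolist()})")
        sides = self.cell_sides()
        if np.any(sides < 3):
            report.append("cell with fewer than 3 sides")
        if sides.sum() != 2 * E:
            report.append(f"sum of cell sides {sides.sum()} != 2E = {2 * E}")
        # every directed edge of every cycle must exist exactly once
        directed: dict[tuple[int, int], int] = {}
        dup = False
        for cid, cyc in enumerate(self.cells):
            if len(set(cyc)) != len(cyc):
                report.append(f"cell {cid} repeats a vertex in its cycle")
            for i, a in enumerate(cyc):
                b = cyc[(i + 1) % len(cyc)]
                if (a, b) in directed:
                    dup = True
                directed[(a, b)] = cid
        if dup:
            report.append("directed edge shared by two cells (orientation clash)")
        for e, ((a, b), (cl, cr)) in enumerate(zip(self.edges, self.edge_cells)):
            if directed.get((a, b)) != cl or directed.get((b, a)) != cr:
                report.append(f"edge {e} left/right cells inconsistent with cycles")
                break
        if len(directed) != 2 * E and "orientation clash" not in " ".join(report):
            report.append("dangling edges or cycles not covering all edges")
        try:
            areas = self.cell_areas()
            if np.any(areas <= 0):
                report.append("non-positive cell area (orientation or crossing)")
            elif self.box.periodic and not np.isclose(
                areas.sum(), self.box.width * self.box.height, rtol=1e-9
            ):
                report.append(
                    f"cell areas sum {areas.sum():.9g} != box area "
                    f"{self.box.width * self.box.height:.9g}"
                )
        except Exception as exc:  # pragma: no cover - defensive
            report.append(f"area computation failed: {exc}")
        return report

    # ------------------------------------------------------------------
    # T1 flip
    def _third_cell_at(self, vertex: int, exclude: set[int]) -> int:
        for e, (a, b) in enumerate(self.edges):
            if vertex in (a, b):
                for c in self.edge_cells[e]:
                    if c not in exclude:
                        return int(c)
        raise TopologyError(f"no third cell at vertex {vertex}")

    def t1_flip(self, edge_id: int, new_length: float) -> T1Record:
        """Rewire ``edge_id`` across its quartet and place it at ~90 degrees.

        The two cells previously sharing the edge each lose one side; the
        two cells at its endpoints each gain one.  Counts of vertices,
        edges and cells are unchanged.
        """
        if not 0 <= edge_id < self.n_edges:
            raise KeyError(f"unknown edge id {edge_id}")
        va, vb = map(int, self.edges[edge_id])
        cl, cr = map(int, self.edge_cells[edge_id])
        if len(self.cells[cl]) <= 3 or len(self.cells[cr]) <= 3:
            raise TopologyError(
                f"t1_flip refused on edge {edge_id}: adjacent cell has 3 sides"
            )
        # third cells at each endpoint (the quartet's end cells)
        cp = self._third_cell_at(va, {cl, cr})
        cq = self._third_cell_at(vb, {cl, cr})

        # outer edges that swap endpoints: at va the edge bordering cr moves
        # to vb; at vb the edge bordering cl moves to va
        move_a = move_b = -1
        for e, (x, y) in enumerate(self.edges):
            if e == edge_id:
                continue
            if va in (x, y) and cr in self.edge_cells[e]:
                move_a = e
            if vb in (x, y) and cl in self.edge_cells[e]:
                move_b = e
        if move_a < 0 or move_b < 0:
            raise TopologyError("quartet edges not found; mesh inconsistent")
        self.edges[move_a][self.edges[move_a] == va] = vb
        self.edges[move_b][self.edges[move_b] == vb] = va

        # reposition: new edge perpendicular to the old one through its midpoint
        pa, pb = self.positions[va], self.positions[vb]
        d = self.box.delta(pa, pb)
        norm = np.linalg.norm(d)
        if norm > 1e-9:
            n = np.array([-d[1], d[0]]) / norm  # +90deg: points into cell_left
        else:  # degenerate four-way vertex: open along the losing-cell axis
            axis = self.box.delta(self.cell_centroid(cr), self.cell_centroid(cl))
            n = axis / max(np.linalg.norm(axis), 1e-12)
        mid = self.box.wrap(pa + 0.5 * self.box.delta(pa, pb))
        self.positions[va] = self.box.wrap(mid + 0.5 * new_length * n)
        self.positions[vb] = self.box.wrap(mid - 0.5 * new_length * n)

        # update cycles: losing cells drop one endpoint, gaining cells pick
        # up the other endpoint adjacent to the one they already hold
        self.cells[cl].remove(vb)
        self.cells[cr].remove(va)
        i = self.cells[cp].index(va)
        self.cells[cp].insert(i, vb)  # b precedes a in cp's cycle
        j = self.cells[cq].index(vb)
        self.cells[cq].insert(j, va)  # a precedes b in cq's cycle
        # new edge separates cq (left of a->b) from cp
        self.edge_cells[edge_id] = (cq, cp)
        self._topology_version += 1
        self._flat_cache = None
        return T1Record(
            edge_id=edge_id,
            quartet=(cl, cr, cp, cq),
            losing=(min(cl, cr), max(cl, cr)),
            gaining=(min(cp, cq), max(cp, cq)),
        )

    # ------------------------------------------------------------------
    # serialization: three flat tables
    def to_tables(self):
        import pandas as pd

        verts = pd.DataFrame(
            {
                "id": np.arange(self.n_vertices),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
            }
        )
        edges = pd.DataFrame(
            {
                "id": np.arange(self.n_edges),
                "v1": self.edges[:, 0],
                "v2": self.edges[:, 1],
                "cell_left": self.edge_cells[:, 0],
                "cell_right": self.edge_cells[:, 1],
            }
        )
        cells = pd.DataFrame(
            {
                "id": np.arange(self.n_cells),
                "vertex_cycle": [" ".join(map(str, c)) for c in self.cells],
                "preferred_area": self.preferred_areas,
            }
        )
        return verts, edges, cells

    @classmethod
    def from_tables(cls, verts, edges, cells, box: Box) -> "Tissue":
        pos = np.column_stack([verts["x"].to_numpy(), verts["y"].to_numpy()])
        e = np.column_stack([edges["v1"].to_numpy(), edges["v2"].to_numpy()])
        ec = np.column_stack(
            [edges["cell_left"].to_numpy(), edges["cell_right"].to_numpy()]
        )
        cyc = [list(map(int, s.split())) for s in cells["vertex_cycle"]]
        return cls(pos, e, ec, cyc, box, cells["preferred_area"].to_numpy())


# ----------------------------------------------------------------------
# construction helpers

def _shoelace(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def tissue_from_cell_polygons(
    polygons: list[np.ndarray],
    box: Box,
    merge_tol: float = 1e-6,
    split_len: float = 1e-3,
) -> Tissue:
    """Build a periodic mesh from per-cell corner polygons.

    Corners within ``merge_tol`` (minimum-image) are fused into shared
    vertices; vertices incident to four cells (degenerate, e.g. from a
    cocircular Voronoi input) are split into two degree-3 vertices
    separated by ``split_len``.
    """
    all_pts = []
    all_orig = []
    for cid, poly in enumerate(polygons):
        poly = np.asarray(poly, dtype=float)
        if len(poly) < 3:
            raise TopologyError(f"cell {cid} has fewer than 3 corners")
        if _shoelace(poly) < 0:
            poly = poly[::-1]
        all_pts.append(box.wrap(poly))
        all_orig.append(poly)
    pts = np.vstack(all_pts)

    tree = cKDTree(pts, boxsize=(box.width, box.height))
    pairs = tree.query_pairs(merge_tol, output_type="ndarray")
    parent = np.arange(len(pts))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(len(pts))])
    uniq, inverse = np.unique(roots, return_inverse=True)
    positions = np.array(
        [
            box.wrap(pts[r] + box.delta(pts[r], pts[roots == r]).mean(axis=0))
            for r in uniq
        ]
    )

    cycles: list[list[int]] = []
    origs: list[list[np.ndarray]] = []
    k = 0
    for poly, orig in zip(all_pts, all_orig):
        n = len(poly)
        cyc = [int(inverse[k + i]) for i in range(n)]
        k += n
        dedup, odedup = [], []
        for i, v in enumerate(cyc):
            if v != cyc[(i - 1) % len(cyc)]:
                dedup.append(v)
                odedup.append(orig[i])
        cycles.append(dedup)
        origs.append(odedup)

    positions, cycles = _split_degenerate_vertices(
        positions, cycles, origs, box, split_len
    )
    return _mesh_from_cycles(positions, cycles, box)


def _split_degenerate_vertices(positions, cycles, origs, box: Box, split_len: float):
    """Resolve vertices shared by 4 cells into two degree-3 vertices.

    Local directions are taken from the original (unwrapped) polygon
    corners, which stay geometrically faithful even when cells span a
    large fraction of the box.
    """
    incident: dict[int, list[int]] = {}
    for cid, cyc in enumerate(cycles):
        for v in cyc:
            incident.setdefault(v, []).append(cid)
    positions = list(positions)

    def _wedge_bisector(cid: int, v: int) -> np.ndarray:
        """Unit vector from corner v into the interior wedge of cell cid."""
        cyc, orig = cycles[cid], origs[cid]
        i = cyc.index(v)
        p, pp, pn = orig[i], orig[i - 1], orig[(i + 1) % len(cyc)]
        u1 = pp - p
        u2 = pn - p
        u1 = u1 / np.linalg.norm(u1)
        u2 = u2 / np.linalg.norm(u2)
        b = u1 + u2
        nrm = np.linalg.norm(b)
        if nrm < 1e-12:  # collinear wedge: rotate one arm by 90deg
            b = np.array([-u2[1], u2[0]])
            nrm = 1.0
        return b / nrm

    for v in sorted(incident):
        cids = incident[v]
        if len(cids) <= 3:
            continue
        if len(cids) > 4:
            raise TopologyError(
                f"vertex shared by {len(cids)} cells; cannot resolve automatically"
            )
        pv = positions[v]
        bis = {cid: _wedge_bisector(cid, v) for cid in cids}
        order = sorted(cids, key=lambda c: np.arctan2(bis[c][1], bis[c][0]))
        # the new edge separates an opposite pair; pick the pair holding
        # the smallest cell id (deterministic tie-break)
        if min(order[0], order[2]) < min(order[1], order[3]):
            order = order[1:] + order[:1]
        side1, end_a, side2, end_b = order
        va = v
        vb = len(positions)
        positions[va] = box.wrap(pv + 0.5 * split_len * bis[end_a])
        positions.append(box.wrap(pv + 0.5 * split_len * bis[end_b]))
        # end cell toward vb swaps its copy of the vertex
        i2 = cycles[end_b].index(v)
        cycles[end_b][i2] = vb
        # side cells keep va and gain vb next to it, on the side whose
        # boundary arm points toward end_b's wedge
        for cid in (side1, side2):
            cyc, orig = cycles[cid], origs[cid]
            i = cyc.index(v)
            p, pp, pn = orig[i], orig[i - 1], orig[(i + 1) % len(cyc)]
            d_prev = (pp - p) / np.linalg.norm(pp - p)
            d_next = (pn - p) / np.linalg.norm(pn - p)
            if np.dot(d_next, bis[end_b]) > np.dot(d_prev, bis[end_b]):
                cyc.insert(i + 1, vb)
                orig.insert(i + 1, p)
            else:
                cyc.insert(i, vb)
                orig.insert(i, p)
    return np.asarray(positions), cycles


def _mesh_from_cycles(positions: np.ndarray, cycles: list[list[int]], box: Box) -> Tissue:
    directed: dict[tuple[int, int], int] = {}
    for cid, cyc in enumerate(cycles):
        for i, a in enumerate(cyc):
            b = cyc[(i + 1) % len(cyc)]
            if (a, b) in directed:
                raise TopologyError(
                    f"directed edge {(a, b)} claimed by cells "
                    f"{directed[(a, b)]} and {cid}"
                )
            directed[(a, b)] = cid
    edges = []
    edge_cells = []
    seen = set()
    for (a, b), cl in sorted(directed.items()):
        if (b, a) in seen or (a, b) in seen:
            continue
        if (b, a) not in directed:
            raise TopologyError(f"edge {(a, b)} has only one incident cell")
        seen.add((a, b))
        seen.add((b, a))
        edges.append((a, b))
        edge_cells.append((cl, directed[(b, a)]))
    return Tissue(positions, np.array(edges), np.array(edge_cells), cycles, box)


def build_honeycomb(nx: int, ny: int, side: float = 1.0) -> Tissue:
    """Regular hexagonal packing of ``nx * ny`` cells on a periodic box."""
    if nx < 2 or ny < 2:
        raise ValueError("honeycomb requires nx, ny >= 2")
    if ny % 2:
        raise ValueError("honeycomb requires even ny for periodic closure")
    if side <= 0:
        raise ValueError("side must be positive")
    w = np.sqrt(3.0) * side
    box = Box(nx * w, ny * 1.5 * side)
    # pointy-top hexagon corners, counterclockwise
    corners = np.array(
        [
            [0.0, side],
            [-w / 2, side / 2],
            [-w / 2, -side / 2],
            [0.0, -side],
            [w / 2, -side / 2],
            [w / 2, side / 2],
        ]
    )[::-1]
    polys = []
    for j in range(ny):
        for i in range(nx):
            cx = i * w + (w / 2 if j % 2 else 0.0)
            cy = j * 1.5 * side + side
            polys.append(corners + [cx, cy])
    return tissue_from_cell_polygons(polys, box, merge_tol=1e-6 * side)


def build_voronoi(n_cells: int, seed: int, box: Box) -> Tissue:
    """Periodic Voronoi tessellation of uniformly random points."""
    if n_cells < 4:
        raise ValueError("build_voronoi requires n_cells >= 4")
    rng = np.random.default_rng(seed)
    for _attempt in range(10):
        pts = rng.uniform([0, 0], [box.width, box.height], size=(n_cells, 2))
        if len(np.unique(np.round(pts, 9), axis=0)) == n_cells:
            break
    else:  # pragma: no cover
        raise ValueError("could not draw distinct seed points")
    return voronoi_tissue(pts, box)


def voronoi_tissue(points: np.ndarray, box: Box) -> Tissue:
    """Periodic Voronoi mesh for the given generator points."""
    points = box.wrap(np.asarray(points, dtype=float))
    n = len(points)
    shifts = np.array(
        [[i, j] for i in (-1, 0, 1) for j in (-1, 0, 1)]
    ) * box.size
    tiled = np.vstack([points + s for s in shifts])
    vor = Voronoi(tiled)
    center_offset = 4 * n  # shift (0,0) is the 5th block
    polys = []
    for k in range(n):
        region = vor.regions[vor.point_region[center_offset + k]]
        if -1 in region or len(region) < 3:
            raise TopologyError("unbounded Voronoi region in central tile")
        polys.append(vor.vertices[region])
    scale = min(box.width, box.height)
    return tissue_from_cell_polygons(polys, box, merge_tol=1e-7 * scale)
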