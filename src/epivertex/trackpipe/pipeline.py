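"""End-to-end analysis: skeleton stacks -> parsed frames -> drift
correction -> tracked junctions and cells -> track tables and events."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cells import detect_cells, FrameCell
from .intensity import measure_frame_intensity
from .skeleton import FrameGraph, parse_skeleton
from .tracking import DEFAULT_CUTOFF_PX, register_drift, track_points

__all__ = ["AnalyzedMovie", "analyze_stack", "junction_frames_for_events"]


@dataclass
class AnalyzedMovie:
    """All per-frame and tracked objects extracted from one movie."""

    frames: list[FrameGraph]
    cells: list[list[FrameCell]]
    drift: np.ndarray  # (T, 2) cumulative (row, col) offsets
    junction_tracks: list  # Track: frame -> junction index in frame
    cell_tracks: list  # Track: frame -> cell index in frame
    px_size_um: float = 1.0
    frame_interval_min: float = 0.5
    intensity: list[dict[int, float]] | None = None  # per frame: jid -> value

    def junction_table(self) -> pd.DataFrame:
        """Long-format table: one row per (junction track, frame)."""
        rows = []
        for tr in self.junction_tracks:
            for f, idx in sorted(tr.obs.items()):
                j = self.frames[f].junctions[idx]
                if j.border:
                    continue
                p1 = self.frames[f].vertices[j.v1].pos
                p2 = self.frames[f].vertices[j.v2].pos
                off = self.drift[f]
                ang = np.degrees(
                    np.arctan2(p2[0] - p1[0], p2[1] - p1[1])
                )
                inten = np.nan
                if self.intensity is not None:
                    inten = self.intensity[f].get(j.id, np.nan)
                rows.append(
                    {
                        "junction_id": tr.id,
                        "frame": f,
                        "x1": p1[1] - off[1],
                        "y1": p1[0] - off[0],
                        "x2": p2[1] - off[1],
                        "y2": p2[0] - off[0],
                        "length_um": j.length_px * self.px_size_um,
                        "length_px": j.length_px,
                        "angle_deg": ang,
                        "intensity_norm": inten,
                    }
                )
        return pd.DataFrame(rows)

    def length_series(self) -> dict[int, np.ndarray]:
        """Junction track id -> length series (px) over all frames, NaN
        where the track is absent."""
        T = len(self.frames)
        out: dict[int, np.ndarray] = {}
        for tr in self.junction_tracks:
            x = np.full(T, np.nan)
            for f, idx in tr.obs.items():
                x[f] = self.frames[f].junctions[idx].length_px
            out[tr.id] = x
        return out

    def intensity_series(self) -> dict[int, np.ndarray]:
        if self.intensity is None:
            raise ValueError("no intensity channel was measured")
        T = len(self.frames)
        out: dict[int, np.ndarray] = {}
        for tr in self.junction_tracks:
            x = np.full(T, np.nan)
            for f, idx in tr.obs.items():
                jid = self.frames[f].junctions[idx].id
                x[f] = self.intensity[f].get(jid, np.nan)
            out[tr.id] = x
        return out


def analyze_stack(
    skeleton_stack: np.ndarray,
    intensity_stack: np.ndarray | None = None,
    px_size_um: float = 1.0,
    frame_interval_min: float = 0.5,
    cutoff_px: float = DEFAULT_CUTOFF_PX,
    translations: np.ndarray | None = None,
    intensity_width_px: int = 7,
) -> AnalyzedMovie:
    """Run the full chain on a skeleton stack (T, H, W)."""
    frames = [parse_skeleton(im) for im in skeleton_stack]
    cells = [detect_cells(fr) for fr in frames]
    drift = register_drift(frames=skeleton_stack, translations=translations)

    jun_pts = []
    for f, fr in enumerate(frames):
        pts = np.array(
            [j.midpoint for j in fr.junctions], dtype=float
        ) if fr.junctions else np.empty((0, 2))
        jun_pts.append(pts - drift[f] if len(pts) else pts)
    junction_tracks = track_points(jun_pts, cutoff_px)

    cell_pts = []
    for f, cc in enumerate(cells):
        pts = np.array([c.centroid for c in cc], dtype=float) if cc else np.empty((0, 2))
        cell_pts.append(pts - drift[f] if len(pts) else pts)
    # cells move little but can drop out for many frames while an
    # adjacent junction sits at a four-fold vertex: long memory
    cell_tracks = track_points(cell_pts, cutoff_px, memory=12)

    intensity = None
    if intensity_stack is not None:
        intensity = [
            measure_frame_intensity(fr, im, width_px=intensity_width_px)
            for fr, im in zip(frames, intensity_stack)
        ]
    return AnalyzedMovie(
        frames=frames,
        cells=cells,
        drift=drift,
        junction_tracks=junction_tracks,
        cell_tracks=cell_tracks,
        px_size_um=px_size_um,
        frame_interval_min=frame_interval_min,
        intensity=intensity,
    )


def junction_frames_for_events(movie: AnalyzedMovie) -> list[dict]:
    """Assemble the per-track records consumed by
    :func:`epivertex.trackpipe.events.detect_t1_events`, with side and
    end cells expressed as persistent cell-track ids."""
    # per frame: junction index -> side cell track ids / vertex -> cells
    cell_track_of: list[dict[int, int]] = []
    for f in range(len(movie.frames)):
        m: dict[int, int] = {}
        cell_track_of.append(m)
    for tr in movie.cell_tracks:
        for f, idx in tr.obs.items():
            cell_track_of[f][idx] = tr.id

    side_cells: list[dict[int, list[int]]] = []
    vertex_cells: list[dict[int, list[int]]] = []
    for f, cc in enumerate(movie.cells):
        sc: dict[int, list[int]] = {}
        vc: dict[int, list[int]] = {}
        for ci, cell in enumerate(cc):
            ct = cell_track_of[f].get(ci)
            if ct is None:
                continue
            for jid in cell.junction_ids:
                sc.setdefault(jid, []).append(ct)
            for vid in cell.vertex_ids:
                vc.setdefault(vid, []).append(ct)
        side_cells.append(sc)
        vertex_cells.append(vc)

    out: list[dict] = []
    for tr in movie.junction_tracks:
        frames_list, lengths, mids, sides, ends = [], [], [], [], []
        for f in sorted(tr.obs):
            idx = tr.obs[f]
            j = movie.frames[f].junctions[idx]
            if j.border:
                continue
            sc = side_cells[f].get(j.id, [])
            if len(sc) != 2:
                continue
            ec = []
            for v in (j.v1, j.v2):
                cand = [c for c in vertex_cells[f].get(v, []) if c not in sc]
                ec.append(cand[0] if len(cand) == 1 else -1)
            frames_list.append(f)
            lengths.append(j.length_px)
            mids.append(tuple(np.asarray(j.midpoint) - movie.drift[f]))
            sides.append(tuple(sorted(sc)))
            ends.append(tuple(sorted(ec)))
        if frames_list:
            out.append(
                {
                    "track_id": tr.id,
                    "frames": frames_list,
                    "length": lengths,
                    "midpoint": mids,
                    "side_cells": sides,
                    "end_cells": ends,
                }
            )
    return out
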