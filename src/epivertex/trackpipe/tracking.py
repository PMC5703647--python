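"""Frame-to-frame identity assignment and drift registration.

Midpoints at time t are matched to midpoints at t+1 by minimizing the
total squared displacement (Hungarian assignment) subject to a maximum
displacement cutoff; unmatched objects end/start tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.registration import phase_cross_correlation

__all__ = ["match_points", "Track", "track_points", "register_drift"]

DEFAULT_CUTOFF_PX = 10.0


def match_points(
    a: np.ndarray, b: np.ndarray, cutoff: float = DEFAULT_CUTOFF_PX
) -> list[tuple[int, int]]:
    """Optimal pairing of point sets ``a`` (t) and ``b`` (t+1).

    Returns index pairs (i, j) with displacement below ``cutoff``; the
    assignment minimizes the total squared displacement among feasible
    pairings, with unmatched points allowed at cost ``cutoff**2``.
    Ties are resolved toward lower indices.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return []
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    big = cutoff**2
    # square cost matrix with dummy rows/cols for births and deaths
    size = n + m
    cost = np.full((size, size), big)
    cost[:n, :m] = np.minimum(d2, big + 1.0)
    # deterministic tie-break: tiny preference for low-index pairs
    eps = 1e-9 / (size * size)
    cost[:n, :m] += eps * (np.arange(n)[:, None] * m + np.arange(m)[None, :])
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n and j < m and d2[i, j] < big
    ]


@dataclass
class Track:
    """Persistent identity across frames: frame index -> object index."""

    id: int
    obs: dict[int, int] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return min(self.obs)

    @property
    def end(self) -> int:
        return max(self.obs)

    def frames(self) -> list[int]:
        return sorted(self.obs)


def track_points(
    per_frame_points: list[np.ndarray],
    cutoff: float = DEFAULT_CUTOFF_PX,
    memory: int = 3,
) -> list[Track]:
    """Link per-frame point sets into tracks with unique persistent ids.

    Tracks unmatched for up to ``memory`` consecutive frames stay open
    at their last position and can be re-linked (bridging brief
    detection dropouts)."""
    tracks: list[Track] = []
    # open tracks: (track, last position, frames since last seen)
    open_tracks: list[list] = []
    for f, pts in enumerate(per_frame_points):
        pts = (
            np.atleast_2d(np.asarray(pts, dtype=float))
            if len(pts)
            else np.empty((0, 2))
        )
        if open_tracks:
            anchors = np.array([ot[1] for ot in open_tracks])
            pairs = match_points(anchors, pts, cutoff)
        else:
            pairs = []
        matched_a, matched_b = set(), set()
        for i, j in pairs:
            tr = open_tracks[i][0]
            tr.obs[f] = j
            open_tracks[i][1] = pts[j]
            open_tracks[i][2] = 0
            matched_a.add(i)
            matched_b.add(j)
        survivors = []
        for i, ot in enumerate(open_tracks):
            if i in matched_a:
                survivors.append(ot)
            else:
                ot[2] += 1
                if ot[2] <= memory:
                    survivors.append(ot)
        open_tracks = survivors
        for j in range(len(pts)):
            if j not in matched_b:
                tr = Track(id=len(tracks), obs={f: j})
                tracks.append(tr)
                open_tracks.append([tr, pts[j], 0])
    return tracks


def register_drift(
    frames: np.ndarray | None = None,
    translations: np.ndarray | None = None,
) -> np.ndarray:
    """Cumulative per-frame translation offsets (row, col).

    Either explicit per-frame ``translations`` (T-1, 2) are accumulated,
    or whole-frame translations are estimated by phase correlation of
    consecutive frames.  Subtracting the returned offsets from image
    coordinates stabilizes the movie.
    """
    if translations is None:
        if frames is None:
            raise ValueError("need frames or translations")
        translations = []
        for k in range(len(frames) - 1):
            shift, _, _ = phase_cross_correlation(
                frames[k].astype(float), frames[k + 1].astype(float),
                normalization=None,
            )
            # shift maps frame k+1 onto frame k; the tissue moved by -shift
            translations.append(-shift)
        translations = np.array(translations) if translations else np.empty((0, 2))
        if frames is not None and len(translations):
            span = np.abs(translations).max(axis=0)
            h, w = frames[0].shape
            if span[0] > 0.2 * h or span[1] > 0.2 * w:
                import warnings

                warnings.warn("estimated translation exceeds 20% of the frame")
    translations = np.asarray(translations, dtype=float)
    offsets = np.vstack([[0.0, 0.0], np.cumsum(translations, axis=0)])
    return offsets
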