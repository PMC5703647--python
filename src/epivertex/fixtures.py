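"""Ground-truth generators: calibrated stochastic intensity traces and
rasterized skeleton/intensity movies from simulated tissues.

Every generator is deterministic given its seed and carries
machine-readable ground truth, so the image-analysis pipeline can be
tested end to end without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import line as draw_line
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .dynamics import SimResult

__all__ = ["TraceConfig", "RasterConfig", "synth_traces", "rasterize_movie"]


@dataclass
class TraceConfig:
    """Observation design for synthetic per-junction intensity traces.

    Defaults mirror the wild-type calibration: 333 junctions observed
    for 120 frames at 30 s, junction-to-junction (extrinsic) CoV 0.13,
    temporal (intrinsic) CoV 0.08, persistence time 2.2 min.
    """

    n_junctions: int = 333
    n_frames: int = 120
    frame_interval: float = 0.5  # min
    cov_extrinsic: float = 0.13
    cov_intrinsic: float = 0.08
    persistence_time: float = 2.2  # min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cov_extrinsic < 0 or self.cov_intrinsic < 0:
            raise ValueError("CoVs must be nonnegative")
        if self.persistence_time <= 0:
            raise ValueError("persistence time must be positive")
        if self.n_junctions < 1 or self.n_frames < 1:
            raise ValueError("need at least one junction and one frame")


def synth_traces(config: TraceConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthesize stationary per-junction intensity traces.

    Per junction: a mean level drawn from a normal with the extrinsic
    CoV truncated at 0 (unit grand mean), plus an exactly-discretized
    stationary OU fluctuation with the intrinsic CoV and persistence
    time, sampled on the frame grid.

    Returns ``(traces, ground_truth)`` where traces has shape
    ``(n_junctions, n_frames)``.
    """
    rng = np.random.default_rng(config.seed)
    n, t = config.n_junctions, config.n_frames
    mu = rng.normal(1.0, config.cov_extrinsic, size=n)
    while np.any(mu <= 0):  # truncate at 0 by redraw
        bad = mu <= 0
        mu[bad] = rng.normal(1.0, config.cov_extrinsic, size=bad.sum())
    sigma = config.cov_intrinsic * mu

    rho = np.exp(-config.frame_interval / config.persistence_time)
    innov = np.sqrt(1.0 - rho**2)
    traces = np.empty((n, t))
    x = rng.standard_normal(n)  # stationary start, unit variance
    traces[:, 0] = mu + sigma * x
    for k in range(1, t):
        x = rho * x + innov * rng.standard_normal(n)
        traces[:, k] = mu + sigma * x
    gt = pd.DataFrame(
        {
            "junction_id": np.arange(n),
            "mean_level": mu,
            "temporal_sd": sigma,
            "persistence_time": config.persistence_time,
        }
    )
    return traces, gt


# ----------------------------------------------------------------------
# rasterization


@dataclass
class RasterConfig:
    """How to turn a simulated trajectory into 8-bit image stacks."""

    px_per_l: float = 25.0
    frame_interval: float = 0.5  # min (must divide the trajectory grid)
    drift_per_frame: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px
    intensity_gain: float = 1.0  # intensity per tension unit
    vertex_brightness: float = 1.5
    noise_sd: float = 0.0
    bleaching_rate: float = 0.0  # per frame, in [0, 0.05]
    junction_width: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.px_per_l < 10:
            raise ValueError(
                "px_per_l < 10: junctions would not be separable in the raster"
            )
        if not 0 <= self.bleaching_rate <= 0.05:
            raise ValueError("bleaching rate must lie in [0, 0.05]")


@dataclass
class RasterMovie:
    """Rasterized trajectory plus per-frame ground truth."""

    skeleton: np.ndarray  # (T, H, W) uint8
    intensity: np.ndarray  # (T, H, W) uint8
    ground_truth: pd.DataFrame  # per frame & junction
    events: pd.DataFrame  # simulator event log in pixel space
    px_per_l: float
    frame_times: np.ndarray
    drift: np.ndarray  # (T, 2) cumulative (dx, dy) px


def _sim_to_px(xy: np.ndarray, box_h: float, scale: float, h_px: int):
    """Simulation coords (origin bottom-left) -> (row, col) pixels
    (origin top-left)."""
    col = np.asarray(xy)[..., 0] * scale
    row = (box_h - np.asarray(xy)[..., 1]) * scale
    return row, col


def rasterize_movie(result: SimResult, config: RasterConfig) -> RasterMovie:
    """Draw each recorded frame of a simulation as a 1-px skeleton image
    and a matching intensity image with brightness proportional to the
    instantaneous tension.

    Edges crossing the periodic box boundary are drawn clipped at the
    image border (from both endpoints, so each side keeps its stub);
    the parser border-flags them, mirroring how real movies end at the
    field of view.
    """
    if result.frame_tissues is None:
        raise ValueError("rasterize_movie needs a run with keep_tissues=True")
    rng = np.random.default_rng(config.seed)
    scale = config.px_per_l
    box = result.frame_tissues[0].box
    h_px = int(round(box.height * scale))
    w_px = int(round(box.width * scale))
    n_frames = len(result.frame_tissues)

    skel = np.zeros((n_frames, h_px, w_px), dtype=np.uint8)
    inten = np.zeros((n_frames, h_px, w_px), dtype=float)
    gt_rows = []
    selem = disk(config.junction_width // 2)
    drift = np.cumsum(
        np.tile(np.asarray(config.drift_per_frame, float), (n_frames, 1)), axis=0
    ) - np.asarray(config.drift_per_frame, float)

    def _clipped_line(r1, c1, r2, c2):
        rr, cc = draw_line(
            int(round(r1)), int(round(c1)), int(round(r2)), int(round(c2))
        )
        keep = (rr >= 0) & (rr < h_px) & (cc >= 0) & (cc < w_px)
        return rr[keep], cc[keep]

    for f, tissue in enumerate(result.frame_tissues):
        tension = result.tensions[f]
        dcol, drow = drift[f][0], -drift[f][1]
        for e in range(tissue.n_edges):
            v1, v2 = tissue.edges[e]
            p1 = tissue.positions[v1]
            delta = tissue.box.delta(p1, tissue.positions[v2])
            p2w = tissue.positions[v2]
            # draw from both endpoints, clipping at the border, so a
            # boundary-crossing edge leaves a stub on each side
            pixels = []
            for a, b in ((p1, p1 + delta), (p2w - delta, p2w)):
                ra, ca = _sim_to_px(a, box.height, scale, h_px)
                rb, cb = _sim_to_px(b, box.height, scale, h_px)
                pixels.append(
                    _clipped_line(ra + drow, ca + dcol, rb + drow, cb + dcol)
                )
            rr = np.concatenate([p[0] for p in pixels])
            cc = np.concatenate([p[1] for p in pixels])
            if rr.size:
                skel[f, rr, cc] = 255
                mask = np.zeros((h_px, w_px), dtype=bool)
                mask[rr, cc] = True
                mask = binary_dilation(mask, structure=selem)
                inten[f][mask] += config.intensity_gain * tension[e]
            mr, mc = _sim_to_px(
                tissue.box.wrap(p1 + 0.5 * tissue.box.delta(p1, tissue.positions[v2])),
                box.height, scale, h_px,
            )
            gt_rows.append(
                {
                    "frame": f,
                    "junction_id": e,
                    "length_px": float(np.linalg.norm(
                        tissue.box.delta(p1, tissue.positions[v2])) * scale),
                    "tension": float(tension[e]),
                    "mid_row": float((mr + drow) % h_px),
                    "mid_col": float((mc + dcol) % w_px),
                }
            )
        # brighter vertices
        vr, vc = _sim_to_px(tissue.positions, box.height, scale, h_px)
        vr = np.clip(np.round(vr + drow).astype(int), 0, h_px - 1)
        vc = np.clip(np.round(vc + dcol).astype(int), 0, w_px - 1)
        vmask = np.zeros((h_px, w_px), dtype=bool)
        vmask[vr, vc] = True
        vmask = binary_dilation(vmask, structure=selem)
        inten[f][vmask] *= config.vertex_brightness
        inten[f] *= np.exp(-config.bleaching_rate * f)
        if config.noise_sd > 0:
            inten[f] += rng.normal(0.0, config.noise_sd, size=(h_px, w_px))

    # scale the whole stack into 8 bits with one global factor
    top = inten.max()
    if top > 0:
        inten = inten * (255.0 / top)
    inten8 = np.clip(np.round(inten), 0, 255).astype(np.uint8)

    frame_times = result.times[:n_frames]
    ev_rows = []
    for ev in result.events:
        f = int(np.argmin(np.abs(frame_times - ev.time)))
        ev_rows.append(
            {
                "event_id": ev.event_id,
                "time_min": ev.time,
                "frame": f,
                "edge_id": ev.edge_id,
                "losing_1": ev.losing[0],
                "losing_2": ev.losing[1],
                "gaining_1": ev.gaining[0],
                "gaining_2": ev.gaining[1],
                "reversal_of": -1 if ev.reversal_of is None else ev.reversal_of,
            }
        )
    return RasterMovie(
        skeleton=skel,
        intensity=inten8,
        ground_truth=pd.DataFrame(gt_rows),
        events=pd.DataFrame(
            ev_rows,
            columns=[
                "event_id", "time_min", "frame", "edge_id",
                "losing_1", "losing_2", "gaining_1", "gaining_2", "reversal_of",
            ],
        ),
        px_per_l=scale,
        frame_times=frame_times,
        drift=drift,
    )
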