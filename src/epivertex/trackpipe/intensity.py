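"""Junction intensity measurement with bleaching normalization.

Each junction chain is dilated to a target width, disks around vertices
are excluded (vertices are bright and shared between junctions), pixel
intensities are summed, normalized so the average intensity per pixel
over all dilated junction pixels equals 1 in every frame, and divided by
the junction's pixel count."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .skeleton import FrameGraph

__all__ = ["measure_frame_intensity"]


def measure_frame_intensity(
    frame: FrameGraph,
    image: np.ndarray,
    width_px: int = 7,
) -> dict[int, float]:
    """Normalized average intensity per junction for one frame.

    Returns junction id -> value; junctions fully inside vertex
    exclusion zones map to NaN.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    selem = disk(width_px // 2)

    vertex_zone = np.zeros((h, w), dtype=bool)
    for v in frame.vertices:
        r, c = int(round(v.pos[0])), int(round(v.pos[1]))
        vertex_zone[max(r, 0) : r + 1, max(c, 0) : c + 1] = True
    vertex_zone = binary_dilation(vertex_zone, structure=selem)

    masks: dict[int, np.ndarray] = {}
    union = np.zeros((h, w), dtype=bool)
    for j in frame.junctions:
        if not j.chain:
            continue
        m = np.zeros((h, w), dtype=bool)
        rr, cc = zip(*j.chain)
        m[list(rr), list(cc)] = True
        m = binary_dilation(m, structure=selem) & ~vertex_zone
        masks[j.id] = m
        union |= m

    n_px = int(union.sum())
    if n_px == 0:
        return {j.id: np.nan for j in frame.junctions}
    frame_factor = img[union].sum() / n_px  # mean per-pixel intensity

    out: dict[int, float] = {}
    for j in frame.junctions:
        m = masks.get(j.id)
        if m is None or not m.any() or frame_factor == 0:
            out[j.id] = np.nan
            continue
        total = img[m].sum() / frame_factor
        out[j.id] = float(total / m.sum())
    return out
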