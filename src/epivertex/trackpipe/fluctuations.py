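"""Persistence segmentation of junction length series.

A hysteresis filter suppresses reversals whose peak-to-trough amplitude
is below a threshold; the surviving turning points delimit maximal
monotone contraction/expansion segments."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PersistenceSegment", "persistence_segments", "ballistic_velocity"]


@dataclass
class PersistenceSegment:
    junction_id: int
    start_frame: int
    end_frame: int
    delta_length: float  # signed
    duration: float  # min
    sign: str  # 'contraction' | 'expansion'

    @property
    def velocity(self) -> float:
        """Ballistic velocity |delta|/duration."""
        return abs(self.delta_length) / self.duration


def _turning_points(x: np.ndarray) -> list[int]:
    """Indices of strict local extrema plus both endpoints."""
    tp = [0]
    direction = 0
    for i in range(1, len(x)):
        d = np.sign(x[i] - x[i - 1])
        if d == 0:
            continue
        if direction != 0 and d != direction:
            tp.append(i - 1)
        direction = d
    tp.append(len(x) - 1)
    # dedupe while keeping order
    out = []
    for i in tp:
        if not out or i != out[-1]:
            out.append(i)
    return out


def _filter_turning_points(x: np.ndarray, tp: list[int], amplitude: float) -> list[int]:
    """Remove reversals with swing amplitude below ``amplitude``."""
    tp = list(tp)
    while len(tp) > 2:
        swings = [abs(x[tp[i + 1]] - x[tp[i]]) for i in range(len(tp) - 1)]
        k = int(np.argmin(swings))
        if swings[k] >= amplitude:
            break
        if k == 0:
            tp.pop(1)
        elif k == len(swings) - 1:
            tp.pop(-2)
        else:
            del tp[k : k + 2]
    if len(tp) == 2 and abs(x[tp[1]] - x[tp[0]]) < amplitude:
        return [tp[0]] if tp[0] != tp[1] else tp[:1]
    return tp


def persistence_segments(
    lengths: np.ndarray,
    frame_interval: float,
    filter_amplitude: float = 0.0,
    junction_id: int = -1,
) -> list[PersistenceSegment]:
    """Maximal monotone stretches between hysteresis-filtered turning
    points of a regularly sampled length series."""
    x = np.asarray(lengths, dtype=float)
    if len(x) < 3:
        return []
    tp = _turning_points(x)
    tp = _filter_turning_points(x, tp, filter_amplitude)
    segments: list[PersistenceSegment] = []
    for i in range(len(tp) - 1):
        a, b = tp[i], tp[i + 1]
        dl = float(x[b] - x[a])
        if dl == 0:
            continue
        segments.append(
            PersistenceSegment(
                junction_id=junction_id,
                start_frame=a,
                end_frame=b,
                delta_length=dl,
                duration=(b - a) * frame_interval,
                sign="contraction" if dl < 0 else "expansion",
            )
        )
    return segments


def ballistic_velocity(segment: PersistenceSegment) -> float:
    return segment.velocity
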