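"""T1 neighbor-exchange detection on tracked junctions and cells, event
directionality, quartet geometry and reversibility statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Polygon
from shapely.ops import unary_union

__all__ = [
    "TrackedT1Event",
    "detect_t1_events",
    "classify_directionality",
    "quartet_aspect_ratios",
    "reversal_survival",
]


@dataclass
class TrackedT1Event:
    """A neighbor exchange reconstructed from tracked data."""

    event_id: int
    frame: int  # four-way-vertex frame (end of the four-fold interval)
    old_track: int  # junction track that collapsed (-1 if unobserved)
    new_track: int  # junction track that emerged (may equal old_track)
    losing: tuple[int, int]  # cell track ids that lost contact
    gaining: tuple[int, int]
    near_miss: bool = False  # reached four-way vertex, no exchange
    site: tuple[float, float] = (np.nan, np.nan)  # (row, col)


def detect_t1_events(
    junction_frames: list[dict],
    min_new_frames: int = 4,
    fourway_scale_px: float = 6.0,
    search_radius_px: float = 10.0,
    max_gap_frames: int = 12,
) -> list[TrackedT1Event]:
    """Find junction collapses followed by re-expansion with swapped
    cell neighbors.

    Parameters
    ----------
    junction_frames : one dict per junction track, with keys
        ``track_id``, ``frames`` (sorted list), ``length`` (same order),
        ``midpoint`` ((row, col) per frame), ``side_cells`` (pair of cell
        track ids per frame), ``end_cells`` (pair per frame).
    min_new_frames : frames the new configuration must persist.
    fourway_scale_px : length below which a junction counts as a
        four-way vertex.
    search_radius_px : max distance between the collapse site and the
        emerging junction's midpoint.
    max_gap_frames : max frames between collapse and re-expansion.

    Events where the junction shrinks below scale and re-expands with
    the *same* neighbors are returned as near-misses.
    """
    by_track = {jf["track_id"]: jf for jf in junction_frames}
    events: list[TrackedT1Event] = []

    def stable_pair(jf: dict, start_idx: int) -> bool:
        pairs = jf["side_cells"][start_idx : start_idx + min_new_frames]
        if len(pairs) < min_new_frames:
            return False
        first = set(pairs[0])
        return all(set(p) == first for p in pairs)

    for jf in junction_frames:
        frames = jf["frames"]
        lengths = np.asarray(jf["length"], dtype=float)
        below = lengths < fourway_scale_px
        if not below.any():
            continue
        # every contiguous below-scale excursion is a candidate; the
        # event is dated at the (last) minimum-length frame
        i0 = 0
        n = len(frames)
        while i0 < n:
            if not below[i0]:
                i0 += 1
                continue
            rest = np.flatnonzero(~below[i0:])
            i1 = i0 + int(rest[0]) if rest.size else n  # first frame back out
            seg = lengths[i0:i1]
            i_min = i0 + int(len(seg) - 1 - np.argmin(seg[::-1]))
            collapse_frame = frames[i_min]
            site = np.asarray(jf["midpoint"][i_min], dtype=float)
            losing = tuple(sorted(jf["side_cells"][max(i0 - 1, 0)]))

            if i1 < n:  # (a) same track re-expands
                new_pair = tuple(sorted(jf["side_cells"][i1]))
                if not set(new_pair) & set(losing) and stable_pair(jf, i1):
                    events.append(
                        TrackedT1Event(
                            event_id=len(events),
                            frame=collapse_frame,
                            old_track=jf["track_id"],
                            new_track=jf["track_id"],
                            losing=losing,
                            gaining=new_pair,
                            site=tuple(site),
                        )
                    )
                elif new_pair == losing and stable_pair(jf, i1):
                    events.append(
                        TrackedT1Event(
                            event_id=len(events),
                            frame=collapse_frame,
                            old_track=jf["track_id"],
                            new_track=jf["track_id"],
                            losing=losing,
                            gaining=losing,
                            near_miss=True,
                            site=tuple(site),
                        )
                    )
                i0 = i1
                continue

            # (b) track ends collapsed; look for an emerging junction
            end_cells = tuple(sorted(jf["end_cells"][max(i0 - 1, 0)]))
            candidate = None
            for other in junction_frames:
                if other["track_id"] == jf["track_id"]:
                    continue
                f_start = other["frames"][0]
                if not (collapse_frame <= f_start <= frames[-1] + max_gap_frames):
                    continue
                if (
                    np.linalg.norm(np.asarray(other["midpoint"][0]) - site)
                    > search_radius_px
                ):
                    continue
                pair = tuple(sorted(other["side_cells"][0]))
                ends_ok = pair == end_cells or -1 in end_cells
                if ends_ok and not set(pair) & set(losing) and stable_pair(other, 0):
                    if candidate is None or f_start < candidate["frames"][0]:
                        candidate = other
            if candidate is not None:
                events.append(
                    TrackedT1Event(
                        event_id=len(events),
                        frame=max(candidate["frames"][0] - 1, collapse_frame),
                        old_track=jf["track_id"],
                        new_track=candidate["track_id"],
                        losing=losing,
                        gaining=tuple(sorted(candidate["side_cells"][0])),
                        site=tuple(site),
                    )
                )
            break  # excursion ran to the end of the track

    # (c) exchanges whose collapsing junction was never tracked: a
    # junction born small at a four-fold vertex that grows out stably.
    # A genuine exchange changes cell adjacency: the gaining pair must
    # not have been adjacent just before the emergence, and the losing
    # pair (the new junction's end cells) must have been.
    adjacency: dict[int, set[frozenset]] = {}
    first_seen: dict[int, int] = {}
    for jf in junction_frames:
        for f, pair in zip(jf["frames"], jf["side_cells"]):
            adjacency.setdefault(f, set()).add(frozenset(pair))
            for c in pair:
                if c not in first_seen or f < first_seen[c]:
                    first_seen[c] = f

    def adjacent_in_window(pair, f_lo, f_hi) -> bool:
        key = frozenset(pair)
        return any(key in adjacency.get(f, ()) for f in range(f_lo, f_hi + 1))

    for jf in junction_frames:
        if jf["frames"][0] == 0:
            continue  # present from the start: not an emergence
        lengths = np.asarray(jf["length"], dtype=float)
        if lengths[0] >= fourway_scale_px + 2.0:
            continue  # track fragment of an existing junction
        if lengths.max() < fourway_scale_px:
            continue
        f0 = jf["frames"][0]
        gaining = tuple(sorted(jf["side_cells"][0]))
        if not stable_pair(jf, 0):
            continue
        if adjacent_in_window(gaining, f0 - max_gap_frames, f0 - 1):
            continue  # pair already neighbors: no exchange happened
        if any(first_seen.get(c, f0) >= f0 - 2 for c in gaining):
            continue  # fresh track ids: relabeling artifact, not a gain
        ends = next((e for e in jf["end_cells"][:6] if -1 not in e), None)
        if ends is not None:
            losing = tuple(sorted(ends))
            if set(losing) & set(gaining):
                continue
            if not adjacent_in_window(losing, f0 - max_gap_frames, f0 - 1):
                continue  # no record of the losing contact
        else:
            losing = (-1, -1)  # collapsed junction never resolved
        events.append(
            TrackedT1Event(
                event_id=len(events),
                frame=f0 - 1,
                old_track=-1,
                new_track=jf["track_id"],
                losing=losing,
                gaining=gaining,
                site=tuple(np.asarray(jf["midpoint"][0], dtype=float)),
            )
        )

    # dedup: branches can describe the same exchange from both sides
    out: list[TrackedT1Event] = []
    for ev in events:
        dup = False
        for kept in out:
            if (
                not ev.near_miss
                and not kept.near_miss
                and set(kept.gaining) == set(ev.gaining)
                and abs(kept.frame - ev.frame) <= 8
                and np.hypot(
                    kept.site[0] - ev.site[0], kept.site[1] - ev.site[1]
                )
                <= 12.0
            ):
                dup = True
                break
        if not dup:
            out.append(ev)
    for k, ev in enumerate(out):
        ev.event_id = k
    return out


def classify_directionality(
    events: list, window: float, times: np.ndarray | None = None
) -> tuple[dict[int, str], dict[str, float]]:
    """Label each event's quartet uni- or multi-directional.

    A quartet with two or more events where a later losing pair equals
    an earlier gaining pair within ``window`` minutes is
    multi-directional.  ``events`` need ``losing``, ``gaining`` and
    either ``time`` (min) or ``frame`` (use ``times`` to convert).
    """

    def time_of(ev) -> float:
        if hasattr(ev, "time"):
            return float(ev.time)
        return float(times[ev.frame]) if times is not None else float(ev.frame)

    def quartet_key(ev) -> frozenset:
        return frozenset(ev.losing) | frozenset(ev.gaining)

    labels: dict[int, str] = {}
    by_quartet: dict[frozenset, list] = {}
    for ev in events:
        if getattr(ev, "near_miss", False):
            continue
        by_quartet.setdefault(quartet_key(ev), []).append(ev)
    for evs in by_quartet.values():
        evs.sort(key=time_of)
        multi_ids: set[int] = set()
        for i, later in enumerate(evs):
            for earlier in evs[:i]:
                if (
                    set(later.losing) == set(earlier.gaining)
                    and time_of(later) - time_of(earlier) <= window
                ):
                    multi_ids.update({id(later), id(earlier)})
        for ev in evs:
            labels[ev.event_id] = "multi" if id(ev) in multi_ids else "uni"
    n = len(labels)
    n_multi = sum(1 for v in labels.values() if v == "multi")
    fractions = {
        "multi": n_multi / n if n else 0.0,
        "uni": 1.0 - n_multi / n if n else 0.0,
    }
    return labels, fractions


def quartet_aspect_ratios(
    losing_polys: list[np.ndarray], gaining_polys: list[np.ndarray]
) -> tuple[float, float]:
    """Internal and external aspect ratio of a four-cell cluster.

    internal = distance between the centers of area (CoA) of the two
    losing cells over the same distance for the gaining cells; external
    uses, per pair, the distance between the intersections of the CoA
    axis with the cluster's outer perimeter.
    """
    losing = [Polygon(p) for p in losing_polys]
    gaining = [Polygon(p) for p in gaining_polys]
    cluster = unary_union(losing + gaining)

    def coa(poly: Polygon) -> np.ndarray:
        return np.asarray(poly.centroid.coords[0])

    l1, l2 = coa(losing[0]), coa(losing[1])
    g1, g2 = coa(gaining[0]), coa(gaining[1])
    internal = float(np.linalg.norm(l1 - l2) / np.linalg.norm(g1 - g2))

    def perimeter_span(a: np.ndarray, b: np.ndarray) -> float:
        d = b - a
        norm = np.linalg.norm(d)
        if norm == 0:
            return np.nan
        d = d / norm
        span = 4.0 * np.sqrt(cluster.area)
        line = LineString([a - span * d, b + span * d])
        inter = line.intersection(cluster.boundary)
        pts = []
        if inter.is_empty:
            return np.nan
        for geom in getattr(inter, "geoms", [inter]):
            pts.extend(np.asarray(geom.coords))
        pts = np.asarray(pts)
        proj = pts @ d
        return float(proj.max() - proj.min())

    ext_l = perimeter_span(l1, l2)
    ext_g = perimeter_span(g1, g2)
    external = float(ext_l / ext_g) if ext_g and not np.isnan(ext_g) else np.nan
    return internal, external


def reversal_survival(
    durations: np.ndarray, observed: np.ndarray, ci: bool = True
):
    """Kaplan-Meier curve for the time a neighbor exchange stays
    uni-directional.

    ``durations``: minutes from each exchange until its reversal (event)
    or until the end of observation (censored); ``observed``: 1 for a
    reversal, 0 for censoring.  Returns the fitted lifelines estimator.
    """
    from lifelines import KaplanMeierFitter

    durations = np.asarray(durations, dtype=float)
    observed = np.asarray(observed, dtype=int)
    if len(durations) == 0:
        raise ValueError("no events to estimate a survival curve from")
    km = KaplanMeierFitter()
    km.fit(durations, event_observed=observed, label="uni-directional")
    return km
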