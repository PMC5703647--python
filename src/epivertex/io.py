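"""Readers/writers for image stacks and the delimited trajectory,
event, track and statistics tables.

Images are 8-bit TIFF stacks (or numbered image sequences); all tables
are tab-separated text with documented headers.  Coordinates follow the
convention recorded in the run manifest: pixels (row, col, origin
top-left) for images, model units (x, y, origin bottom-left) for
simulation output.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .tissue import Box, Tissue

__all__ = [
    "read_stack",
    "write_stack",
    "read_table",
    "write_table",
    "write_tissue",
    "read_tissue",
    "write_events",
]

EVENT_COLUMNS = [
    "event_id",
    "time_min",
    "edge_id",
    "quartet_1",
    "quartet_2",
    "quartet_3",
    "quartet_4",
    "losing_1",
    "losing_2",
    "gaining_1",
    "gaining_2",
    "reversal_of",
]


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write an (T, H, W) uint8 stack as a multi-page TIFF."""
    stack = np.asarray(stack)
    if stack.dtype != np.uint8:
        raise ValueError(f"stacks must be 8-bit, got {stack.dtype}")
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    stack = tifffile.imread(str(path))
    if stack.dtype != np.uint8:
        raise ValueError(f"expected an 8-bit stack, got {stack.dtype}")
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, expected_columns: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if expected_columns is not None and list(df.columns) != list(expected_columns):
        raise ValueError(
            f"header mismatch in {path}: expected {expected_columns}, "
            f"got {list(df.columns)}"
        )
    return df


def write_tissue(tissue: Tissue, directory: str | Path, prefix: str = "frame") -> None:
    """One file set per frame: vertices, edges, cells tables."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    verts, edges, cells = tissue.to_tables()
    write_table(verts, directory / f"{prefix}_vertices.tsv")
    write_table(edges, directory / f"{prefix}_edges.tsv")
    write_table(cells, directory / f"{prefix}_cells.tsv")
    (directory / f"{prefix}_box.tsv").write_text(
        f"width\theight\n{tissue.box.width!r}\t{tissue.box.height!r}\n"
    )


def read_tissue(directory: str | Path, prefix: str = "frame") -> Tissue:
    directory = Path(directory)
    verts = read_table(directory / f"{prefix}_vertices.tsv", ["id", "x", "y"])
    edges = read_table(
        directory / f"{prefix}_edges.tsv", ["id", "v1", "v2", "cell_left", "cell_right"]
    )
    cells = read_table(
        directory / f"{prefix}_cells.tsv", ["id", "vertex_cycle", "preferred_area"]
    )
    w, h = (
        Path(directory / f"{prefix}_box.tsv").read_text().strip().split("\n")[1].split("\t")
    )
    return Tissue.from_tables(verts, edges, cells, Box(float(w), float(h)))


def write_events(events: list, path: str | Path) -> None:
    rows = []
    for ev in events:
        rows.append(
            {
                "event_id": ev.event_id,
                "time_min": ev.time,
                "edge_id": ev.edge_id,
                "quartet_1": ev.quartet[0],
                "quartet_2": ev.quartet[1],
                "quartet_3": ev.quartet[2],
                "quartet_4": ev.quartet[3],
                "losing_1": ev.losing[0],
                "losing_2": ev.losing[1],
                "gaining_1": ev.gaining[0],
                "gaining_2": ev.gaining[1],
                "reversal_of": -1 if ev.reversal_of is None else ev.reversal_of,
            }
        )
    write_table(pd.DataFrame(rows, columns=EVENT_COLUMNS), path)
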