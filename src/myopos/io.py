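"""CSV/JSON/YAML serialisation of cells, configurations and ellipse tables.

Schemas (shared by synthetic and measured data so they are interchangeable):

cells.csv      cell_id, half_width, half_length, n_nuclei, nuclear_radius
centroids.csv  cell_id, nucleus_id, x, y
ellipses.csv   cell_id, nucleus_id, cx, cy, major, minor, angle_deg

Angles are stored in degrees in files and radians in memory.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import CellGeometry
from .metrics import NuclearEllipse


def cells_to_frame(geoms: Sequence[CellGeometry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": range(len(geoms)),
            "half_width": [g.half_width for g in geoms],
            "half_length": [g.half_length for g in geoms],
            "n_nuclei": [g.n_nuclei for g in geoms],
            "nuclear_radius": [g.nuclear_radius for g in geoms],
        }
    )


def frame_to_cells(df: pd.DataFrame) -> list[CellGeometry]:
    return [
        CellGeometry(
            float(row.half_width), float(row.half_length),
            int(row.n_nuclei), float(row.nuclear_radius),
        )
        for row in df.sort_values("cell_id").itertuples()
    ]


def write_cells(path, geoms: Sequence[CellGeometry]) -> None:
    cells_to_frame(geoms).to_csv(path, index=False)


def read_cells(path) -> list[CellGeometry]:
    return frame_to_cells(pd.read_csv(path))


def configurations_to_frame(configs: Sequence[np.ndarray]) -> pd.DataFrame:
    rows = []
    for cid, pos in enumerate(configs):
        for nid, (x, y) in enumerate(np.asarray(pos, dtype=float)):
            rows.append({"cell_id": cid, "nucleus_id": nid, "x": x, "y": y})
    return pd.DataFrame(rows)


def write_configurations(path, configs: Sequence[np.ndarray]) -> None:
    configurations_to_frame(configs).to_csv(path, index=False)


def read_configurations(path) -> list[np.ndarray]:
    df = pd.read_csv(path)
    out = []
    for _, grp in df.groupby("cell_id", sort=True):
        out.append(grp.sort_values("nucleus_id")[["x", "y"]].to_numpy(dtype=float))
    return out


def ellipses_to_frame(cells: Sequence[Sequence[NuclearEllipse]]) -> pd.DataFrame:
    rows = []
    for cid, ellipses in enumerate(cells):
        for nid, e in enumerate(ellipses):
            rows.append(
                {
                    "cell_id": cid, "nucleus_id": nid,
                    "cx": e.centroid[0], "cy": e.centroid[1],
                    "major": e.major, "minor": e.minor,
                    "angle_deg": math.degrees(e.orientation),
                }
            )
    return pd.DataFrame(rows)


def write_ellipses(path, cells: Sequence[Sequence[NuclearEllipse]]) -> None:
    ellipses_to_frame(cells).to_csv(path, index=False)


def read_ellipses(path) -> list[list[NuclearEllipse]]:
    df = pd.read_csv(path)
    out = []
    for _, grp in df.groupby("cell_id", sort=True):
        out.append(
            [
                NuclearEllipse(
                    (float(r.cx), float(r.cy)), float(r.major), float(r.minor),
                    math.radians(float(r.angle_deg)) % math.pi,
                )
                for r in grp.sort_values("nucleus_id").itertuples()
            ]
        )
    return out
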