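"""Readers and writers for point tables and gridded maps.

Point samples travel as delimited text with columns ``x, y, value`` and
optional ``prediction, pi`` columns (all-or-none). Gridded maps are written
either as long-form CSV (``x, y, value``) or as ESRI ASCII grids with the
standard ``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`` header.
Coordinates are planar Cartesian in user units; grid cells are indexed
row-major from the lower-left corner.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .interpolator import EstimatedMap
from .populations import StudyRegion

__all__ = [
    "read_points_csv",
    "write_points_csv",
    "write_grid",
    "read_esri_ascii",
    "tessellation_shape",
]

_REQUIRED = ("x", "y", "value")
_OPTIONAL = ("prediction", "pi")


def read_points_csv(
    path: str | Path,
    columns: dict[str, str] | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read a point table, validating coordinates and values.

    ``columns`` maps canonical names (``x``, ``y``, ``value``, optionally
    ``prediction`` and ``pi``) to the file's column names.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    columns = columns or {}
    rename = {columns.get(k, k): k for k in _REQUIRED + _OPTIONAL if columns.get(k, k) in df.columns}
    df = df.rename(columns=rename)
    for name in _REQUIRED:
        if name not in df.columns:
            raise ValueError(f"points file {path} is missing required column {name!r}")
    present_opt = [c for c in _OPTIONAL if c in df.columns]
    if present_opt and len(present_opt) != len(_OPTIONAL):
        raise ValueError(
            f"optional columns {_OPTIONAL} must be given all-or-none; found {present_opt}"
        )
    keep = list(_REQUIRED) + present_opt
    df = df[keep]
    if len(df) == 0:
        raise ValueError(f"points file {path} contains no data rows")
    bad = df.apply(lambda c: pd.to_numeric(c, errors="coerce")).isna()
    if bad.any().any():
        rows = np.flatnonzero(bad.any(axis=1))[:5] + 2  # 1-based incl. header
        raise ValueError(f"non-numeric cells in {path} near line(s) {list(rows)}")
    df = df.astype(float)
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ValueError(f"non-finite coordinates in {path}")
    return df


def write_points_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def _grid_geometry(est_map: EstimatedMap) -> tuple[int, int, float, float, float]:
    """(nrows, ncols, xll, yll, cellsize) of a regular-grid map; errors otherwise."""
    if est_map.grid_shape is None:
        raise ValueError("map support is not a regular grid")
    ny, nx = est_map.grid_shape
    xs = np.unique(np.round(est_map.support[:, 0], 12))
    ys = np.unique(np.round(est_map.support[:, 1], 12))
    if len(xs) != nx or len(ys) != ny:
        raise ValueError("grid support does not match its declared shape")
    cs_x = xs[1] - xs[0] if nx > 1 else (ys[1] - ys[0] if ny > 1 else 1.0)
    cs_y = ys[1] - ys[0] if ny > 1 else cs_x
    if not math.isclose(cs_x, cs_y, rel_tol=1e-9):
        raise ValueError("ESRI ASCII grids require square cells")
    return ny, nx, float(xs[0] - cs_x / 2), float(ys[0] - cs_y / 2), float(cs_x)


def write_grid(
    est_map: EstimatedMap,
    path: str | Path,
    fmt: str = "esri_ascii",
    nodata: float = -9999.0,
) -> None:
    """Write a gridded map as ESRI ASCII (``esri_ascii``) or long CSV (``csv``)."""
    path = Path(path)
    if fmt == "csv":
        pd.DataFrame(
            {
                "x": est_map.support[:, 0],
                "y": est_map.support[:, 1],
                "value": est_map.values,
            }
        ).to_csv(path, index=False)
        return
    if fmt != "esri_ascii":
        raise ValueError(f"unknown grid format {fmt!r}")
    ny, nx, xll, yll, cs = _grid_geometry(est_map)
    grid = est_map.values.reshape(ny, nx)
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {cs!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in grid[::-1]:  # ESRI ASCII stores the top row first
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_esri_ascii(path: str | Path) -> tuple[np.ndarray, dict[str, float]]:
    """Read an ESRI ASCII grid: values (row-major from the lower-left) + header."""
    header: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    grid = np.array(rows)[::-1]  # back to lower-left row-major
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid body of {path} does not match its header")
    return grid, header


def tessellation_shape(region: StudyRegion, cell_size: float) -> tuple[int, int]:
    """Quadrat grid shape ``(ny, nx)`` tiling the region at a given cell side.

    The cell must tile the region exactly (as in tessellation stratified
    designs); a 4900-ha square region at 200 m resolution, for instance,
    tiles into 35 x 35 = 1225 quadrats.
    """
    nx = region.width / cell_size
    ny = region.height / cell_size
    if not (
        math.isclose(nx, round(nx), rel_tol=0, abs_tol=1e-9 * max(nx, 1))
        and math.isclose(ny, round(ny), rel_tol=0, abs_tol=1e-9 * max(ny, 1))
    ):
        raise ValueError(
            f"cell size {cell_size} does not tile the region {region.bounds} exactly"
        )
    return int(round(ny)), int(round(nx))
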