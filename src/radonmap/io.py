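"""Readers and writers for the pipeline's file dialects.

CSV tables go through pandas; rasters use the ESRI ASCII grid format (plain
text, row order north to south); region adjacency is a two-column edge list;
ground truth and reports are JSON. Readers validate shape and required
columns so stage boundaries fail loudly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GridSpec, RegionMap, TruthRecord


def write_esri_ascii(path, values: np.ndarray, grid: GridSpec, nodata: float = -9999.0):
    """Write a grid raster as ESRI ASCII (.asc).

    ``values`` is (ny, nx) with row 0 the southernmost row (the package's
    grid convention); the format stores rows north to south, so rows are
    flipped on write. Requires square cells (dx == dy).
    """
    values = np.asarray(values, float)
    if values.shape != (grid.ny, grid.nx):
        raise ValueError(f"values shape {values.shape} != grid ({grid.ny}, {grid.nx})")
    if grid.dx != grid.dy:
        raise ValueError("ESRI ASCII requires square cells (dx == dy)")
    lines = [
        f"ncols {grid.nx}",
        f"nrows {grid.ny}",
        f"xllcorner {grid.x0:.6f}",
        f"yllcorner {grid.y0:.6f}",
        f"cellsize {grid.dx:.6f}",
        f"NODATA_value {nodata:g}",
    ]
    body = np.where(np.isfinite(values), values, nodata)[::-1]
    for row in body:
        lines.append(" ".join(f"{v:.6f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_esri_ascii(path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; returns (values (ny, nx) south-up, GridSpec)."""
    text = Path(path).read_text().strip().splitlines()
    header = {}
    i = 0
    while i < len(text) and text[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    ):
        key, val = text[i].split()[:2]
        header[key.lower()] = float(val)
        i += 1
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"ESRI ASCII header missing {req}")
    nx, ny = int(header["ncols"]), int(header["nrows"])
    body = np.loadtxt(text[i:]).reshape(ny, nx)[::-1]
    nodata = header.get("nodata_value")
    if nodata is not None:
        body = np.where(body == nodata, np.nan, body)
    grid = GridSpec(
        nx=nx, ny=ny,
        x0=header["xllcorner"], y0=header["yllcorner"],
        dx=header["cellsize"], dy=header["cellsize"],
    )
    return body, grid


def write_adjacency(path, adjacency: frozenset):
    """Two-column whitespace edge list, one unordered pair per line, sorted."""
    lines = [f"{a} {b}" for a, b in sorted(adjacency)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_adjacency(path) -> frozenset:
    pairs = set()
    for line in Path(path).read_text().strip().splitlines():
        a, b = line.split()
        a, b = int(a), int(b)
        pairs.add((min(a, b), max(a, b)))
    return frozenset(pairs)


def write_regions(path, regions: RegionMap):
    """Cell-to-region membership as CSV (row, col, region_id)."""
    ny, nx = regions.membership.shape
    rows, cols = np.divmod(np.arange(ny * nx), nx)
    pd.DataFrame(
        {"row": rows, "col": cols, "region_id": regions.membership.ravel()}
    ).to_csv(path, index=False)


def read_regions(path, adjacency_path) -> RegionMap:
    df = pd.read_csv(path)
    for c in ("row", "col", "region_id"):
        if c not in df.columns:
            raise ValueError(f"region membership CSV lacks column {c!r}")
    ny = int(df["row"].max()) + 1
    nx = int(df["col"].max()) + 1
    member = np.full((ny, nx), -1, dtype=int)
    member[df["row"], df["col"]] = df["region_id"]
    if (member == -1).any():
        raise ValueError("region membership does not cover every grid cell")
    ids = tuple(sorted(int(r) for r in df["region_id"].unique()))
    return RegionMap(ids, member, read_adjacency(adjacency_path))


def write_truth(path, truth: TruthRecord):
    Path(path).write_text(truth.to_json() + "\n")


def read_truth(path) -> TruthRecord:
    return TruthRecord.from_json(Path(path).read_text())


def write_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_table(path, df: pd.DataFrame):
    """CSV with stable 12-significant-digit floats for byte reproducibility."""
    df.to_csv(path, index=False, float_format="%.12g")


def read_table(path, required=()) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df
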