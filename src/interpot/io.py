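"""File I/O: per-cell object tables, outlines, and domain masks.

Formats
-------
Points CSV      : header ``cell_id,x,y``; one query point per row.
Outlines CSV    : header ``cell_id,object_id,vertex_index,x,y``; polygons are
                  closed implicitly.
Reference points: same schema as points CSV (used when Y are point-like).
Mask TIFF/PNG   : single-channel image; nonzero pixels are inside Omega.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import CellData
from .geometry import Domain, ObjectSet, PointRef, PolygonRef

__all__ = ["read_points", "read_outlines", "read_mask", "read_objects",
           "write_points", "write_outlines", "write_mask"]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def read_points(path) -> dict[str, np.ndarray]:
    """Points CSV -> {cell_id: (N, 2) array}."""
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "x", "y"], path)
    return {str(cid): g[["x", "y"]].to_numpy(dtype=float) for cid, g in df.groupby("cell_id")}


def read_outlines(path) -> dict[str, list[PolygonRef]]:
    """Outlines CSV -> {cell_id: [PolygonRef, ...]}."""
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "object_id", "vertex_index", "x", "y"], path)
    out: dict[str, list[PolygonRef]] = {}
    for (cid, oid), g in df.groupby(["cell_id", "object_id"]):
        g = g.sort_values("vertex_index")
        try:
            poly = PolygonRef(g[["x", "y"]].to_numpy(dtype=float))
        except ValueError as e:
            raise ValueError(f"{path}: cell {cid!r} object {oid}: {e}") from e
        out.setdefault(str(cid), []).append(poly)
    return out


def read_mask(path) -> Domain:
    """Single-channel TIFF/PNG mask -> Domain (nonzero = inside Omega)."""
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D mask, got shape {arr.shape}")
    return Domain(mask=arr != 0)


def read_objects(points_path, outlines_path=None, ref_points_path=None,
                 mask_path=None) -> list[CellData]:
    """Assemble per-cell object sets from files; q and D are left unfilled.

    Emits a validation report as exceptions: degenerate polygons and objects
    outside the domain are hard errors naming the offending cell/object.
    """
    points = read_points(points_path)
    refs: dict[str, list] = {}
    if outlines_path is not None:
        for cid, polys in read_outlines(outlines_path).items():
            refs.setdefault(cid, []).extend(polys)
    if ref_points_path is not None:
        for cid, pts in read_points(ref_points_path).items():
            refs.setdefault(cid, []).extend(PointRef((x, y)) for x, y in pts)
    domain = read_mask(mask_path) if mask_path is not None else None
    cells = []
    for cid, X in sorted(points.items()):
        Y = refs.get(cid, [])
        if domain is not None:
            inside = domain.contains(X)
            if not inside.all():
                raise ValueError(
                    f"cell {cid!r}: {np.count_nonzero(~inside)} query point(s) outside the domain")
        objs = ObjectSet(X, Y, cell_id=cid)
        cells.append(CellData(cell_id=cid, D=None, q=None, covariates={"objects": objs,
                                                                      "domain": domain}))
    return cells


def write_points(path, cells: dict[str, np.ndarray]) -> None:
    rows = [
        {"cell_id": cid, "x": x, "y": y}
        for cid, pts in cells.items()
        for x, y in np.atleast_2d(pts)
    ]
    pd.DataFrame(rows, columns=["cell_id", "x", "y"]).to_csv(path, index=False)


def write_outlines(path, cells: dict[str, list[PolygonRef]]) -> None:
    rows = []
    for cid, polys in cells.items():
        for oid, poly in enumerate(polys):
            for vi, (x, y) in enumerate(poly.vertices):
                rows.append({"cell_id": cid, "object_id": oid, "vertex_index": vi,
                             "x": x, "y": y})
    pd.DataFrame(rows, columns=["cell_id", "object_id", "vertex_index", "x", "y"]).to_csv(
        path, index=False)


def write_mask(path, domain: Domain) -> None:
    if domain.mask is None:
        raise ValueError("domain has no mask representation")
    arr = domain.mask.astype(np.uint8) * 255
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    Path(path).touch()
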