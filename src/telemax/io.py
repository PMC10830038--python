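"""File I/O: telemetry CSV, ESRI ASCII grid rasters, GeoJSON polygons.

Rasters travel as plain-text ESRI ASCII grids with a JSON sidecar carrying
the CRS and, for stacks, per-layer metadata (base variable, category, focal
extent, focal statistic).  Telemetry is a flat CSV with ISO-8601 UTC
timestamps; malformed rows are collected into a reject table with reasons
rather than raising.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grid import AlignmentError, Grid, LayerMeta, Raster, RasterStack

NODATA = -9999.0

TELEMETRY_COLUMNS = ["deployment_id", "timestamp", "lon", "lat", "fix_type", "argos_class"]


class FormatError(ValueError):
    """Malformed input file (missing column, bad CRS, misaligned grid...)."""


# ---------------------------------------------------------------- telemetry


def read_telemetry(path, crs=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a telemetry CSV.

    Returns ``(fixes, rejects)``.  ``fixes`` has parsed UTC timestamps and,
    when ``crs`` is given, projected ``x``/``y`` columns.  Rows with missing
    fields, unparseable timestamps, or out-of-range coordinates land in
    ``rejects`` with a ``reject_reason`` column.
    """
    raw = pd.read_csv(path, dtype={"deployment_id": str, "argos_class": str})
    missing = [c for c in TELEMETRY_COLUMNS if c not in raw.columns and c != "argos_class"]
    if missing:
        raise FormatError(f"telemetry file {path} missing mandatory column(s): {missing}")
    if "argos_class" not in raw.columns:
        raw["argos_class"] = ""
    raw["argos_class"] = raw["argos_class"].fillna("")

    reasons = pd.Series("", index=raw.index, dtype=object)
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", utc=True, format="ISO8601")
    reasons[ts.isna() & (reasons == "")] = "unparseable timestamp"
    lon = pd.to_numeric(raw["lon"], errors="coerce")
    lat = pd.to_numeric(raw["lat"], errors="coerce")
    bad_lon = lon.isna() | (lon < -180) | (lon > 180)
    bad_lat = lat.isna() | (lat < -90) | (lat > 90)
    reasons[bad_lon & (reasons == "")] = "longitude out of bounds"
    reasons[bad_lat & (reasons == "")] = "latitude out of bounds"
    bad_src = ~raw["fix_type"].isin(["GPS", "Argos"])
    reasons[bad_src & (reasons == "")] = "unknown fix_type"

    ok = reasons == ""
    rejects = raw.loc[~ok].copy()
    rejects["reject_reason"] = reasons[~ok]
    fixes = raw.loc[ok].copy()
    fixes["timestamp"] = ts[ok]
    fixes["lon"] = lon[ok]
    fixes["lat"] = lat[ok]
    if crs is not None and len(fixes):
        fixes["x"], fixes["y"] = crs.forward(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    fixes = fixes.sort_values(["deployment_id", "timestamp"], kind="stable").reset_index(drop=True)
    return fixes, rejects.reset_index(drop=True)


def write_telemetry(fixes: pd.DataFrame, path) -> None:
    out = fixes.copy()
    if len(out):
        out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
            "%Y-%m-%dT%H:%M:%S%z"
        )
    cols = [c for c in TELEMETRY_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols and c not in ("x", "y")]
    out[cols].to_csv(path, index=False)


# ------------------------------------------------------------------ rasters


def write_raster(raster: Raster, path) -> None:
    """Write one layer as an ESRI ASCII grid plus a ``.json`` CRS sidecar."""
    path = Path(path)
    g = raster.grid
    data = np.where(np.isfinite(raster.data), raster.data, NODATA)
    header = (
        f"ncols {g.ncols}\nnrows {g.nrows}\n"
        f"xllcorner {g.x0!r}\nyllcorner {g.y0!r}\n"
        f"cellsize {g.resolution!r}\nNODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.10g")
    Path(str(path) + ".json").write_text(json.dumps(g.crs.to_dict()))


def read_raster(path) -> Raster:
    path = Path(path)
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise FormatError(f"raster {path} has no CRS sidecar ({sidecar.name}); refusing to guess")
    from .grid import LambertAzimuthalEqualArea

    crs = LambertAzimuthalEqualArea.from_dict(json.loads(sidecar.read_text()))
    hdr = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    grid = Grid(
        nrows=int(hdr["nrows"]),
        ncols=int(hdr["ncols"]),
        resolution=hdr["cellsize"],
        x0=hdr["xllcorner"],
        y0=hdr["yllcorner"],
        crs=crs,
    )
    nodata = hdr.get("nodata_value", NODATA)
    data[data == nodata] = np.nan
    return Raster(grid, data)


def write_stack(stack: RasterStack, out_dir) -> None:
    """Write a stack as one ASCII grid per layer plus ``stack.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in stack.names:
        write_raster(Raster(stack.grid, stack[name]), out_dir / f"{name}.asc")
    (out_dir / "stack.json").write_text(stack.metadata_json())


def read_stack(in_dir) -> RasterStack:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "stack.json").read_text())
    grid = Grid.from_dict(meta["grid"])
    stack = RasterStack(grid)
    for layer in meta["layers"]:
        lm = LayerMeta.from_dict(layer)
        r = read_raster(in_dir / f"{lm.name}.asc")
        if r.grid.shape != grid.shape or r.grid.resolution != grid.resolution:
            raise AlignmentError(f"layer {lm.name!r} is not aligned with the stack grid")
        stack.add(r.data, lm)
    return stack


# ----------------------------------------------------------------- polygons


def read_polygons(path, crs=None) -> dict[str, BaseGeometry]:
    """Read a GeoJSON FeatureCollection into ``{feature id: geometry}``.

    Geometries with geographic coordinates (detected via a ``crs84`` flag in
    each feature's properties or coordinates within lon/lat bounds declared
    by ``properties['crs'] == 'geographic'``) are reprojected to the project
    CRS when ``crs`` is given and the file declares geographic coordinates.
    """
    gj = json.loads(Path(path).read_text())
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    declared = gj.get("crs_kind")
    if declared is None:
        raise FormatError(f"{path}: no 'crs_kind' member ('geographic' or 'projected')")
    out: dict[str, BaseGeometry] = {}
    for i, feat in enumerate(gj.get("features", [])):
        geom = shape(feat["geometry"])
        name = str(feat.get("properties", {}).get("name", i))
        if declared == "geographic":
            if crs is None:
                raise FormatError(f"{path}: geographic polygons need a project CRS to load")
            geom = _reproject(geom, crs)
        out[name] = geom
    return out


def _reproject(geom: BaseGeometry, crs) -> BaseGeometry:
    import shapely

    def fwd(coords):
        coords = np.asarray(coords)
        x, y = crs.forward(coords[:, 0], coords[:, 1])
        return np.column_stack([x, y])

    return shapely.transform(geom, fwd)


def write_polygons(geoms: dict[str, BaseGeometry], path, crs_kind="projected") -> None:
    feats = [
        {"type": "Feature", "properties": {"name": name}, "geometry": mapping(geom)}
        for name, geom in geoms.items()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "crs_kind": crs_kind, "features": feats})
    )


def write_manifest(out_dir, stage: str, params: dict, counts: dict | None = None) -> None:
    """Write a provenance manifest for one pipeline stage."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"stage": stage, "params": params, "counts": counts or {}}
    (out_dir / f"manifest_{stage}.json").write_text(json.dumps(payload, indent=2, default=str))
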