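"""Readers and writers for the pipeline's on-disk formats.

Rasters are stored as ESRI ASCII grids (``.asc``) — a plain-text,
widely interchangeable single-band format carrying the full grid
geometry (ncols/nrows/xllcorner/yllcorner/cellsize/NODATA) — with an
optional ``.prj`` sidecar holding the CRS tag. Occurrences are CSV with
``species, lon, lat, source, date`` columns; protected areas are
GeoJSON FeatureCollections.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .grid import ConfigurationError, EnvStack, GridSpec
from .occurrences import OccurrenceSet

__all__ = [
    "write_raster",
    "read_raster",
    "write_stack",
    "read_stack",
    "write_occurrences",
    "read_occurrences",
    "write_polygons",
    "read_polygons",
]


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_raster(path, values: np.ndarray, grid: GridSpec,
                 mask: np.ndarray | None = None, fmt: str = "%.8g") -> None:
    """Write a single-band ASCII grid; NaN and masked cells become nodata."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ConfigurationError("raster shape does not match grid")
    out = values.copy()
    bad = ~np.isfinite(out)
    if mask is not None:
        bad |= ~np.asarray(mask, dtype=bool)
    out[bad] = grid.nodata
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {grid.origin_y!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)
    if grid.crs_tag:
        path.with_suffix(".prj").write_text(grid.crs_tag + "\n")


def read_raster(path) -> tuple[np.ndarray, GridSpec, np.ndarray]:
    """Read an ASCII grid: (values with NaN at nodata, GridSpec, valid mask)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"):
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ConfigurationError(f"missing {req!r} in ASCII grid header of {path}")
    nodata = header.get("nodata_value", -9999.0)
    crs = "local-planar"
    prj = path.with_suffix(".prj")
    if prj.exists():
        crs = prj.read_text().strip()
    grid = GridSpec(
        n_rows=int(header["nrows"]), n_cols=int(header["ncols"]),
        origin_x=header.get("xllcorner", 0.0), origin_y=header.get("yllcorner", 0.0),
        cell_size=header["cellsize"], crs_tag=crs, nodata=nodata,
    )
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape != grid.shape:
        raise ConfigurationError(
            f"{path}: data shape {data.shape} does not match header {grid.shape}"
        )
    valid = data != nodata
    data = np.where(valid, data, np.nan)
    return data, grid, valid


def write_stack(stack: EnvStack, directory) -> list[Path]:
    """One ``<name>.asc`` per layer in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, name in enumerate(stack.names):
        p = directory / f"{name}.asc"
        write_raster(p, stack.data[i], stack.grid, stack.mask)
        paths.append(p)
    return paths


def read_stack(paths, names: list[str] | None = None) -> EnvStack:
    """Stack co-registered single-band rasters; any grid mismatch is a
    hard error naming the offending layers."""
    paths = [Path(p) for p in paths]
    if not paths:
        raise ConfigurationError("no raster paths given")
    if names is None:
        names = [p.stem for p in paths]
    layers, grids, masks = [], [], []
    for p in paths:
        vals, grid, mask = read_raster(p)
        layers.append(vals)
        grids.append(grid)
        masks.append(mask)
    ref = grids[0]
    bad = [str(p) for p, g in zip(paths, grids) if g.shape != ref.shape
           or g.cell_size != ref.cell_size or g.origin_x != ref.origin_x
           or g.origin_y != ref.origin_y]
    if bad:
        raise ConfigurationError(
            f"layers on different grids than {paths[0]} ({ref.shape}, "
            f"cell {ref.cell_size}): {bad}"
        )
    crs_set = {g.crs_tag for g in grids}
    if len(crs_set) > 1:
        raise ConfigurationError(f"CRS mismatch across stack: {sorted(crs_set)}")
    mask = np.logical_and.reduce(masks)
    data = np.where(mask, np.stack(layers), 0.0)
    return EnvStack(ref, list(names), data, mask)


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

def write_occurrences(occ: OccurrenceSet, path) -> None:
    df = occ.records.rename(columns={"x": "lon", "y": "lat", "year": "date"})
    df.to_csv(path, index=False)


def read_occurrences(
    path,
    species_col: str = "species",
    x_col: str = "lon",
    y_col: str = "lat",
    source_col: str = "source",
    date_col: str = "date",
    extent: tuple[float, float, float, float] | None = None,
) -> OccurrenceSet:
    """Load presence records, skipping malformed rows with a counted warning.

    A row is malformed when its coordinates are missing or non-numeric.
    With ``extent`` given, coordinates outside it are flagged (warning)
    but retained. Raises when no valid rows remain.
    """
    df = pd.read_csv(path)
    for col in (species_col, x_col, y_col):
        if col not in df.columns:
            raise ValueError(f"occurrence file {path} lacks column {col!r}")
    x = pd.to_numeric(df[x_col], errors="coerce")
    y = pd.to_numeric(df[y_col], errors="coerce")
    good = x.notna() & y.notna()
    n_bad = int((~good).sum())
    if n_bad:
        warnings.warn(f"skipped {n_bad} malformed occurrence row(s) in {path}")
    if not good.any():
        raise ValueError(f"no valid occurrence rows in {path}")
    out = pd.DataFrame({
        "species": df.loc[good, species_col].astype(str),
        "x": x[good],
        "y": y[good],
        "source": df[source_col][good] if source_col in df.columns else "",
        "year": df[date_col][good] if date_col in df.columns else np.nan,
    })
    if "partition" in df.columns:
        out["partition"] = df.loc[good, "partition"]
    if extent is not None:
        xmin, ymin, xmax, ymax = extent
        outside = ((out["x"] < xmin) | (out["x"] > xmax)
                   | (out["y"] < ymin) | (out["y"] > ymax))
        if outside.any():
            warnings.warn(f"{int(outside.sum())} occurrence(s) outside the "
                          "grid extent")
    return OccurrenceSet(out.reset_index(drop=True))


# ---------------------------------------------------------------------------
# polygons
# ---------------------------------------------------------------------------

def write_polygons(polygons, path, properties: list[dict] | None = None) -> None:
    """Write geometries as a GeoJSON FeatureCollection."""
    feats = []
    for i, poly in enumerate(polygons):
        props = properties[i] if properties else {"id": i}
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(poly)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)


def read_polygons(path):
    """Read geometries from a GeoJSON FeatureCollection (or geometry list)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "GeometryCollection":
        geoms = [shape(g) for g in gj["geometries"]]
    else:
        geoms = [shape(gj)]
    for i, g in enumerate(geoms):
        if not g.is_valid:
            raise ValueError(f"invalid geometry at index {i} in {path}")
    return geoms
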