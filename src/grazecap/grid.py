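"""Planar raster grid and parcel-vector primitives.

The whole pipeline works in a projected planar coordinate system with
kilometre units; the analysis grid is a regular square lattice (default
5 km cells) registered to cell centres, row-major from the north-west
corner. Rasters are written as single-band ESRI ASCII grids (``.asc``,
nodata -9999) and parcel polygons as GeoJSON with a ``parcel_id``
property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Regular square grid in projected km.

    ``xmin``/``ymax`` locate the north-west corner of the north-west
    cell; rows run north to south, columns west to east.
    """

    xmin: float
    ymax: float
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.cell_size

    @property
    def ymin(self) -> float:
        return self.ymax - self.nrows * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def cell_area(self) -> float:
        """Area of one cell in km^2."""
        return self.cell_size**2

    def x_centers(self) -> np.ndarray:
        return self.xmin + (np.arange(self.ncols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.ymax - (np.arange(self.nrows) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, shape (nrows, ncols)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point; points clipped to the grid."""
        col = np.clip(((np.asarray(x) - self.xmin) // self.cell_size).astype(int), 0, self.ncols - 1)
        row = np.clip(((self.ymax - np.asarray(y)) // self.cell_size).astype(int), 0, self.nrows - 1)
        return row, col

    @classmethod
    def from_extent(cls, extent: tuple[float, float, float, float], cell_size: float) -> "GridSpec":
        xmin, ymin, xmax, ymax = map(float, extent)
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"degenerate extent {extent!r}: xmax>xmin and ymax>ymin required")
        ncols = round((xmax - xmin) / cell_size)
        nrows = round((ymax - ymin) / cell_size)
        if ncols < 1 or nrows < 1:
            raise ValueError("extent smaller than one cell")
        if abs(ncols * cell_size - (xmax - xmin)) > 1e-9 or abs(nrows * cell_size - (ymax - ymin)) > 1e-9:
            raise ValueError("extent must be an integer multiple of cell_size")
        return cls(xmin=xmin, ymax=ymax, cell_size=cell_size, nrows=nrows, ncols=ncols)


@dataclass
class Raster:
    """A single-band float raster on a :class:`GridSpec`."""

    spec: GridSpec
    values: np.ndarray
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.spec.shape}")

    def valid_mask(self) -> np.ndarray:
        return ~np.isclose(self.values, self.nodata) & np.isfinite(self.values)

    def filled(self, fill: float = np.nan) -> np.ndarray:
        out = self.values.copy()
        out[~self.valid_mask()] = fill
        return out

    def with_values(self, values: np.ndarray) -> "Raster":
        return Raster(spec=self.spec, values=values, nodata=self.nodata)

    def sample_nearest(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Value of the cell containing each point (nodata -> nan)."""
        row, col = self.spec.cell_of(x, y)
        vals = self.values[row, col]
        bad = ~self.valid_mask()[row, col]
        vals = np.asarray(vals, dtype=float)
        vals[bad] = np.nan
        return vals

    def total(self) -> float:
        """Integral of the raster over valid cells: sum(value) * cell area."""
        return float(np.sum(self.values[self.valid_mask()]) * self.spec.cell_area)

    # ------------------------------------------------------------------ I/O

    def write_asc(self, path: str | Path) -> Path:
        path = Path(path)
        spec = self.spec
        vals = self.values.copy()
        vals[~self.valid_mask()] = self.nodata
        header = (
            f"ncols {spec.ncols}\n"
            f"nrows {spec.nrows}\n"
            f"xllcorner {float(spec.xmin):.17g}\n"
            f"yllcorner {float(spec.ymin):.17g}\n"
            f"cellsize {float(spec.cell_size):.17g}\n"
            f"NODATA_value {float(self.nodata):.17g}\n"
        )
        body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in vals)
        path.write_text(header + body + "\n")
        return path

    @classmethod
    def read_asc(cls, path: str | Path) -> "Raster":
        lines = Path(path).read_text().splitlines()
        hdr: dict[str, float] = {}
        i = 0
        while i < len(lines) and lines[i].split()[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            key, val = lines[i].split()
            hdr[key.lower()] = float(val)
            i += 1
        ncols, nrows = int(hdr["ncols"]), int(hdr["nrows"])
        cell = hdr["cellsize"]
        spec = GridSpec(
            xmin=hdr["xllcorner"],
            ymax=hdr["yllcorner"] + nrows * cell,
            cell_size=cell,
            nrows=nrows,
            ncols=ncols,
        )
        data = np.loadtxt(lines[i:], dtype=float).reshape(nrows, ncols)
        return cls(spec=spec, values=data, nodata=hdr.get("nodata_value", NODATA))


def constant_raster(spec: GridSpec, value: float) -> Raster:
    return Raster(spec=spec, values=np.full(spec.shape, float(value)))


# --------------------------------------------------------------------- parcels


def parcels_to_geojson(parcels: pd.DataFrame, path: str | Path, extra_columns: list[str] | None = None) -> Path:
    """Write a parcel table (columns ``parcel_id``, ``geometry`` + extras) as GeoJSON."""
    feats = []
    extra_columns = extra_columns or [c for c in parcels.columns if c not in ("parcel_id", "geometry")]
    for _, row in parcels.iterrows():
        props = {"parcel_id": int(row["parcel_id"])}
        for c in extra_columns:
            v = row[c]
            props[c] = v.item() if isinstance(v, np.generic) else v
        feats.append({"type": "Feature", "properties": props, "geometry": mapping(row["geometry"])})
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}, indent=1))
    return path


def parcels_from_geojson(path: str | Path) -> pd.DataFrame:
    gj = json.loads(Path(path).read_text())
    rows = []
    for feat in gj["features"]:
        props = dict(feat.get("properties") or {})
        geom: BaseGeometry = shape(feat["geometry"])
        props["geometry"] = geom
        rows.append(props)
    df = pd.DataFrame(rows)
    if "parcel_id" not in df.columns:
        raise ValueError(f"{path}: GeoJSON features lack the 'parcel_id' property")
    return df.sort_values("parcel_id").reset_index(drop=True)
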