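"""Tabular and gridded input/output, and assignment of records to the analysis grid.

All tables are plain delimited text (CSV) with documented column names.
Gridded driver layers use a "CSV raster" representation: one row per cell
with columns ``lon, lat, value`` giving the cell *centre* coordinates.
Cells absent from the file are explicitly missing, never silently NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Mandatory columns of an isotope sample table.
ISOTOPE_COLUMNS = ("species", "region", "lon", "lat", "d13c", "d15n")

#: Optional metadata carried through unchanged when present.
ISOTOPE_OPTIONAL = ("length_cm", "date")


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat analysis grid, cell-edge anchored.

    Cells are half-open intervals ``[edge, edge + cell_size)`` in both
    axes, so every in-extent point belongs to exactly one cell.  The
    default 1-degree resolution matches the scale at which isotope samples
    and longline sets are pooled.
    """

    lon0: float
    lat0: float
    cell_size: float
    n_lon: int
    n_lat: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_lon < 1 or self.n_lat < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def lon_max(self) -> float:
        return self.lon0 + self.n_lon * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.lat0 + self.n_lat * self.cell_size

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat

    def lon_centers(self) -> np.ndarray:
        return self.lon0 + (np.arange(self.n_lon) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.lat0 + (np.arange(self.n_lat) + 0.5) * self.cell_size

    def cell_index(self, lon, lat):
        """Half-open cell indices ``(ix, iy)``; -1 marks out-of-extent points."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        ix = np.floor((lon - self.lon0) / self.cell_size).astype(int)
        iy = np.floor((lat - self.lat0) / self.cell_size).astype(int)
        bad = (ix < 0) | (ix >= self.n_lon) | (iy < 0) | (iy >= self.n_lat)
        ix = np.where(bad, -1, ix)
        iy = np.where(bad, -1, iy)
        return ix, iy

    def cell_id(self, ix, iy):
        """Flat cell identifier ``iy * n_lon + ix`` (-1 stays -1)."""
        ix = np.asarray(ix)
        iy = np.asarray(iy)
        out = iy * self.n_lon + ix
        return np.where((ix < 0) | (iy < 0), -1, out)

    def cell_bounds(self, ix: int, iy: int) -> tuple[float, float, float, float]:
        """``(lon_lo, lon_hi, lat_lo, lat_hi)`` of one cell, half-open."""
        lo_lon = self.lon0 + ix * self.cell_size
        lo_lat = self.lat0 + iy * self.cell_size
        return lo_lon, lo_lon + self.cell_size, lo_lat, lo_lat + self.cell_size

    @classmethod
    def parse(cls, text: str) -> "GridSpec":
        """Parse the CLI form ``"lon0,lat0,size,nlon,nlat"``."""
        parts = text.split(",")
        if len(parts) != 5:
            raise ValueError(f"grid spec needs 5 comma-separated fields, got {text!r}")
        return cls(float(parts[0]), float(parts[1]), float(parts[2]),
                   int(parts[3]), int(parts[4]))


@dataclass
class DriverLayer:
    """One gridded driver (Chl, MLD, OPFish, fishing effort, abundance...).

    ``values`` has shape ``(n_lat, n_lon)``; ``valid`` flags cells that carry
    data.  Values of invalid cells are NaN by convention but only ``valid``
    is authoritative.
    """

    name: str
    grid: GridSpec
    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expect = (self.grid.n_lat, self.grid.n_lon)
        if self.values.shape != expect:
            raise ValueError(f"values shape {self.values.shape} != grid {expect}")
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != expect:
            raise ValueError("valid mask shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        """Long-form CSV-raster table (valid cells only)."""
        lon, lat = np.meshgrid(self.grid.lon_centers(), self.grid.lat_centers())
        m = self.valid.ravel()
        return pd.DataFrame({
            "lon": lon.ravel()[m],
            "lat": lat.ravel()[m],
            "value": self.values.ravel()[m],
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, grid: GridSpec, name: str = "") -> "DriverLayer":
        df = pd.read_csv(path)
        for col in ("lon", "lat", "value"):
            if col not in df.columns:
                raise ValueError(f"CSV raster missing column {col!r}")
        values = np.full((grid.n_lat, grid.n_lon), np.nan)
        ix, iy = grid.cell_index(df["lon"].to_numpy(), df["lat"].to_numpy())
        inside = (ix >= 0) & (iy >= 0)
        if not inside.all():
            logger.warning("%d raster rows outside grid extent dropped", (~inside).sum())
        values[iy[inside], ix[inside]] = df.loc[inside, "value"].to_numpy()
        return cls(name=name or str(path), grid=grid, values=values)


class TableValidationError(ValueError):
    """Raised when an isotope table cannot satisfy its schema."""


def read_isotope_table(path, column_map: dict | None = None):
    """Read and validate an isotope sample table.

    Parameters
    ----------
    path : str or file-like
        Delimited text with a header row.
    column_map : dict, optional
        Maps file column names to canonical names (``species, region, lon,
        lat, d13c, d15n`` plus optional ``length_cm, date``).

    Returns
    -------
    (DataFrame, list of str)
        Validated rows, and a diagnostic report for rejected rows.  Rows
        violate the schema when coordinates leave [-180, 180] x [-90, 90]
        or an isotope value is missing/non-finite; each rejection names
        the 1-based data line.

    Raises
    ------
    TableValidationError
        If a mandatory column is absent.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in ISOTOPE_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"missing mandatory columns: {missing}")

    errors: list[str] = []
    for col in ("lon", "lat", "d13c", "d15n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    bad = pd.Series(False, index=df.index)
    checks = [
        (~np.isfinite(df["d13c"]), "d13c not finite"),
        (~np.isfinite(df["d15n"]), "d15n not finite"),
        (~df["lat"].between(-90, 90) | ~np.isfinite(df["lat"]), "lat outside [-90, 90]"),
        (~df["lon"].between(-180, 180) | ~np.isfinite(df["lon"]), "lon outside [-180, 180]"),
    ]
    for mask, msg in checks:
        for idx in df.index[mask & ~bad]:
            errors.append(f"line {idx + 1}: {msg}")
        bad |= mask

    keep = [c for c in ISOTOPE_COLUMNS + ISOTOPE_OPTIONAL if c in df.columns]
    out = df.loc[~bad, keep].reset_index(drop=True)
    return out, errors


def write_isotope_table(df: pd.DataFrame, path) -> None:
    """Write an isotope table so that ``read_isotope_table`` round-trips it.

    Float columns use repr-precision formatting, so finite values survive
    the text round trip bit-exactly.
    """
    df.to_csv(path, index=False)


def assign_to_grid(df: pd.DataFrame, grid: GridSpec,
                   lon_col: str = "lon", lat_col: str = "lat") -> pd.DataFrame:
    """Attach half-open grid-cell indices to a table of located records.

    Adds ``cell_ix``, ``cell_iy`` and flat ``cell_id`` columns.  Points
    outside the grid extent are excluded from the result with a logged
    warning.  Idempotent: re-assigning an already assigned table yields
    the same cells.
    """
    lon = df[lon_col].to_numpy(dtype=float)
    lat = df[lat_col].to_numpy(dtype=float)
    ix, iy = grid.cell_index(lon, lat)
    inside = (ix >= 0) & (iy >= 0)
    if not inside.all():
        logger.warning("assign_to_grid: %d of %d records outside grid extent excluded",
                       int((~inside).sum()), len(df))
    out = df.loc[inside].copy()
    out["cell_ix"] = ix[inside]
    out["cell_iy"] = iy[inside]
    out["cell_id"] = grid.cell_id(ix[inside], iy[inside])
    return out


def temporal_mean_layer(layers: list[DriverLayer], how: str = "mean") -> DriverLayer:
    """Aggregate monthly layers over the temporal window.

    Environmental drivers are averaged per cell over the months where the
    cell carries data; cumulative fishing effort is summed instead
    (``how="sum"``).  All layers must share the same grid.
    """
    if not layers:
        raise ValueError("no layers given")
    grid = layers[0].grid
    for lay in layers[1:]:
        if lay.grid != grid:
            raise ValueError("layers are on different grids")
    stack = np.stack([np.where(l.valid, l.values, np.nan) for l in layers])
    with np.errstate(invalid="ignore"):
        if how == "mean":
            agg = np.nanmean(stack, axis=0)
        elif how == "sum":
            agg = np.nansum(stack, axis=0)
            agg[np.all(np.isnan(stack), axis=0)] = np.nan
        else:
            raise ValueError(f"unknown aggregation {how!r}")
    return DriverLayer(name=layers[0].name, grid=grid, values=agg)
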