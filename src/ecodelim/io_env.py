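"""Occurrence and environmental-raster input.

Occurrence records are georeferenced, lineage-labelled collection points
(CSV with header ``lineage,lon,lat[,year]``).  Environmental layers are
read as an :class:`EnvRasterStack` of co-registered grids (ESRI ASCII
grid format, one file per variable); each record's environmental vector
is the cell value under its coordinate.

Record filtering follows standard distribution-data hygiene: records
collected before a cutoff year (default 1990) are dropped to avoid
identification problems in older collections, and variable collinearity
is screened so that no retained pair exceeds a Pearson |r| threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OCC_COLUMNS = ("lineage", "lon", "lat")


@dataclass
class EnvRasterStack:
    """Co-registered environmental grids sharing one extent and cell size.

    Parameters
    ----------
    variables
        Ordered variable names, one per layer.
    grids
        Array of shape ``(n_vars, nrows, ncols)``; row 0 is the
        northernmost row (ESRI ASCII convention).
    xmin, ymin
        Coordinates of the lower-left corner of the extent.
    cellsize
        Cell edge length in coordinate units.
    nodata_mask
        Boolean ``(nrows, ncols)`` array, True where any layer is nodata.
    """

    variables: list[str]
    grids: np.ndarray
    xmin: float
    ymin: float
    cellsize: float
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.grids = np.asarray(self.grids, dtype=float)
        if self.grids.ndim != 3 or self.grids.shape[0] != len(self.variables):
            raise ValueError("grids must be (n_vars, nrows, ncols) matching variables")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.grids).all(axis=0)
        # mask consistently across layers
        self.grids[:, self.nodata_mask] = np.nan

    @property
    def shape(self) -> tuple[int, int]:
        return self.grids.shape[1], self.grids.shape[2]

    @property
    def xmax(self) -> float:
        return self.xmin + self.cellsize * self.grids.shape[2]

    @property
    def ymax(self) -> float:
        return self.ymin + self.cellsize * self.grids.shape[1]

    def cell_index(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the cell containing each point.

        Cell membership is half-open, [west, east) x [south, north);
        points exactly on the east/north boundary fall in the last cell.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        nrows, ncols = self.shape
        col = np.floor((lon - self.xmin) / self.cellsize).astype(int)
        row_from_bottom = np.floor((lat - self.ymin) / self.cellsize).astype(int)
        # boundary points belong to the last cell
        col = np.where((lon == self.xmax), ncols - 1, col)
        row_from_bottom = np.where((lat == self.ymax), nrows - 1, row_from_bottom)
        row = nrows - 1 - row_from_bottom
        return row, col

    def background_env(self) -> np.ndarray:
        """Environmental matrix of all valid cells, shape (n_cells, n_vars)."""
        valid = ~self.nodata_mask
        return np.column_stack([g[valid] for g in self.grids])


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float, float, float]:
    """Read one ESRI ASCII grid; returns (array, xmin, ymin, cellsize, nodata)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {key!r}")
    arr = np.loadtxt(lines[n_header:], dtype=float, ndmin=2)
    if arr.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: data shape {arr.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value", -9999.0)
    arr = np.where(arr == nodata, np.nan, arr)
    return arr, header["xllcorner"], header["yllcorner"], header["cellsize"], nodata


def write_ascii_grid(
    path: str | Path,
    array: np.ndarray,
    xmin: float,
    ymin: float,
    cellsize: float,
    nodata: float = -9999.0,
) -> None:
    array = np.asarray(array, dtype=float)
    nrows, ncols = array.shape
    out = np.where(np.isfinite(array), array, nodata)
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {xmin}\nyllcorner {ymin}\n"
            f"cellsize {cellsize}\nNODATA_value {nodata}\n"
        )
        np.savetxt(fh, out, fmt="%.8g")


def read_rasters(paths: Sequence[str | Path], variables: Sequence[str] | None = None) -> EnvRasterStack:
    """Read a stack of ESRI ASCII grids; all layers must be co-registered."""
    if not paths:
        raise ValueError("no raster paths given")
    arrays = []
    geo = None
    for p in paths:
        arr, xmin, ymin, cs, _ = read_ascii_grid(p)
        if geo is None:
            geo = (arr.shape, xmin, ymin, cs)
        elif (arr.shape, xmin, ymin, cs) != geo:
            raise ValueError(
                f"{p}: extent/resolution {(arr.shape, xmin, ymin, cs)} "
                f"differs from first layer {geo}"
            )
        arrays.append(arr)
    names = list(variables) if variables else [Path(p).stem for p in paths]
    return EnvRasterStack(names, np.stack(arrays), geo[1], geo[2], geo[3])


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Read occurrence records from CSV with header ``lineage,lon,lat[,year]``.

    Returns a DataFrame with columns lineage (str), lon, lat (float),
    year (nullable integer).  Rows with unparseable or out-of-range
    coordinates raise, naming the offending row (1-based data row).
    """
    df = pd.read_csv(path, dtype={"lineage": str})
    missing = [c for c in OCC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: empty occurrence file", path)
        df["year"] = pd.Series(dtype="Int64")
        return df[["lineage", "lon", "lat", "year"]]
    for col, lo, hi in (("lon", -180.0, 180.0), ("lat", -90.0, 90.0)):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < lo) | (vals > hi)
        if bad.any():
            rows = (df.index[bad] + 1).tolist()
            raise ValueError(f"{path}: invalid {col} in data row(s) {rows}")
        df[col] = vals.astype(float)
    if "year" in df.columns:
        df["year"] = pd.to_numeric(df["year"], errors="coerce").astype("Int64")
    else:
        df["year"] = pd.Series([pd.NA] * len(df), dtype="Int64")
    return df[["lineage", "lon", "lat", "year"]]


def filter_by_year(records: pd.DataFrame, min_year: int = 1990) -> pd.DataFrame:
    """Drop records collected strictly before ``min_year``.

    Records with a missing year are retained: the year cutoff targets
    identification reliability of old, dated collections, and discarding
    undated herbarium material would silently bias sampling.
    """
    if "year" not in records.columns:
        return records.copy()
    year = records["year"]
    keep = year.isna() | (year >= min_year)
    n_missing = int(year.isna().sum())
    if n_missing:
        logger.info("filter_by_year: %d records with missing year retained", n_missing)
    out = records[keep].reset_index(drop=True)
    logger.info("filter_by_year: %d of %d records retained", len(out), len(records))
    return out


def extract_env(records: pd.DataFrame, rasters: EnvRasterStack) -> pd.DataFrame:
    """Attach an environmental vector to each record from the raster stack.

    Records on nodata cells are dropped (and counted in the log).
    Records outside the raster extent raise, listing the offenders.
    """
    lon = records["lon"].to_numpy(dtype=float)
    lat = records["lat"].to_numpy(dtype=float)
    outside = (
        (lon < rasters.xmin) | (lon > rasters.xmax)
        | (lat < rasters.ymin) | (lat > rasters.ymax)
    )
    if outside.any():
        rows = (records.index[outside] + 1).tolist()
        raise ValueError(f"records outside raster extent: data row(s) {rows}")
    row, col = rasters.cell_index(lon, lat)
    env = rasters.grids[:, row, col].T  # (n_records, n_vars)
    out = records.copy().reset_index(drop=True)
    for j, name in enumerate(rasters.variables):
        out[name] = env[:, j]
    on_nodata = rasters.nodata_mask[row, col]
    if on_nodata.any():
        logger.info("extract_env: %d records on nodata cells dropped", int(on_nodata.sum()))
        out = out[~on_nodata].reset_index(drop=True)
    return out


def dedupe_by_cell(records: pd.DataFrame, rasters: EnvRasterStack) -> pd.DataFrame:
    """Collapse duplicates to one occurrence per (lineage, raster cell).

    Standard practice before density estimation on gridded environments:
    repeated collections from one cell carry no extra environmental
    information and would inflate local density.
    """
    row, col = rasters.cell_index(
        records["lon"].to_numpy(dtype=float), records["lat"].to_numpy(dtype=float)
    )
    key = pd.DataFrame({"lineage": records["lineage"].to_numpy(), "_r": row, "_c": col})
    first = ~key.duplicated()
    out = records[first.to_numpy()].reset_index(drop=True)
    logger.info("dedupe_by_cell: %d of %d records retained", len(out), len(records))
    return out


def screen_collinearity(
    env_matrix: pd.DataFrame | np.ndarray,
    threshold: float = 0.70,
    variables: Sequence[str] | None = None,
) -> list[str]:
    """Greedily drop variables until all pairwise Pearson |r| <= threshold.

    At each step the variable with the largest mean |r| among currently
    offending pairs is removed; ties break on input column order, so the
    result is deterministic.
    """
    if isinstance(env_matrix, pd.DataFrame):
        names = list(env_matrix.columns)
        X = env_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(env_matrix, dtype=float)
        names = list(variables) if variables else [f"var{i}" for i in range(X.shape[1])]
    X = X[np.isfinite(X).all(axis=1)]
    if X.shape[0] < 2:
        raise ValueError("screen_collinearity needs at least 2 complete records")
    if X.shape[1] < 2:
        return names
    keep = list(range(X.shape[1]))
    while True:
        R = np.abs(np.corrcoef(X[:, keep], rowvar=False))
        np.fill_diagonal(R, 0.0)
        offending = R > threshold
        if not offending.any():
            break
        # mean |r| over offending pairs only, per variable
        score = np.where(offending, R, 0.0).sum(axis=1) / np.maximum(offending.sum(axis=1), 1)
        score = np.where(offending.any(axis=1), score, -np.inf)
        # ties drop the later-ordered variable, keeping the input priority order
        drop_local = int(np.flatnonzero(score == score.max())[-1])
        dropped = keep.pop(drop_local)
        logger.info("screen_collinearity: dropped %s", names[dropped])
        if len(keep) < 2:
            break
    return [names[i] for i in keep]
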