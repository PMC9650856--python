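"""Gridded landscape covariates: NDVI anomaly and change, terrain ruggedness,
bilinear resampling, and extraction at step endpoints.

Grids are 2-D arrays on a north-up, axis-aligned projected raster: row 0 is
the northernmost row, ``x0``/``y0`` are the west and north edges and ``cell``
the square cell size in metres.  No-data is NaN in memory and a sentinel value
on disk.  On-disk format is the plain-text ESRI ASCII grid (.asc); a
time-indexed layer is a set of ``<name>_YYYYMMDD.asc`` files.

Derived covariates:

* dNDVI — 16-day change in greenness, ``NDVI_t - NDVI_{t-16}``.
* aNDVI — greenness anomaly, current NDVI minus a multi-year baseline mean.
  By default the baseline is the per-composite-slot mean (the long-term
  seasonal cycle); a grand 4-year mean is available via ``mode="grand"``.
* TRI — terrain ruggedness index, the root of the summed squared elevation
  differences between a cell and its 8 neighbours; border cells use the
  neighbours that exist.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CoverageError, DataError

logger = logging.getLogger(__name__)

NODATA = -9999.0


@dataclass
class Grid:
    """A single-band raster: values (NaN = no-data), west/north origin, cell size."""

    values: np.ndarray
    x0: float
    y0: float
    cell: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("grid values must be 2-D")
        if self.cell <= 0:
            raise ConfigurationError("cell size must be positive")

    @property
    def shape(self):
        return self.values.shape

    def same_transform(self, other: "Grid") -> bool:
        return (self.shape == other.shape and self.cell == other.cell
                and self.x0 == other.x0 and self.y0 == other.y0)

    def cell_centers(self):
        """(x, y) 1-D arrays of column / row cell-centre coordinates."""
        nr, nc = self.shape
        xs = self.x0 + (np.arange(nc) + 0.5) * self.cell
        ys = self.y0 - (np.arange(nr) + 0.5) * self.cell
        return xs, ys

    def index_of(self, x, y):
        """Nearest-cell (row, col) indices for projected points."""
        col = np.floor((np.asarray(x, dtype=float) - self.x0) / self.cell).astype(int)
        row = np.floor((self.y0 - np.asarray(y, dtype=float)) / self.cell).astype(int)
        return row, col

    def value_at(self, x, y, method: str = "nearest"):
        """Sample the grid at projected points; outside the extent -> NaN."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if method == "nearest":
            row, col = self.index_of(x, y)
            nr, nc = self.shape
            ok = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
            out = np.full(x.shape, np.nan)
            out[ok] = self.values[row[ok], col[ok]]
            return out
        if method == "bilinear":
            return _bilinear_sample(self, x, y)
        raise ConfigurationError(f"unknown sampling method {method!r}")


def _bilinear_sample(grid: Grid, x, y):
    """Bilinear interpolation at points, no-data excluded with renormalised weights.

    Fractional indices are clamped to the cell-centre lattice so points between
    the outer cell centre and the grid edge take edge values; points beyond the
    grid extent return NaN.
    """
    nr, nc = grid.shape
    inside = ((x >= grid.x0) & (x <= grid.x0 + nc * grid.cell)
              & (y <= grid.y0) & (y >= grid.y0 - nr * grid.cell))
    fc = (x - grid.x0) / grid.cell - 0.5
    fr = (grid.y0 - y) / grid.cell - 0.5
    fc = np.clip(fc, 0.0, nc - 1.0)
    fr = np.clip(fr, 0.0, nr - 1.0)
    c0 = np.clip(np.floor(fc).astype(int), 0, nc - 2) if nc > 1 else np.zeros_like(fc, int)
    r0 = np.clip(np.floor(fr).astype(int), 0, nr - 2) if nr > 1 else np.zeros_like(fr, int)
    tc = fc - c0
    tr = fr - r0
    c1 = np.minimum(c0 + 1, nc - 1)
    r1 = np.minimum(r0 + 1, nr - 1)

    vals = np.stack([grid.values[r0, c0], grid.values[r0, c1],
                     grid.values[r1, c0], grid.values[r1, c1]])
    wts = np.stack([(1 - tr) * (1 - tc), (1 - tr) * tc, tr * (1 - tc), tr * tc])
    valid = np.isfinite(vals)
    wts = np.where(valid, wts, 0.0)
    wsum = wts.sum(axis=0)
    out = np.where(wsum > 0, np.nansum(wts * vals, axis=0) / np.where(wsum > 0, wsum, 1.0),
                   np.nan)
    return np.where(inside, out, np.nan)


def write_ascii_grid(grid: Grid, path) -> None:
    """Write a grid as an ESRI ASCII raster (plain text)."""
    nr, nc = grid.shape
    vals = np.where(np.isfinite(grid.values), grid.values, NODATA)
    header = (f"ncols {nc}\nnrows {nr}\n"
              f"xllcorner {grid.x0:.6f}\nyllcorner {grid.y0 - nr * grid.cell:.6f}\n"
              f"cellsize {grid.cell:.6f}\nNODATA_value {NODATA:.1f}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.6g")


def read_ascii_grid(path) -> Grid:
    """Read an ESRI ASCII raster."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines) and re.match(r"^[A-Za-z_]", lines[i]):
        key, val = lines[i].split()
        header[key.lower()] = float(val)
        i += 1
    try:
        nc, nr = int(header["ncols"]), int(header["nrows"])
        cell = header["cellsize"]
        x0 = header["xllcorner"]
        y0 = header["yllcorner"] + nr * cell
    except KeyError as exc:
        raise DataError(f"ASCII grid {path} is missing header field {exc}") from exc
    vals = np.loadtxt(lines[i:]).reshape(nr, nc)
    nodata = header.get("nodata_value", NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    return Grid(vals, x0=x0, y0=y0, cell=cell)


@dataclass
class GridSeries:
    """A time-indexed stack of co-registered grids (e.g. 16-day NDVI composites)."""

    dates: list[pd.Timestamp]
    grids: list[Grid]

    def __post_init__(self):
        self.dates = [pd.Timestamp(d) for d in self.dates]
        if len(self.dates) != len(self.grids):
            raise ConfigurationError("dates and grids must align")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ConfigurationError("composite dates must be strictly increasing")
        ref = self.grids[0] if self.grids else None
        if ref is not None and not all(g.same_transform(ref) for g in self.grids):
            raise ConfigurationError("all grids in a series must share one transform")

    def __len__(self):
        return len(self.grids)

    def layer_index_for(self, timestamps) -> np.ndarray:
        """Index of the most recent composite at or before each timestamp."""
        ts = np.asarray(pd.DatetimeIndex(np.atleast_1d(timestamps)).values)
        dates = np.asarray(pd.DatetimeIndex(self.dates).values)
        idx = np.searchsorted(dates, ts, side="right") - 1
        if (idx < 0).any():
            first = pd.Timestamp(dates[0])
            raise CoverageError(f"timestamp(s) precede first composite {first.date()}")
        return idx

    def layer_for(self, timestamp) -> Grid:
        return self.grids[int(self.layer_index_for(timestamp)[0])]

    def write(self, directory, name: str) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for d, g in zip(self.dates, self.grids):
            write_ascii_grid(g, directory / f"{name}_{d.strftime('%Y%m%d')}.asc")

    @classmethod
    def read(cls, directory, name: str) -> "GridSeries":
        paths = sorted(Path(directory).glob(f"{name}_*.asc"))
        if not paths:
            raise DataError(f"no {name}_YYYYMMDD.asc files under {directory}")
        dates = [pd.Timestamp(re.search(r"_(\d{8})\.asc$", p.name).group(1)) for p in paths]
        return cls(dates=dates, grids=[read_ascii_grid(p) for p in paths])


@dataclass
class LandscapeStack:
    """All covariate layers co-registered at the analysis resolution."""

    andvi: GridSeries
    dndvi: GridSeries
    elevation: Grid
    tri: Grid
    temperature: GridSeries
    ndvi: GridSeries | None = field(default=None, repr=False)


def _check_coregistered(series: GridSeries) -> None:
    ref = series.grids[0]
    if not all(g.same_transform(ref) for g in series.grids):
        raise ConfigurationError("series grids are not co-registered")


def compute_dndvi(series: GridSeries) -> GridSeries:
    """16-day NDVI change: for each composite with a predecessor, NDVI_t - NDVI_{t-1 composite}."""
    if len(series) < 2:
        raise DataError("dNDVI needs at least 2 composites")
    _check_coregistered(series)
    grids = [Grid(b.values - a.values, x0=b.x0, y0=b.y0, cell=b.cell)
             for a, b in zip(series.grids, series.grids[1:])]
    return GridSeries(dates=series.dates[1:], grids=grids)


def composite_slot(date) -> int:
    """16-day composite slot within the calendar year (0..22)."""
    return (pd.Timestamp(date).dayofyear - 1) // 16


def compute_andvi(series: GridSeries, baseline_start, baseline_end,
                  mode: str = "slot") -> GridSeries:
    """NDVI anomaly relative to a multi-year baseline.

    ``mode="slot"`` (default): each composite is compared with the mean of
    baseline composites in the same 16-day slot of the year, i.e. the anomaly
    is relative to the long-term seasonal cycle.  ``mode="grand"`` compares
    with the single mean over all baseline composites.
    """
    baseline_start = pd.Timestamp(baseline_start)
    baseline_end = pd.Timestamp(baseline_end)
    _check_coregistered(series)
    in_base = [baseline_start <= d <= baseline_end for d in series.dates]
    if not any(in_base):
        raise DataError("no composites fall inside the baseline window")

    ref = series.grids[0]
    if mode == "grand":
        base = np.mean([g.values for g, b in zip(series.grids, in_base) if b], axis=0)
        means = {slot: base for slot in range(23)}
    elif mode == "slot":
        means = {}
        for slot in {composite_slot(d) for d in series.dates}:
            members = [g.values for g, d, b in zip(series.grids, series.dates, in_base)
                       if b and composite_slot(d) == slot]
            if not members:
                raise DataError(f"baseline window has no composite in slot {slot}")
            means[slot] = np.mean(members, axis=0)
    else:
        raise ConfigurationError(f"unknown aNDVI mode {mode!r}")

    grids = [Grid(g.values - means[composite_slot(d)], x0=ref.x0, y0=ref.y0, cell=ref.cell)
             for d, g in zip(series.dates, series.grids)]
    return GridSeries(dates=list(series.dates), grids=grids)


def compute_tri(elevation: Grid) -> Grid:
    """Terrain ruggedness index (root-sum-of-squares over the 8 neighbours)."""
    z = elevation.values
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise DataError("TRI needs an elevation grid of at least 3 x 3")
    padded = np.pad(z, 1, constant_values=np.nan)
    sq = np.zeros_like(z)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = padded[1 + dr: 1 + dr + z.shape[0], 1 + dc: 1 + dc + z.shape[1]]
            diff = nb - z
            sq += np.where(np.isfinite(diff), diff ** 2, 0.0)
    tri = np.sqrt(sq)
    tri[~np.isfinite(z)] = np.nan
    return Grid(tri, x0=elevation.x0, y0=elevation.y0, cell=elevation.cell)


def resample_bilinear(grid: Grid, target_cell: float = 500.0) -> Grid:
    """Resample a grid to a coarser/finer cell size by bilinear interpolation.

    The target raster covers the source extent; values are interpolated at
    target cell centres with no-data cells dropped and weights renormalised.
    """
    if target_cell <= 0:
        raise ConfigurationError("target cell size must be positive")
    nr, nc = grid.shape
    width, height = nc * grid.cell, nr * grid.cell
    nct = max(1, int(round(width / target_cell)))
    nrt = max(1, int(round(height / target_cell)))
    out = Grid(np.empty((nrt, nct)), x0=grid.x0, y0=grid.y0, cell=target_cell)
    xs, ys = out.cell_centers()
    xx, yy = np.meshgrid(xs, ys)
    out.values = _bilinear_sample(grid, xx.ravel(), yy.ravel()).reshape(nrt, nct)
    return out


def extract_covariates(strata: pd.DataFrame, stack: LandscapeStack,
                       method: str = "nearest") -> pd.DataFrame:
    """Attach covariate values at step endpoints; drop incomplete strata whole.

    For each stratum row the aNDVI/dNDVI/temperature layer whose composite
    interval contains the step-end timestamp (most recent composite at or
    before it, no look-ahead) is sampled at (x2, y2), together with the static
    elevation and TRI grids.  Any row with a missing value flags its whole
    stratum, which is dropped so every retained stratum keeps its full
    1 used : n available balance.
    """
    out = strata.copy()
    x = out["x2"].to_numpy(dtype=float)
    y = out["y2"].to_numpy(dtype=float)
    t = out["t_end"].to_numpy()

    for name, series in (("aNDVI", stack.andvi), ("dNDVI", stack.dndvi),
                         ("temperature", stack.temperature)):
        idx = series.layer_index_for(t)
        vals = np.full(len(out), np.nan)
        for li in np.unique(idx):
            sel = idx == li
            vals[sel] = series.grids[int(li)].value_at(x[sel], y[sel], method=method)
        out[name] = vals
    out["elevation"] = stack.elevation.value_at(x, y, method=method)
    out["TRI"] = stack.tri.value_at(x, y, method=method)

    cov_cols = ["aNDVI", "dNDVI", "elevation", "TRI", "temperature"]
    bad_rows = ~np.isfinite(out[cov_cols].to_numpy(dtype=float)).all(axis=1)
    bad_strata = set(out.loc[bad_rows, "stratum_id"])
    if bad_strata:
        logger.info("extract_covariates: dropping %d stratum(a) with missing covariates",
                    len(bad_strata))
        out = out[~out["stratum_id"].isin(bad_strata)]
    return out.reset_index(drop=True)
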