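"""Geographic primitives: rasters, great-circle distance, thinning, IDW, bias grids.

Rasters are regular lon/lat grids with a cell-center coordinate
convention; point-in-cell assignment is half-open [west, east) x
[south, north).  I/O uses the ESRI ASCII grid text format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "GridRaster",
    "OccurrenceSet",
    "great_circle_km",
    "spatial_rarefy",
    "gaussian_bias_grid",
    "idw_surface",
    "correlation_prune",
    "read_ascii_grid",
    "read_occurrences",
    "write_occurrences",
]


@dataclass
class GridRaster:
    """Regular lon/lat grid; row 0 is the northernmost row.

    ``xll``/``yll`` locate the lower-left *corner* of the grid; values
    are attributed to cell centers.
    """

    xll: float
    yll: float
    cellsize: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def valid(self) -> np.ndarray:
        return (self.values != self.nodata) & np.isfinite(self.values)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols)."""
        lon = self.xll + (np.arange(self.n_cols) + 0.5) * self.cellsize
        lat = self.yll + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cellsize
        return np.meshgrid(lon, lat)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) containing the point, or None if outside the grid."""
        col = int(np.floor((lon - self.xll) / self.cellsize))
        row_from_bottom = int(np.floor((lat - self.yll) / self.cellsize))
        row = self.n_rows - 1 - row_from_bottom
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def like(self, values: np.ndarray) -> "GridRaster":
        return GridRaster(self.xll, self.yll, self.cellsize,
                          np.asarray(values, dtype=float), self.nodata)

    def same_grid(self, other: "GridRaster") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def write_ascii(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.n_cols}\n")
            fh.write(f"nrows {self.n_rows}\n")
            fh.write(f"xllcorner {float(self.xll)!r}\n")
            fh.write(f"yllcorner {float(self.yll)!r}\n")
            fh.write(f"cellsize {float(self.cellsize)!r}\n")
            fh.write(f"NODATA_value {float(self.nodata)!r}\n")
            vals = np.where(np.isfinite(self.values), self.values, self.nodata)
            for row in vals:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> GridRaster:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if not toks:
                continue
            if len(toks) == 2 and toks[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            }:
                header[toks[0].lower()] = float(toks[1])
            else:
                rows.append([float(t) for t in toks])
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid dimensions disagree with header")
    return GridRaster(
        xll=header["xllcorner"], yll=header["yllcorner"],
        cellsize=header["cellsize"], values=values,
        nodata=header.get("nodata_value", -9999.0),
    )


@dataclass
class OccurrenceSet:
    ids: list[str]
    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if len(self.ids) != len(self.lon) or len(self.lon) != len(self.lat):
            raise ValueError("id/lon/lat length mismatch")
        if np.any(np.abs(self.lat) > 90) or np.any(np.abs(self.lon) > 180):
            raise ValueError("coordinates out of range")

    def __len__(self) -> int:
        return len(self.ids)

    def drop_duplicates(self) -> "OccurrenceSet":
        """Remove exact (lon, lat) duplicates, keeping the first record."""
        seen: set[tuple[float, float]] = set()
        keep = []
        for i, (x, y) in enumerate(zip(self.lon, self.lat)):
            key = (float(x), float(y))
            if key not in seen:
                seen.add(key)
                keep.append(i)
        return self.subset(keep)

    def subset(self, idx) -> "OccurrenceSet":
        idx = list(idx)
        return OccurrenceSet(
            [self.ids[i] for i in idx], self.lon[idx], self.lat[idx]
        )


def read_occurrences(path) -> OccurrenceSet:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    idc = cols.get("id", df.columns[0])
    return OccurrenceSet(
        df[idc].astype(str).tolist(),
        df[cols["lon"]].to_numpy(float),
        df[cols["lat"]].to_numpy(float),
    )


def write_occurrences(occ: OccurrenceSet, path) -> None:
    pd.DataFrame({"id": occ.ids, "lon": occ.lon, "lat": occ.lat}).to_csv(
        path, index=False
    )


def great_circle_km(p1, p2) -> float:
    """Haversine distance in km between (lon, lat) points on a 6371-km sphere."""
    lon1, lat1 = np.radians(np.asarray(p1, dtype=float))
    lon2, lat2 = np.radians(np.asarray(p2, dtype=float))
    h = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def _pairwise_km(lon: np.ndarray, lat: np.ndarray,
                 lon2: np.ndarray | None = None,
                 lat2: np.ndarray | None = None) -> np.ndarray:
    la1 = np.radians(lat)[:, None]
    lo1 = np.radians(lon)[:, None]
    la2 = np.radians(lat if lat2 is None else lat2)[None, :]
    lo2 = np.radians(lon if lon2 is None else lon2)[None, :]
    h = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(
        (lo2 - lo1) / 2
    ) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def spatial_rarefy(occ: OccurrenceSet, r_km: float) -> OccurrenceSet:
    """Thin occurrences so no retained pair lies closer than ``r_km``.

    Greedy heuristic: exact coordinate duplicates are removed first, then
    the point with the most neighbors within ``r_km`` is deleted
    repeatedly (ties broken by lowest record index) until the remainder
    is an independent set.
    """
    if len(occ) == 0:
        raise ValueError("empty occurrence set")
    if r_km <= 0:
        raise ValueError("r_km must be positive")
    occ = occ.drop_duplicates()
    d = _pairwise_km(occ.lon, occ.lat)
    np.fill_diagonal(d, np.inf)
    alive = np.ones(len(occ), dtype=bool)
    neigh = d < r_km
    while True:
        counts = (neigh & alive[None, :] & alive[:, None]).sum(axis=1)
        counts[~alive] = 0
        worst = int(np.argmax(counts))  # argmax takes the lowest index on ties
        if counts[worst] == 0:
            break
        alive[worst] = False
    return occ.subset(np.where(alive)[0])


def gaussian_bias_grid(occ: OccurrenceSet, template: GridRaster,
                       bandwidth_km: float | None = None,
                       max_bias: float | None = None) -> GridRaster:
    """Gaussian kernel density of occurrences, rescaled so the minimum is 1.

    Kernels are isotropic in great-circle distance.  ``bandwidth_km``
    defaults to the mean nearest-neighbor distance of the occurrences.
    By default the density is shifted linearly so its minimum over valid
    cells is exactly 1; passing ``max_bias`` instead maps
    [min, max] -> [1, max_bias] linearly.
    """
    if not template.valid.any():
        raise ValueError("template raster has no valid cells")
    if bandwidth_km is None:
        d = _pairwise_km(occ.lon, occ.lat)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        bandwidth_km = float(np.mean(nn[np.isfinite(nn)])) if len(occ) > 1 else 100.0
        logger.info("bias bandwidth defaulted to %.2f km", bandwidth_km)
    if bandwidth_km <= 0:
        raise ValueError("bandwidth must be positive")
    lon_g, lat_g = template.cell_centers()
    valid = template.valid
    d = _pairwise_km(lon_g[valid].ravel(), lat_g[valid].ravel(), occ.lon, occ.lat)
    dens = np.exp(-0.5 * (d / bandwidth_km) ** 2).sum(axis=1)
    lo, hi = dens.min(), dens.max()
    if max_bias is not None and hi > lo:
        scaled = 1.0 + (dens - lo) * (max_bias - 1.0) / (hi - lo)
    else:
        scaled = dens - lo + 1.0
    out = np.full(template.values.shape, template.nodata)
    out[valid] = scaled
    return template.like(out)


def idw_surface(points: OccurrenceSet, values: np.ndarray, template: GridRaster,
                power: float = 2.0) -> GridRaster:
    """Inverse-distance-weighted interpolation onto the template grid.

    At a cell center coinciding with a data point the value is returned
    exactly; the surface is bounded by the input value range.
    """
    if len(points) == 0:
        raise ValueError("need at least one point")
    values = np.asarray(values, dtype=float)
    lon_g, lat_g = template.cell_centers()
    valid = template.valid
    d = _pairwise_km(lon_g[valid].ravel(), lat_g[valid].ravel(), points.lon, points.lat)
    out_vals = np.empty(d.shape[0])
    zero = d <= 1e-12
    has_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[~np.isfinite(w)] = 0.0
    denom = w.sum(axis=1)
    denom[denom == 0] = 1.0
    out_vals[:] = (w @ values) / denom
    for i in np.where(has_zero)[0]:
        out_vals[i] = values[np.argmax(zero[i])]
    out = np.full(template.values.shape, template.nodata)
    out[valid] = out_vals
    return template.like(out)


def correlation_prune(stack: dict[str, GridRaster], threshold: float = 0.7
                      ) -> list[str]:
    """Drop layers until no pair has |Pearson r| above ``threshold``.

    Iteratively removes the layer with the most offending partners, ties
    broken by largest mean |r|; correlations use jointly valid cells.
    Constant layers (undefined r) are dropped first with a warning.
    """
    names = list(stack)
    if len(names) < 2:
        raise ValueError("need at least two layers")
    first = stack[names[0]]
    for nm in names[1:]:
        if not first.same_grid(stack[nm]):
            raise ValueError(f"layer {nm!r} is not on the template grid")
    joint = np.ones(first.values.shape, dtype=bool)
    for nm in names:
        joint &= stack[nm].valid
    data = {nm: stack[nm].values[joint] for nm in names}
    keep = []
    for nm in names:
        if np.std(data[nm]) == 0:
            logger.warning("constant layer %r dropped (correlation undefined)", nm)
        else:
            keep.append(nm)
    while True:
        k = len(keep)
        if k < 2:
            break
        mat = np.corrcoef(np.array([data[nm] for nm in keep]))
        absr = np.abs(mat)
        np.fill_diagonal(absr, 0.0)
        offend = (absr > threshold).sum(axis=1)
        if offend.max() == 0:
            break
        worst = np.where(offend == offend.max())[0]
        if len(worst) > 1:
            worst = worst[np.argsort(-absr[worst].mean(axis=1), kind="stable")[:1]]
        drop = keep[int(worst[0])]
        logger.info("dropping layer %r (%d correlations > %.2f)", drop,
                    int(offend.max()), threshold)
        keep.remove(drop)
    return keep
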