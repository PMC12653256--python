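"""Fishnet gridding of endpoints and natural-neighbour surfaces.

Valid takeoff endpoints are counted on a regular lat/lon fishnet
(0.5 x 0.5 degrees by default, half-open cells ``[edge, edge+size)``)
and normalised to a per-endpoint-set probability distribution.  The
probabilities at non-empty cell centroids are then interpolated with
Sibson's natural-neighbour method: the weight of each data site is the
Voronoi area the query point "steals" from that site's cell when it is
inserted into the diagram.  Queries outside the convex hull of the data
sites are returned as NaN rather than extrapolated.

A barycentric linear fallback (``method='linear'``) is provided for
robustness comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .trajectory import Endpoint

__all__ = [
    "DensityGrid",
    "DegenerateGeometryError",
    "fishnet_counts",
    "natural_neighbor_surface",
    "sibson_weights",
]


class DegenerateGeometryError(ValueError):
    """Raised when interpolation geometry is degenerate (collinear/too few)."""


@dataclass
class DensityGrid:
    """Counts of endpoints per fishnet cell, with probabilities.

    ``counts`` maps (row, col) -> count where row/col index latitude and
    longitude offsets from ``origin`` in units of ``cell_size``.
    """

    cell_size: float
    origin: tuple[float, float]  # (lat0, lon0) of the grid's lower-left edge
    counts: dict

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def probs(self) -> dict:
        tot = self.total
        if tot == 0:
            return {}
        return {k: c / tot for k, c in self.counts.items()}

    def cell_centroid(self, row: int, col: int) -> tuple[float, float]:
        lat0, lon0 = self.origin
        return (lat0 + (row + 0.5) * self.cell_size, lon0 + (col + 0.5) * self.cell_size)

    def to_records(self) -> list[dict]:
        probs = self.probs
        out = []
        for (row, col), count in sorted(self.counts.items()):
            lat, lon = self.cell_centroid(row, col)
            out.append(
                {
                    "row": row,
                    "col": col,
                    "cell_lat": lat,
                    "cell_lon": lon,
                    "count": count,
                    "prob": probs.get((row, col), 0.0),
                }
            )
        return out


def fishnet_counts(
    endpoints: list[Endpoint],
    cell_size: float = 0.5,
    origin: tuple[float, float] = (0.0, 0.0),
) -> DensityGrid:
    """Count endpoints per half-open fishnet cell.

    Each endpoint increments exactly one cell, so the counts always sum
    to ``len(endpoints)``.  A point exactly on a cell edge belongs to
    the higher cell (half-open ``[edge, edge + cell_size)`` convention).
    """
    lat0, lon0 = origin
    counts: dict = {}
    for ep in endpoints:
        row = int(np.floor((ep.lat - lat0) / cell_size))
        col = int(np.floor((ep.lon - lon0) / cell_size))
        counts[(row, col)] = counts.get((row, col), 0) + 1
    return DensityGrid(cell_size=cell_size, origin=origin, counts=counts)


def _data_sites(grid: DensityGrid) -> tuple[np.ndarray, np.ndarray]:
    """Non-empty cell centroids as (n, 2) lon/lat points with prob values."""
    probs = grid.probs
    pts = []
    vals = []
    for (row, col), p in sorted(probs.items()):
        lat, lon = grid.cell_centroid(row, col)
        pts.append((lon, lat))
        vals.append(p)
    return np.asarray(pts, dtype=float), np.asarray(vals, dtype=float)


def _check_nondegenerate(pts: np.ndarray) -> None:
    if len(pts) < 3:
        raise DegenerateGeometryError(
            f"natural-neighbour interpolation needs >= 3 data cells, got {len(pts)}"
        )
    # collinearity: rank of centred coordinates < 2
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-10) < 2:
        raise DegenerateGeometryError("data cell centroids are collinear")


def sibson_weights(pts: np.ndarray, query: tuple[float, float]) -> np.ndarray | None:
    """Sibson weights of ``query`` w.r.t. data points (n, 2), or None
    when the query lies outside the data's convex hull.

    Implementation: Voronoi area stealing.  The diagram of the data
    points is computed once with the query inserted; the area that the
    query's new cell takes from each original cell, normalised, gives
    the weights.  For queries inside the convex hull the new cell is
    bounded, so the clipping envelope does not affect the result.
    """
    qx, qy = float(query[0]), float(query[1])
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    qpt = Point(qx, qy)
    if not hull.covers(qpt):
        return None
    # exact hit on a data site: degenerate diagram, snap to that site
    d2 = np.sum((pts - [qx, qy]) ** 2, axis=1)
    if d2.min() < 1e-20:
        w = np.zeros(len(pts))
        w[int(np.argmin(d2))] = 1.0
        return w
    minx, miny, maxx, maxy = hull.bounds
    pad = 10.0 * max(maxx - minx, maxy - miny, 1.0)
    env = box(minx - pad, miny - pad, maxx + pad, maxy + pad)

    def cells_for(sites: np.ndarray) -> list:
        diagram = voronoi_diagram(MultiPoint([tuple(p) for p in sites]), envelope=env)
        cells = [None] * len(sites)
        for cell in diagram.geoms:
            clipped = cell.intersection(env)
            for i, p in enumerate(sites):
                if cells[i] is None and clipped.covers(Point(*p)):
                    cells[i] = clipped
                    break
        return cells

    base_cells = cells_for(pts)
    aug = np.vstack([pts, [qx, qy]])
    aug_cells = cells_for(aug)
    qcell = aug_cells[-1]
    if qcell is None:  # numerical failure; should not happen inside the hull
        return None
    stolen = np.array(
        [qcell.intersection(c).area if c is not None else 0.0 for c in base_cells]
    )
    total = stolen.sum()
    if total <= 0:
        return None
    return stolen / total


def natural_neighbor_surface(
    grid: DensityGrid,
    query: list[tuple[float, float]],
    method: str = "sibson",
) -> np.ndarray:
    """Interpolate the grid's probability values at (lat, lon) queries.

    Returns one value per query point; NaN marks queries outside the
    convex hull of the non-empty cell centroids.  ``method='linear'``
    selects barycentric linear interpolation instead of Sibson.
    """
    pts, vals = _data_sites(grid)
    _check_nondegenerate(pts)
    query = np.atleast_2d(np.asarray(query, dtype=float))
    out = np.full(len(query), np.nan)
    if method == "linear":
        from scipy.interpolate import LinearNDInterpolator

        interp = LinearNDInterpolator(pts, vals)
        out[:] = interp(query[:, 1], query[:, 0])  # (lon, lat) order
        return out
    if method != "sibson":
        raise ValueError(f"unknown interpolation method {method!r}")
    for k, (lat, lon) in enumerate(query):
        w = sibson_weights(pts, (lon, lat))
        if w is not None:
            out[k] = float(w @ vals)
    return out
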