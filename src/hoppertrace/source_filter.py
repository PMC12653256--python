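"""Valid-source screening of trajectory endpoints.

A takeoff endpoint only marks a plausible emigration source when
(1) it is not north of the latitude cutoff (25 degN by default: rice
further north is still at sowing/seedling stage in May and cannot host
emigrants), (2) it falls inside a rice-cultivation polygon, and (3) the
polygon hosts macropterous (long-winged, flight-capable) adults.
Criteria are evaluated in that order and the first failure is reported.

The cutoff is strict "north of": an endpoint exactly on the cutoff
latitude is retained.  Point-in-polygon tests are planar in geographic
coordinates; the study domain spans well under 15 degrees of latitude,
so the distortion is negligible at the 0.5-degree analysis resolution.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, box, shape
from shapely.prepared import prep

from .trajectory import Endpoint

__all__ = ["SourceMask", "is_valid_source", "filter_endpoints"]

REASONS = ("ok", "north_of_cutoff", "not_rice", "no_macroptery")


@dataclass
class SourceMask:
    """Rice-area polygons with per-polygon emigrant availability.

    ``rice_polygons`` is a list of shapely polygons; ``macroptery_flags``
    is a parallel list of booleans marking whether macropterous adults
    are present (i.e. the polygon can actually export migrants).
    """

    rice_polygons: list
    macroptery_flags: list
    lat_cutoff: float = 25.0

    def __post_init__(self) -> None:
        if len(self.rice_polygons) != len(self.macroptery_flags):
            raise ValueError("one macroptery flag per polygon required")
        if not np.isfinite(self.lat_cutoff):
            raise ValueError("lat_cutoff must be finite")
        for poly in self.rice_polygons:
            if not poly.is_valid:
                raise ValueError("rice polygon is invalid (self-intersecting?)")
        self._prepared = [prep(p) for p in self.rice_polygons]

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_geojson(cls, path, lat_cutoff: float = 25.0) -> "SourceMask":
        """Read polygons from GeoJSON; feature properties ``rice`` and
        ``macroptery`` (both defaulting true) select and annotate them."""
        with open(path) as fh:
            gj = json.load(fh)
        polys, flags = [], []
        for feat in gj.get("features", []):
            props = feat.get("properties") or {}
            if not props.get("rice", True):
                continue
            polys.append(shape(feat["geometry"]))
            flags.append(bool(props.get("macroptery", True)))
        return cls(polys, flags, lat_cutoff=lat_cutoff)

    @classmethod
    def from_raster(
        cls,
        lats: np.ndarray,
        lons: np.ndarray,
        values: np.ndarray,
        cell_size: float,
        lat_cutoff: float = 25.0,
        macroptery: bool = True,
    ) -> "SourceMask":
        """Build a mask from a 0/1 raster given by cell lower-left corners."""
        polys, flags = [], []
        for la, lo, v in zip(np.ravel(lats), np.ravel(lons), np.ravel(values)):
            if v:
                polys.append(box(lo, la, lo + cell_size, la + cell_size))
                flags.append(macroptery)
        return cls(polys, flags, lat_cutoff=lat_cutoff)

    def polygon_index(self, lat: float, lon: float) -> int | None:
        pt = Point(lon, lat)
        for i, prepared in enumerate(self._prepared):
            if prepared.intersects(pt):  # boundary-inclusive containment
                return i
        return None


def is_valid_source(endpoint: Endpoint, mask: SourceMask) -> tuple[bool, str]:
    """Apply the three source criteria; return (valid, first_failed_reason)."""
    if endpoint.status != "complete":
        raise ValueError(
            f"endpoint has status {endpoint.status!r}; only complete "
            "trajectory endpoints can be screened"
        )
    if endpoint.lat > mask.lat_cutoff:
        return False, "north_of_cutoff"
    idx = mask.polygon_index(endpoint.lat, endpoint.lon)
    if idx is None:
        return False, "not_rice"
    if not mask.macroptery_flags[idx]:
        return False, "no_macroptery"
    return True, "ok"


def filter_endpoints(
    endpoints: list[Endpoint], mask: SourceMask
) -> tuple[list[Endpoint], dict[str, int]]:
    """Partition endpoints into valid sources and an audit of exclusions.

    The audit counts every endpoint exactly once, so the per-reason
    counts always sum to ``len(endpoints)``.
    """
    audit = Counter({r: 0 for r in REASONS})
    valid = []
    for ep in endpoints:
        ok, reason = is_valid_source(ep, mask)
        audit[reason] += 1
        if ok:
            valid.append(ep)
    return valid, dict(audit)
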