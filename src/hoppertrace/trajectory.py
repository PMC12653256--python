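"""Backward Lagrangian trajectories with planthopper flight rules.

Migrating planthoppers are treated as passive wind-borne particles at a
fixed representative flight level.  A backward trajectory starts at a
trap site at a candidate landing time and is integrated upwind to the
most recent dusk takeoff (19:00 local by default).  Biological
constraints shape the integration:

* takeoff at dusk (19:00 Beijing Time), the species' peak activity;
* flight completed within 24 h of takeoff;
* air temperature along the path must stay at or above 16.5 degC --
  a violation invalidates the path segment beyond it;
* candidate landings span 20:00 on the departure day to 19:00 the next
  day (the default enumerates the nocturnal 20:00-06:00 hours of the
  capture night).

Integration uses the Petterssen predictor-corrector (iterated midpoint)
scheme on degree-rate velocities: dlat/dt = v / 111320 m/deg and
dlon/dt = u / (111320 cos(lat)), a spherical-Earth metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .metfield import MetField, OutOfDomainError

__all__ = [
    "FlightConfig",
    "MigrationEvent",
    "Trajectory",
    "Endpoint",
    "TrapDataError",
    "select_events",
    "backward_trajectory",
    "forward_trajectory",
    "trajectories_for_event",
    "takeoff_endpoints",
]

log = logging.getLogger(__name__)

M_PER_DEG = 111_320.0  # metres per degree of latitude, spherical Earth

DEFAULT_LANDING_HOURS = (20, 21, 22, 23, 0, 1, 2, 3, 4, 5, 6)
FULL_WINDOW_LANDING_HOURS = tuple(range(20, 24)) + tuple(range(0, 20))


class TrapDataError(ValueError):
    """Raised for malformed light-trap records (e.g. negative counts)."""


@dataclass(frozen=True)
class FlightConfig:
    """Behavioural and numerical parameters of the trajectory model."""

    takeoff_hour: int = 19
    altitude_m: float = 1000.0
    temp_floor_C: float = 16.5
    max_duration_h: float = 24.0
    step_min: float = 6.0
    landing_hours: tuple[int, ...] = DEFAULT_LANDING_HOURS

    def __post_init__(self) -> None:
        if not (0 < self.step_min <= 60):
            raise ValueError("step_min must be in (0, 60]")
        if not np.isfinite(self.temp_floor_C):
            raise ValueError("temp_floor_C must be finite")
        for h in self.landing_hours:
            dur = self._duration_h(h)
            if not (0 < dur <= self.max_duration_h):
                raise ValueError(
                    f"landing hour {h} implies flight duration {dur} h outside "
                    f"(0, {self.max_duration_h}]"
                )

    def _duration_h(self, landing_hour: int) -> float:
        return (landing_hour - self.takeoff_hour) % 24 or 24.0

    def full_window(self) -> "FlightConfig":
        """Variant enumerating every landing hour of the 24 h window."""
        return replace(self, landing_hours=FULL_WINDOW_LANDING_HOURS)


@dataclass(frozen=True)
class MigrationEvent:
    """A site-night with trap catch at or above the event threshold."""

    site_id: str
    lat: float
    lon: float
    capture_date: pd.Timestamp
    nightly_count: int


@dataclass
class Trajectory:
    """One backward path: points ordered landing -> takeoff.

    ``status`` is ``complete`` when integration reached the takeoff
    time, ``truncated_temp`` when the temperature floor was violated,
    ``exited_domain`` when the path left the met grid.
    """

    points: list  # [(Timestamp, lat, lon)] with strictly decreasing times
    status: str
    landing_time: pd.Timestamp
    takeoff_time: pd.Timestamp
    event: MigrationEvent | None = None

    @property
    def duration_h(self) -> float:
        return (self.landing_time - self.takeoff_time) / pd.Timedelta(hours=1)


@dataclass(frozen=True)
class Endpoint:
    """Takeoff terminus of a complete backward trajectory."""

    lat: float
    lon: float
    takeoff_time: pd.Timestamp
    event: MigrationEvent | None
    status: str = "complete"


def select_events(trap_records, threshold: int = 10) -> list[MigrationEvent]:
    """Select site-nights with catch >= ``threshold`` (inclusive).

    ``trap_records`` is a DataFrame with columns ``site_id, date, count``
    and optionally ``lat, lon``, or any iterable convertible to one.
    """
    if not isinstance(trap_records, pd.DataFrame):
        rows = list(trap_records)
        cols = (
            ["site_id", "date", "count"]
            if rows and len(rows[0]) == 3
            else ["site_id", "lat", "lon", "date", "count"]
        )
        trap_records = pd.DataFrame(rows, columns=cols)
    df = trap_records.copy()
    counts = df["count"].to_numpy()
    if (counts < 0).any():
        bad = df.loc[df["count"] < 0].iloc[0]
        raise TrapDataError(
            f"negative trap count {bad['count']} at site {bad['site_id']} on {bad['date']}"
        )
    if not np.array_equal(counts, counts.astype(int)):
        raise TrapDataError("trap counts must be integers")
    sel = df.loc[counts >= threshold]
    events = []
    for _, row in sel.iterrows():
        events.append(
            MigrationEvent(
                site_id=str(row["site_id"]),
                lat=float(row.get("lat", np.nan)),
                lon=float(row.get("lon", np.nan)),
                capture_date=pd.Timestamp(row["date"]).normalize(),
                nightly_count=int(row["count"]),
            )
        )
    return events


def _deg_rate(fld: MetField, lat: float, lon: float, t) -> tuple[float, float]:
    """(dlat/dt, dlon/dt) in deg/s from the wind at (lat, lon, t)."""
    u = fld.sample(lat, lon, t, "u")
    v = fld.sample(lat, lon, t, "v")
    return v / M_PER_DEG, u / (M_PER_DEG * np.cos(np.radians(lat)))


def _petterssen_step(fld, lat, lon, t0, t1, n_corrector: int = 4):
    """Advect (lat, lon) from time t0 to t1 (t1 may precede t0)."""
    dt = (t1 - t0) / pd.Timedelta(seconds=1)
    r0 = _deg_rate(fld, lat, lon, t0)
    lat1 = lat + r0[0] * dt
    lon1 = lon + r0[1] * dt
    for _ in range(n_corrector):
        r1 = _deg_rate(fld, lat1, lon1, t1)
        lat_new = lat + 0.5 * (r0[0] + r1[0]) * dt
        lon_new = lon + 0.5 * (r0[1] + r1[1]) * dt
        if abs(lat_new - lat1) < 1e-12 and abs(lon_new - lon1) < 1e-12:
            lat1, lon1 = lat_new, lon_new
            break
        lat1, lon1 = lat_new, lon_new
    return lat1, lon1


def _most_recent_takeoff(landing_time: pd.Timestamp, takeoff_hour: int) -> pd.Timestamp:
    """Latest occurrence of ``takeoff_hour`` strictly before landing."""
    cand = landing_time.normalize() + pd.Timedelta(hours=takeoff_hour)
    if cand >= landing_time:
        cand -= pd.Timedelta(days=1)
    return cand


def backward_trajectory(
    fld: MetField, start: tuple[float, float], landing_time, cfg: FlightConfig | None = None
) -> Trajectory:
    """Integrate backward from a landing point to the dusk takeoff.

    The path runs from ``landing_time`` back to the most recent
    occurrence of ``cfg.takeoff_hour`` (so flight duration is at most
    24 h by construction).  The temperature floor is enforced at every
    point including the landing point.
    """
    cfg = cfg or FlightConfig()
    landing_time = pd.Timestamp(landing_time)
    takeoff_time = _most_recent_takeoff(landing_time, cfg.takeoff_hour)
    if pd.Timestamp(np.datetime64(fld.times[0])) > takeoff_time:
        raise OutOfDomainError(
            f"takeoff candidate {takeoff_time} precedes the met field's time domain",
            coord=(start[0], start[1], takeoff_time),
        )
    lat, lon = float(start[0]), float(start[1])
    t = landing_time
    points = [(t, lat, lon)]
    try:
        if fld.sample(lat, lon, t, "T") < cfg.temp_floor_C:
            return Trajectory(points, "truncated_temp", landing_time, takeoff_time)
    except OutOfDomainError:
        return Trajectory(points, "exited_domain", landing_time, takeoff_time)
    step = pd.Timedelta(minutes=cfg.step_min)
    while t > takeoff_time:
        t_next = max(t - step, takeoff_time)
        try:
            lat, lon = _petterssen_step(fld, lat, lon, t, t_next)
            temp = fld.sample(lat, lon, t_next, "T")
        except OutOfDomainError:
            return Trajectory(points, "exited_domain", landing_time, takeoff_time)
        if temp < cfg.temp_floor_C:
            return Trajectory(points, "truncated_temp", landing_time, takeoff_time)
        t = t_next
        points.append((t, lat, lon))
    return Trajectory(points, "complete", landing_time, takeoff_time)


def forward_trajectory(
    fld: MetField,
    start: tuple[float, float],
    takeoff_time,
    landing_time,
    cfg: FlightConfig | None = None,
) -> Trajectory:
    """Forward integration with the same scheme (used for reversal checks)."""
    cfg = cfg or FlightConfig()
    takeoff_time = pd.Timestamp(takeoff_time)
    landing_time = pd.Timestamp(landing_time)
    lat, lon = float(start[0]), float(start[1])
    t = takeoff_time
    points = [(t, lat, lon)]
    step = pd.Timedelta(minutes=cfg.step_min)
    while t < landing_time:
        t_next = min(t + step, landing_time)
        lat, lon = _petterssen_step(fld, lat, lon, t, t_next)
        t = t_next
        points.append((t, lat, lon))
    return Trajectory(points[::-1], "complete", landing_time, takeoff_time)


def _landing_times(event: MigrationEvent, cfg: FlightConfig) -> list[pd.Timestamp]:
    """Landing timestamps on the capture night, in flight-duration order."""
    base = pd.Timestamp(event.capture_date)
    out = []
    for h in cfg.landing_hours:
        day = base if h >= cfg.takeoff_hour else base + pd.Timedelta(days=1)
        out.append(day + pd.Timedelta(hours=h))
    return out


def trajectories_for_event(
    fld: MetField, event: MigrationEvent, cfg: FlightConfig | None = None
) -> list[Trajectory]:
    """One backward trajectory per configured landing hour of the night.

    Failures of individual landing hours (e.g. a landing time outside
    the met time domain) are logged and skipped, not fatal.
    """
    cfg = cfg or FlightConfig()
    out = []
    for landing in _landing_times(event, cfg):
        try:
            traj = backward_trajectory(fld, (event.lat, event.lon), landing, cfg)
        except OutOfDomainError as exc:
            log.warning(
                "event %s/%s landing %s failed: %s",
                event.site_id,
                event.capture_date.date(),
                landing,
                exc,
            )
            continue
        traj.event = event
        out.append(traj)
    return out


def takeoff_endpoints(trajectories: list[Trajectory]) -> list[Endpoint]:
    """Takeoff endpoints from complete trajectories only."""
    out = []
    for traj in trajectories:
        if traj.status != "complete":
            continue
        t, lat, lon = traj.points[-1]
        out.append(Endpoint(lat=lat, lon=lon, takeoff_time=t, event=traj.event))
    return out


def endpoints_to_frame(endpoints: list[Endpoint]) -> pd.DataFrame:
    """Tabular view of endpoints for CSV export."""
    rows = []
    for ep in endpoints:
        rows.append(
            {
                "site_id": ep.event.site_id if ep.event else "",
                "capture_date": ep.event.capture_date.date() if ep.event else "",
                "takeoff_time": ep.takeoff_time,
                "status": ep.status,
                "lat": ep.lat,
                "lon": ep.lon,
            }
        )
    return pd.DataFrame(
        rows, columns=["site_id", "capture_date", "takeoff_time", "status", "lat", "lon"]
    )
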