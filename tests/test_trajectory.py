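import numpy as np
import pandas as pd
import pytest

from hoppertrace.metfield import OutOfDomainError
from hoppertrace.synthetic import WindScenario, gen_windfield
from hoppertrace.trajectory import (
    FlightConfig,
    MigrationEvent,
    TrapDataError,
    backward_trajectory,
    forward_trajectory,
    select_events,
    takeoff_endpoints,
    trajectories_for_event,
)

M_PER_DEG = 111_320.0


def trap_frame(counts, site="S1"):
    return pd.DataFrame(
        {
            "site_id": site,
            "lat": 27.0,
            "lon": 111.0,
            "date": pd.date_range("2024-05-01", periods=len(counts)),
            "count": counts,
        }
    )


class TestSelectEvents:
    def test_threshold_selects_expected_nights(self):
        events = select_events(trap_frame([5, 12, 30]))
        assert [e.capture_date.day for e in events] == [2, 3]

    def test_boundary_count_of_ten_is_included(self):
        events = select_events(trap_frame([9, 10]))
        assert len(events) == 1 and events[0].nightly_count == 10

    def test_all_zero_counts_give_no_events(self):
        assert select_events(trap_frame([0, 0, 0])) == []

    def test_negative_count_raises(self):
        with pytest.raises(TrapDataError, match="negative"):
            select_events(trap_frame([5, -1]))


class TestBackwardTrajectory:
    def test_uniform_wind_matches_closed_form(self, east_wind_field):
        """12 h in a 10 m/s eastward wind: the source is 432 km west."""
        traj = backward_trajectory(east_wind_field, (25.0, 112.0), "2024-05-24 07:00")
        assert traj.status == "complete"
        t, lat, lon = traj.points[-1]
        assert t == pd.Timestamp("2024-05-23 19:00")
        expected_dlon = 432_000.0 / (M_PER_DEG * np.cos(np.radians(25.0)))
        assert lat == pytest.approx(25.0, abs=1e-9)
        assert lon == pytest.approx(112.0 - expected_dlon, rel=0.005)

    def test_zero_wind_endpoint_is_start(self, calm_field):
        traj = backward_trajectory(calm_field, (25.0, 112.0), "2024-05-24 22:00")
        t, lat, lon = traj.points[-1]
        assert (lat, lon) == (25.0, 112.0)
        assert t == pd.Timestamp("2024-05-24 19:00")
        assert traj.duration_h == pytest.approx(3.0)

    def test_cold_field_truncates_immediately(self, cold_field):
        traj = backward_trajectory(cold_field, (25.0, 112.0), "2024-05-24 07:00")
        assert traj.status == "truncated_temp"
        assert len(traj.points) == 1
        assert takeoff_endpoints([traj]) == []

    def test_exiting_domain_is_flagged(self):
        fld = gen_windfield(
            WindScenario(kind="uniform", speed=25.0, bearing_deg=90.0,
                         lat_range=(24.0, 26.0), lon_range=(111.0, 113.0))
        )
        traj = backward_trajectory(fld, (25.0, 111.2), "2024-05-24 07:00")
        assert traj.status == "exited_domain"
        assert takeoff_endpoints([traj]) == []

    def test_takeoff_before_time_domain_raises(self, east_wind_field):
        with pytest.raises(OutOfDomainError):
            backward_trajectory(east_wind_field, (25.0, 112.0), "2024-05-20 02:00")

    def test_forward_reintegration_returns_to_landing(self):
        """Time-reversal check in a smoothly sheared jet field."""
        fld = gen_windfield(
            WindScenario(kind="southwesterly_jet", speed=12.0, jet_axis=(24.0, 108.0),
                         jet_width_deg=4.0, temp_C=22.0)
        )
        landing = (27.5, 112.5)
        traj = backward_trajectory(fld, landing, "2024-05-24 05:00")
        assert traj.status == "complete"
        t0, lat0, lon0 = traj.points[-1]
        fw = forward_trajectory(fld, (lat0, lon0), t0, traj.landing_time)
        _, la, lo = fw.points[0]
        err_km = np.hypot(
            (la - landing[0]) * 111.32,
            (lo - landing[1]) * 111.32 * np.cos(np.radians(landing[0])),
        )
        assert err_km <= 2.0


class TestEventTrajectories:
    def make_event(self, lat=27.0, lon=111.0):
        return MigrationEvent("S1", lat, lon, pd.Timestamp("2024-05-24"), 50)

    def test_default_night_gives_eleven_trajectories(self, east_wind_field):
        trajs = trajectories_for_event(east_wind_field, self.make_event())
        assert len(trajs) == 11
        assert sorted(t.duration_h for t in trajs) == list(range(1, 12))

    def test_single_landing_hour(self, east_wind_field):
        cfg = FlightConfig(landing_hours=(20,))
        trajs = trajectories_for_event(east_wind_field, self.make_event(), cfg)
        assert len(trajs) == 1 and trajs[0].duration_h == pytest.approx(1.0)

    def test_full_window_covers_24_hours(self, east_wind_field):
        cfg = FlightConfig().full_window()
        trajs = trajectories_for_event(east_wind_field, self.make_event(), cfg)
        assert len(trajs) == 24
        assert max(t.duration_h for t in trajs) == pytest.approx(24.0)
        assert all(t.duration_h <= 24.0 for t in trajs)

    def test_southwesterly_wind_puts_endpoints_southwest_on_bearing(self):
        fld = gen_windfield(WindScenario(kind="uniform", speed=10.0, bearing_deg=45.0))
        ev = self.make_event()
        endpoints = takeoff_endpoints(trajectories_for_event(fld, ev))
        assert endpoints
        for ep in endpoints:
            assert ep.lat < ev.lat and ep.lon < ev.lon
        # straight upwind bearing: dlat (in metres) == dlon (in metres)
        for ep in endpoints:
            dy = (ev.lat - ep.lat) * M_PER_DEG
            dx = (ev.lon - ep.lon) * M_PER_DEG * np.cos(np.radians(0.5 * (ev.lat + ep.lat)))
            assert dx / dy == pytest.approx(1.0, rel=0.01)

    def test_complete_trajectories_take_off_at_dusk(self, east_wind_field):
        trajs = trajectories_for_event(east_wind_field, self.make_event())
        for t in trajs:
            if t.status == "complete":
                assert t.points[-1][0].hour == 19

    def test_mixed_statuses_yield_only_complete_endpoints(self, east_wind_field, cold_field):
        ev = self.make_event()
        good = trajectories_for_event(east_wind_field, ev)
        bad = trajectories_for_event(cold_field, ev)
        eps = takeoff_endpoints(good + bad)
        assert len(eps) == sum(1 for t in good if t.status == "complete")


def test_flight_config_rejects_bad_step():
    with pytest.raises(ValueError):
        FlightConfig(step_min=0)
    with pytest.raises(ValueError):
        FlightConfig(step_min=90)
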