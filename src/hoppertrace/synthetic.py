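"""Seeded generators for every pipeline input.

Real runs consume reanalysis winds, light-trap logs, rice masks and
bioassay tables; none of these can be bundled, so each has a
parametric synthetic twin:

* :func:`gen_windfield` -- analytic wind/temperature scenarios
  (uniform, solid-body rotation, a Gaussian southwesterly jet);
* :func:`gen_bioassay` -- binomial dose-mortality draws from a probit
  truth at the standard assay design (5 log-spaced concentrations
  spanning LC10-LC90, 80 insects per concentration);
* :func:`gen_trap_series` -- Poisson nightly catches with immigration
  pulse nights;
* :func:`planted_source_scenario` -- a full end-to-end scenario with a
  known planted source and a 3x-LC50 decoy, used to demonstrate that
  the pipeline recovers the true origin.

All randomness flows from the explicit seed passed to each call; there
is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from shapely.geometry import box

from .bioassay import BioassayTable
from .metfield import MetField
from .source_filter import SourceMask

__all__ = [
    "WindScenario",
    "AssayTruth",
    "design_concentrations",
    "gen_windfield",
    "gen_bioassay",
    "gen_trap_series",
    "planted_source_scenario",
]


@dataclass(frozen=True)
class WindScenario:
    """Parametric wind/temperature field on a regular grid.

    ``bearing_deg`` is the compass direction the wind blows *toward*
    (45 = toward the northeast, i.e. a southwesterly wind).
    """

    kind: str = "uniform"  # uniform | rotational | southwesterly_jet
    speed: float = 10.0  # m/s (peak speed for the jet)
    bearing_deg: float = 45.0
    temp_C: float = 20.0
    temp_grad_per_deg_lat: float = 0.0
    center: tuple[float, float] = (25.0, 110.0)  # rotational: (lat, lon)
    omega: float = 1e-5  # rotational angular velocity, 1/s
    jet_axis: tuple[float, float] = (24.0, 108.0)  # point on the jet axis
    jet_width_deg: float = 3.0
    lat_range: tuple[float, float] = (15.0, 35.0)
    lon_range: tuple[float, float] = (98.0, 120.0)
    resolution_deg: float = 1.0
    time_start: str = "2024-05-20 00:00"
    time_end: str = "2024-05-31 00:00"
    time_step_h: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution_deg <= 0:
            raise ValueError("resolution_deg must be positive")


def gen_windfield(scenario: WindScenario) -> MetField:
    """Deterministic MetField realising a :class:`WindScenario`."""
    sc = scenario
    lats = np.arange(sc.lat_range[0], sc.lat_range[1] + 1e-9, sc.resolution_deg)
    lons = np.arange(sc.lon_range[0], sc.lon_range[1] + 1e-9, sc.resolution_deg)
    times = pd.date_range(sc.time_start, sc.time_end, freq=f"{sc.time_step_h}h").values
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    theta = np.radians(sc.bearing_deg)
    if sc.kind == "uniform":
        u2 = np.full_like(glat, sc.speed * np.sin(theta))
        v2 = np.full_like(glat, sc.speed * np.cos(theta))
    elif sc.kind == "rotational":
        lat0, lon0 = sc.center
        dy = (glat - lat0) * 111_320.0
        dx = (glon - lon0) * 111_320.0 * np.cos(np.radians(lat0))
        u2 = -sc.omega * dy
        v2 = sc.omega * dx
    elif sc.kind == "southwesterly_jet":
        # Gaussian speed profile across the axis line through jet_axis
        # with direction bearing_deg; flow is parallel to the axis.
        ax_lat, ax_lon = sc.jet_axis
        # signed perpendicular distance (degrees) from the axis
        d = (glat - ax_lat) * np.cos(theta) - (glon - ax_lon) * np.sin(theta)
        s = sc.speed * np.exp(-(d**2) / (2 * sc.jet_width_deg**2))
        u2 = s * np.sin(theta)
        v2 = s * np.cos(theta)
    else:
        raise ValueError(f"unknown scenario kind {scenario.kind!r}")
    T2 = sc.temp_C + sc.temp_grad_per_deg_lat * (glat - lats[0])
    shape = (len(times), len(lats), len(lons))
    u = np.broadcast_to(u2, shape).copy()
    v = np.broadcast_to(v2, shape).copy()
    T = np.broadcast_to(T2, shape).copy()
    return MetField(lats, lons, times, u, v, T)


@dataclass(frozen=True)
class AssayTruth:
    """Generating truth for a simulated bioassay."""

    lc50: float  # mg/L
    slope: float  # probits per log10 mg/L
    control_mortality: float = 0.0
    concentrations: tuple | None = None  # None -> LC10-LC90 design
    n_per_conc: int = 80
    n_control: int = 80
    n_conc: int = 5

    def __post_init__(self) -> None:
        if self.lc50 <= 0 or self.slope <= 0:
            raise ValueError("lc50 and slope must be positive")
        if not (0 <= self.control_mortality < 1):
            raise ValueError("control_mortality must be in [0, 1)")


def design_concentrations(
    lc50: float, slope: float, k: int = 5, p_lo: float = 0.10, p_hi: float = 0.90
) -> np.ndarray:
    """k log10-equispaced concentrations spanning the LC(p_lo)-LC(p_hi) range."""
    lo = np.log10(lc50) + norm.ppf(p_lo) / slope
    hi = np.log10(lc50) + norm.ppf(p_hi) / slope
    return 10.0 ** np.linspace(lo, hi, k)


def gen_bioassay(
    truth: AssayTruth,
    seed: int,
    site_id: str = "synthetic",
    insecticide: str = "synthetic",
) -> BioassayTable:
    """Binomial draws from the probit truth, mixed with control mortality.

    P(death | c) = c0 + (1 - c0) * Phi(slope * (log10 c - log10 LC50)).

    An assay realisation whose control mortality exceeds the 10%
    quality threshold is discarded and redrawn, as the lab protocol
    repeats discarded tests (each redraw uses a fresh substream of the
    same seed, so results stay reproducible).
    """
    rng = np.random.default_rng(seed)
    conc = (
        np.asarray(truth.concentrations, dtype=float)
        if truth.concentrations is not None
        else design_concentrations(truth.lc50, truth.slope, truth.n_conc)
    )
    p_kill = norm.cdf(truth.slope * (np.log10(conc) - np.log10(truth.lc50)))
    p_obs = truth.control_mortality + (1 - truth.control_mortality) * p_kill
    for _ in range(100):
        dead = rng.binomial(truth.n_per_conc, p_obs)
        ctrl_dead = rng.binomial(truth.n_control, truth.control_mortality)
        if truth.n_control <= 0 or ctrl_dead / truth.n_control <= 0.10:
            break
    return BioassayTable(
        site_id=site_id,
        insecticide=insecticide,
        concentrations=conc,
        n_exposed=np.full(len(conc), truth.n_per_conc),
        n_dead=dead,
        control_n=truth.n_control,
        control_dead=int(ctrl_dead),
    )


def bioassay_to_frame(table: BioassayTable) -> pd.DataFrame:
    """Long-format rows (the CSV dialect the pipeline reads)."""
    rows = [
        {
            "site_id": table.site_id,
            "insecticide": table.insecticide,
            "conc_mg_L": c,
            "n_exposed": int(n),
            "n_dead": int(d),
            "is_control": False,
        }
        for c, n, d in zip(table.concentrations, table.n_exposed, table.n_dead)
    ]
    rows.append(
        {
            "site_id": table.site_id,
            "insecticide": table.insecticide,
            "conc_mg_L": 0.0,
            "n_exposed": table.control_n,
            "n_dead": table.control_dead,
            "is_control": True,
        }
    )
    return pd.DataFrame(rows)


def gen_trap_series(
    sites: list[tuple[str, float, float]],
    dates,
    base_rate: float,
    pulses: list[tuple[str, float]],
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson nightly catches with immigration pulses.

    ``sites`` are (site_id, lat, lon); ``pulses`` are (date, magnitude)
    applied at every site.  Counts are Poisson(base_rate) plus
    Poisson(magnitude) on pulse nights.
    """
    if base_rate < 0 or any(m < 0 for _, m in pulses):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    pulse_by_date = {pd.Timestamp(d).normalize(): m for d, m in pulses}
    rows = []
    for site_id, lat, lon in sites:
        for d in pd.to_datetime(list(dates)):
            d = d.normalize()
            lam = base_rate + pulse_by_date.get(d, 0.0)
            count = int(rng.poisson(lam)) if lam > 0 else 0
            rows.append(
                {"site_id": site_id, "lat": lat, "lon": lon, "date": d, "count": count}
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# end-to-end planted-source scenario


@dataclass
class PlantedScenario:
    """All inputs for the planted-source recovery experiment."""

    field: MetField
    trap_records: pd.DataFrame
    mask: SourceMask
    bioassays: pd.DataFrame  # long format, destinations + sources, both insecticides
    dest_sites: list
    true_source: str
    decoy_source: str
    capture_date: str
    fishnet_origin: tuple[float, float]


def planted_source_scenario(seed: int) -> PlantedScenario:
    """A uniform southwesterly flow carrying migrants from a known source.

    Two destination trap sites in the north catch an immigration pulse;
    backward trajectories point to a rice area in the southwest where
    the planted source lives.  The destination populations and the
    planted source share one susceptibility truth; a decoy source in
    the same rice area is generated with 3x the LC50 for both
    insecticides, so only the true source should be attributed.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(12)]
    scenario = WindScenario(
        kind="uniform", speed=10.0, bearing_deg=45.0, temp_C=22.0,
        lat_range=(18.0, 32.0), lon_range=(100.0, 118.0),
        time_start="2024-05-22 00:00", time_end="2024-05-27 00:00",
    )
    fld = gen_windfield(scenario)
    dest_sites = [("D1", 26.8, 111.0), ("D2", 27.0, 111.3)]
    capture_date = "2024-05-24"
    traps = gen_trap_series(
        dest_sites,
        dates=pd.date_range("2024-05-23", "2024-05-25"),
        base_rate=2.0,
        pulses=[(capture_date, 60.0)],
        seed=seeds[0],
    )
    mask = SourceMask(
        rice_polygons=[box(104.0, 20.0, 112.0, 25.2)],
        macroptery_flags=[True],
    )
    # susceptibility truths: destinations == planted source; decoy 3x LC50
    shared = {"pymetrozine": (30.0, 3.2), "nitenpyram": (1.0, 3.4)}
    frames = []
    k = 1
    for site_id in ["D1", "D2", "SRC_true", "SRC_decoy"]:
        factor = 3.0 if site_id == "SRC_decoy" else 1.0
        for ins, (lc50, slope) in shared.items():
            truth = AssayTruth(
                lc50=factor * lc50, slope=slope, control_mortality=0.05
            )
            table = gen_bioassay(truth, seeds[k], site_id=site_id, insecticide=ins)
            frames.append(bioassay_to_frame(table))
            k += 1
    return PlantedScenario(
        field=fld,
        trap_records=traps,
        mask=mask,
        bioassays=pd.concat(frames, ignore_index=True),
        dest_sites=dest_sites,
        true_source="SRC_true",
        decoy_source="SRC_decoy",
        capture_date=capture_date,
        fishnet_origin=(18.0, 100.0),
    )
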