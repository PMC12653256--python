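"""End-to-end orchestration: events -> trajectories -> filter -> density
-> toxicity fits -> grouping -> source matching, with a JSON run report.

The two halves of the analysis are deliberately decoupled: the
attribution half can run from the packaged toxicity tables alone
(``skip_trajectory``), and the trajectory half can run without any
bioassay input.  Every stage failure is re-raised with the stage name
so a broken input names the stage that rejected it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import attribution as attr
from . import bioassay, density_map, fixtures, metfield, source_filter, trajectory

log = logging.getLogger(__name__)

STAGES = (
    "metfield",
    "events",
    "trajectories",
    "filter",
    "density",
    "assay",
    "attribution",
)


class PipelineStageError(RuntimeError):
    """An error raised by a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """File paths and knobs for a pipeline run (YAML-serialisable)."""

    outdir: str = "hoppertrace_out"
    seed: int = 0
    # trajectory half
    met_path: str | None = None
    met_format: str = "netcdf"
    traps_path: str | None = None
    mask_path: str | None = None  # GeoJSON rice mask
    event_threshold: int = 10
    flight: dict = field(default_factory=dict)  # FlightConfig overrides
    lat_cutoff: float = 25.0
    cell_size: float = 0.5
    grid_origin: tuple[float, float] = (0.0, 0.0)
    skip_trajectory: bool = False
    # assay / attribution half
    bioassay_path: str | None = None  # long-format CSV; None -> packaged tables
    dest_sites: list | None = None  # None -> 'region' column == 'HN'
    rule: str = "both_all"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.grid_origin, list):
            cfg.grid_origin = tuple(cfg.grid_origin)
        return cfg


def _check_inputs(cfg: RunConfig) -> None:
    for stage, path in (
        ("metfield", cfg.met_path),
        ("events", cfg.traps_path),
        ("filter", cfg.mask_path),
        ("assay", cfg.bioassay_path),
    ):
        if path is not None and not Path(path).exists():
            raise PipelineStageError(stage, f"input file {path!r} does not exist")


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write all outputs under outdir.

    Returns the run report (also written as ``report.json``).
    """
    _check_inputs(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stages": {},
    }

    if not cfg.skip_trajectory:
        if cfg.met_path is None or cfg.traps_path is None:
            raise PipelineStageError(
                "metfield", "met_path and traps_path are required unless skip_trajectory"
            )
        try:
            fld = metfield.load_metfield(cfg.met_path, format=cfg.met_format)
        except Exception as exc:
            raise PipelineStageError("metfield", str(exc)) from exc
        try:
            traps = pd.read_csv(cfg.traps_path, parse_dates=["date"])
            events = trajectory.select_events(traps, threshold=cfg.event_threshold)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("events", str(exc)) from exc
        report["stages"]["events"] = {"n_events": len(events)}
        try:
            fcfg = trajectory.FlightConfig(**cfg.flight)
            trajs: list = []
            for ev in events:
                trajs.extend(trajectory.trajectories_for_event(fld, ev, fcfg))
            endpoints = trajectory.takeoff_endpoints(trajs)
            status_counts = pd.Series([t.status for t in trajs]).value_counts().to_dict()
        except Exception as exc:
            raise PipelineStageError("trajectories", str(exc)) from exc
        report["stages"]["trajectories"] = {
            "n_trajectories": len(trajs),
            "status_counts": status_counts,
            "n_endpoints": len(endpoints),
        }
        trajectory.endpoints_to_frame(endpoints).to_csv(
            outdir / "endpoints.csv", index=False
        )
        try:
            if cfg.mask_path is not None:
                mask = source_filter.SourceMask.from_geojson(
                    cfg.mask_path, lat_cutoff=cfg.lat_cutoff
                )
            else:
                raise ValueError("mask_path required for endpoint filtering")
            valid, audit = source_filter.filter_endpoints(endpoints, mask)
        except Exception as exc:
            raise PipelineStageError("filter", str(exc)) from exc
        report["stages"]["filter"] = {"audit": audit, "n_valid": len(valid)}
        trajectory.endpoints_to_frame(valid).to_csv(
            outdir / "endpoints_valid.csv", index=False
        )
        try:
            grid = density_map.fishnet_counts(
                valid, cell_size=cfg.cell_size, origin=tuple(cfg.grid_origin)
            )
        except Exception as exc:
            raise PipelineStageError("density", str(exc)) from exc
        pd.DataFrame(grid.to_records()).to_csv(outdir / "density.csv", index=False)
        report["stages"]["density"] = {
            "n_cells": len(grid.counts),
            "total_count": grid.total,
        }

    # ---- assay / attribution half ------------------------------------
    discrepancies = pd.DataFrame()
    try:
        if cfg.bioassay_path is not None:
            raw = pd.read_csv(cfg.bioassay_path)
            fits = bioassay.fit_all(raw)
            fits.to_csv(outdir / "fits.csv", index=False)
            tox = fits
            printed_letters = None
        else:
            tox = fixtures.load_toxicity_tables()
            printed_letters = tox.set_index(["insecticide", "site_id"])["letter"]
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("assay", str(exc)) from exc
    report["stages"]["assay"] = {"n_fits": len(tox)}

    try:
        if cfg.dest_sites is not None:
            dest_tox = tox[tox["site_id"].isin(cfg.dest_sites)]
            src_tox = tox[~tox["site_id"].isin(cfg.dest_sites)]
        elif "region" in tox.columns:
            dest_tox = tox[tox["region"] == "HN"]
            src_tox = tox[tox["region"] != "HN"]
        else:
            raise ValueError("dest_sites must be given when fits carry no region column")
        dest_iv = attr.intervals_from_frame(dest_tox)
        src_iv = attr.intervals_from_frame(src_tox)
        groups = attr.destination_groups(dest_iv)
        result = attr.match_sources(dest_iv, groups, src_iv, rule=cfg.rule)
        if printed_letters is not None:
            parts = []
            for ins, sub in tox.groupby("insecticide"):
                parts.append(
                    attr.letter_discrepancies(
                        attr.intervals_from_frame(sub),
                        printed_letters[ins].to_dict(),
                    )
                )
            discrepancies = pd.concat(parts, ignore_index=True)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("attribution", str(exc)) from exc

    letters_rows = []
    for ins, sub in dest_tox.groupby("insecticide"):
        cld = attr.compact_letter_display(attr.intervals_from_frame(sub))
        for pid, let in cld.letters.items():
            letters_rows.append({"insecticide": ins, "population_id": pid, "letters": let})
    pd.DataFrame(letters_rows).to_csv(outdir / "letters.csv", index=False)
    pooled_rows = [
        {"group": g, "insecticide": ins, "lower": lo, "upper": hi}
        for (g, ins), (lo, hi) in sorted(result.pooled.items())
    ]
    pd.DataFrame(pooled_rows).to_csv(outdir / "pooled.csv", index=False)
    result.decisions.to_csv(outdir / "decisions.csv", index=False)
    discrepancies.to_csv(outdir / "discrepancies.csv", index=False)
    match_rows = [
        {"group": g, "sources": ";".join(srcs)} for g, srcs in sorted(result.matches.items())
    ]
    pd.DataFrame(match_rows).to_csv(outdir / "matches.csv", index=False)

    report["stages"]["attribution"] = {
        "groups": result.groups,
        "matches": result.matches,
        "unmatched_sources": result.unmatched_sources,
        "n_letter_discrepancies": int(len(discrepancies)),
    }
    report["discrepancies"] = discrepancies.to_dict(orient="records")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
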