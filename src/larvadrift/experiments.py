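"""Experiment orchestration: one config in, an artifact directory out.

An experiment runs one cell of the validation grid — Base (record-and-keep)
or Invasion (remove-on-recruit), with or without DVM, one of three growth
modes, mortality on (three replicates sharing trajectories) or off — on a
synthetic ocean generated from the same master seed.  All sub-seeds (wind,
release positions, physics turbulence, each mortality replicate) are derived
deterministically from the master seed, so identical configs give identical
outputs and every artifact is regenerable from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biology import BioConfig
from .engine import run_tracker
from .exceptions import ConfigurationError
from .lagrangian import TrackerConfig
from .ocean import OceanParams, default_grid, generate_wind_series, wind_to_fields, write_archive
from .recruitment import average_replicates
from .release import ReleaseConfig, build_release_plan, default_estuaries, load_estuaries
from .stats import dispersal_summary, survival_summary, trajectory_density


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    mode: str = "invasion"            # base | invasion
    dvm: bool = True
    growth_mode: str = "normal"       # normal | fast | slow
    mortality_on: bool = True
    replicates: int | None = None     # default: 3 with mortality, else 1
    master_seed: int = 0
    # ocean
    duration_days: float = 120.0
    wind_amplitude: float = 0.05
    wind_event_scale_days: float = 5.0
    grid_x_max_km: float = 60.0
    grid_y_max_km: float = 800.0
    background_v: float = -0.03
    # release
    season_start: str = "2006-02-01"
    season_days: int = 70
    larvae_per_night: int = 225
    estuary_table: str | None = None  # CSV path; None -> shipped defaults
    focal_estuary: str = "Aveiro"
    # tracking
    dt_seconds: float = 300.0
    w_turb_sigma: float = 1e-3
    # outputs
    outdir: str = "experiment_out"
    save_archive: bool = False
    record_trajectories: bool = False

    def validate(self) -> None:
        bad = []
        if self.mode not in ("base", "invasion"):
            bad.append("mode")
        if self.growth_mode not in ("normal", "fast", "slow"):
            bad.append("growth_mode")
        if self.duration_days <= 0:
            bad.append("duration_days")
        if self.season_days <= 0 or self.season_days > self.duration_days:
            bad.append("season_days")
        if self.larvae_per_night <= 0:
            bad.append("larvae_per_night")
        if self.dt_seconds <= 0:
            bad.append("dt_seconds")
        if self.replicates is not None and self.replicates < 1:
            bad.append("replicates")
        if bad:
            raise ConfigurationError(f"invalid configuration keys: {', '.join(bad)}")

    @property
    def n_replicates(self) -> int:
        if self.replicates is not None:
            return self.replicates
        return 3 if self.mortality_on else 1

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(
                f"invalid configuration keys: {', '.join(sorted(unknown))}")
        return cls(**raw)


def derive_seeds(master_seed: int, n_replicates: int) -> dict:
    """Deterministic independent sub-seeds (< 2^31) from the master seed."""
    state = np.random.SeedSequence(int(master_seed)).generate_state(
        4 + n_replicates, dtype=np.uint64)
    vals = (state % (2 ** 31 - 1)).astype(np.int64)
    return {
        "wind": int(vals[0]),
        "release": int(vals[1]),
        "physics": int(vals[2]),
        "replicates": [int(v) for v in vals[4:4 + n_replicates]],
    }


def run_experiment(config: ExperimentConfig) -> Path:
    """Run one experiment end-to-end, writing its artifact directory."""
    config.validate()
    outdir = Path(config.outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, outdir)
    except Exception:
        # remove partial outputs so a failed run leaves no half-written state
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        else:
            for p in outdir.glob("*"):
                if p.is_file():
                    p.unlink()
        raise


def _run(config: ExperimentConfig, outdir: Path) -> Path:
    seeds = derive_seeds(config.master_seed, config.n_replicates)
    estuaries = (load_estuaries(config.estuary_table)
                 if config.estuary_table else default_estuaries())
    if config.focal_estuary not in {e.name for e in estuaries}:
        raise ConfigurationError("invalid configuration keys: focal_estuary")

    grid = default_grid(x_max_km=config.grid_x_max_km,
                        y_max_km=config.grid_y_max_km)
    wind = generate_wind_series(config.duration_days,
                                config.wind_event_scale_days,
                                config.wind_amplitude, seed=seeds["wind"])
    params = OceanParams(background_v=config.background_v)
    archive = wind_to_fields(wind, grid, params,
                             [(e.y_center_km, 0.0) for e in estuaries])
    if config.save_archive:
        write_archive(archive, outdir / "archive.nc")

    start = pd.Timestamp(config.season_start)
    plan = build_release_plan(
        estuaries, start, start + pd.Timedelta(days=config.season_days),
        ReleaseConfig(larvae_per_night=config.larvae_per_night),
        seed=seeds["release"])
    plan.to_csv(outdir / "release_plan.csv")

    tracker_cfg = TrackerConfig(dt_seconds=config.dt_seconds,
                                w_turb_sigma=config.w_turb_sigma,
                                dvm=config.dvm, seed=seeds["physics"])
    bio_cfg = BioConfig(growth_mode=config.growth_mode,
                        mortality_on=config.mortality_on)
    result = run_tracker(archive, plan, tracker_cfg, bio_cfg, config.mode,
                         replicate_seeds=tuple(seeds["replicates"]),
                         record=config.record_trajectories)

    result.events.to_csv(outdir / "events.csv", index=False)
    series = [result.supply(config.focal_estuary, r)
              for r in range(result.n_replicates)]
    for r, s in enumerate(series):
        s.to_csv(outdir / f"supply_{config.focal_estuary}_rep{r}.csv")
    average_replicates(series).to_csv(
        outdir / f"supply_{config.focal_estuary}_mean.csv")

    focal = next(e for e in estuaries if e.name == config.focal_estuary)
    disp = dispersal_summary(result.events, estuaries, config.focal_estuary,
                             replicate=0)
    pd.DataFrame([{
        "destination": disp.destination, "n_recruits": disp.n_recruits,
        "mean_south_km": disp.mean_south_km, "mean_north_km": disp.mean_north_km,
        "max_south_km": disp.max_south_km, "max_north_km": disp.max_north_km,
        "self_recruitment_fraction": disp.self_recruitment_fraction,
    }]).to_csv(outdir / "dispersal_summary.csv", index=False)
    disp.daily_contribution.rename("events_per_day").to_csv(
        outdir / "daily_contribution.csv")

    surv_rows = []
    for r in range(result.n_replicates):
        s = survival_summary(result.fate[r])
        surv_rows.append({"replicate": r, "n_hatched": s.n_hatched,
                          "pct_recruited": s.pct_recruited,
                          "pct_died_physiology": s.pct_died_physiology,
                          "pct_wastage": s.pct_wastage,
                          **{f"n_{n}": c for n, c in
                             result.fate_counts(r).items()}})
    pd.DataFrame(surv_rows).to_csv(outdir / "survival_summary.csv", index=False)

    if config.record_trajectories:
        band = (focal.y_center_km - 80.0, focal.y_center_km + 80.0)
        dens = trajectory_density(result.traj_x, result.traj_y, band,
                                  grid.x_edges)
        dens.to_frame().to_csv(outdir / "trajectory_density.csv", index=False)

    cfg_dict = asdict(config)
    hashed = {k: v for k, v in cfg_dict.items() if k != "outdir"}
    manifest = {
        "package": "larvadrift",
        "version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(hashed, sort_keys=True).encode()).hexdigest(),
        "seeds": seeds,
        "n_emitted": int(plan.n_total),
        "n_pulses": int(plan.n_pulses),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
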