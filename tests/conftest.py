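"""Shared fixtures: synthetic archives and the desk-scale reference run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import larvadrift as ld

# Desk-scale conditions for the reference Invasion run: 120-day ocean,
# six fortnightly pulses from eight estuaries, 450 larvae per night (86,400
# emitted -- the full annual emission total compressed into the window),
# mortality on with two replicates sharing trajectories.
REFERENCE_RUN = dict(duration_days=120.0, season_days=74, larvae_per_night=450,
                     wind_seed=11, release_seed=12, physics_seed=13,
                     replicate_seeds=(21, 22), focal="Aveiro")


@pytest.fixture(scope="session")
def estuaries():
    return ld.default_estuaries()


@pytest.fixture(scope="session")
def coarse_archive():
    """30-day archive over a 3-estuary sub-domain, for generic field tests."""
    ests = ld.default_estuaries()[1:4]  # Mondego, Aveiro, Cavado
    wind = ld.generate_wind_series(30, event_scale_days=5.0, amplitude=0.05,
                                   seed=101)
    grid = ld.default_grid(y_max_km=500.0)
    archive = ld.wind_to_fields(wind, grid, ld.OceanParams(),
                                [(e.y_center_km, 0.0) for e in ests])
    return archive, ests


@pytest.fixture(scope="session")
def reference_run(estuaries):
    """The desk-scale Invasion run with two mortality replicates.

    Shared by the replicate-consistency, lag-recovery and bookkeeping tests
    (it is by far the most expensive fixture in the suite).
    """
    p = REFERENCE_RUN
    wind = ld.generate_wind_series(p["duration_days"], event_scale_days=5.0,
                                   amplitude=0.05, seed=p["wind_seed"])
    grid = ld.default_grid()
    archive = ld.wind_to_fields(wind, grid, ld.OceanParams(),
                                [(e.y_center_km, 0.0) for e in estuaries])
    start = pd.Timestamp("2006-02-01")
    plan = ld.build_release_plan(
        estuaries, start, start + pd.Timedelta(days=p["season_days"]),
        ld.ReleaseConfig(larvae_per_night=p["larvae_per_night"]),
        seed=p["release_seed"])
    result = ld.run_tracker(
        archive, plan,
        ld.TrackerConfig(seed=p["physics_seed"]),
        ld.BioConfig(mortality_on=True),
        mode="invasion",
        replicate_seeds=p["replicate_seeds"])
    return result


def make_analytic_archive(u_fn, v_fn, grid, duration_hours=240.0,
                          interval_hours=4.0, T=15.0, S=34.0):
    """Archive whose u/v are analytic functions of (x, y) km; w = 0."""
    times = np.arange(0.0, duration_hours + interval_hours / 2, interval_hours)
    X, Y = np.meshgrid(grid.x_centers, grid.y_centers, indexing="xy")
    u2d = np.broadcast_to(u_fn(X, Y), (grid.ny, grid.nx)).astype(np.float32)
    v2d = np.broadcast_to(v_fn(X, Y), (grid.ny, grid.nx)).astype(np.float32)
    shape = (times.size, grid.nz, grid.ny, grid.nx)
    u = np.broadcast_to(u2d, shape).copy()
    v = np.broadcast_to(v2d, shape).copy()
    w = np.zeros(shape, dtype=np.float32)
    Tf = np.full(shape, T, dtype=np.float32)
    Sf = np.full(shape, S, dtype=np.float32)
    return ld.FieldArchive(grid, times, u, v, w, Tf, Sf)
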