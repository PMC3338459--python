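"""The particle-tracking engine: couples fields, behaviour, biology, recruitment.

One run advances every larva of a release plan through an archived flow field
at a fixed step (default 300 s), evaluating age and the probability of death
at every step, and scanning for recruitment-box crossings.

Randomness is split into independent streams so that experiments compose:

- *physics* (vertical turbulence) is seeded by the tracker seed and drawn
  positionally over the emitted-particle slots, so trajectories do not depend
  on particle ordering, on how many mortality replicates run, or on which
  particles are alive;
- *mortality* gets one stream per replicate seed, consumed only for that
  replicate's own still-in-water particles (in slot order), so a replicate's
  kill set does not depend on which other replicates run alongside it.

Several mortality replicates therefore share bitwise-identical trajectories
while their kill sets are independent — the property behind averaging
replicate supply series and checking their lag-0 cross-correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import biology
from .biology import (BioConfig, FATE_DIED_AGE, FATE_DIED_PHYSIOLOGY,
                      FATE_IN_WATER, FATE_LEFT_DOMAIN, FATE_NAMES,
                      FATE_RECRUITED, GrowthTable, MortalityTable)
from .exceptions import ParameterError
from .lagrangian import FieldSampler, TrackerConfig, dvm_target_depth, vertical_update
from .ocean import FieldArchive
from .recruitment import EVENT_COLUMNS, SupplySeries, box_membership, build_supply_series
from .release import ReleasePlan

_KM_PER_M = 1e-3


@dataclass
class RunResult:
    """Outputs of one tracking run (possibly several mortality replicates)."""

    plan: ReleasePlan
    mode: str
    replicate_seeds: tuple
    fate: np.ndarray    # (R, N) int8 fate codes
    t_fate: np.ndarray  # (R, N) hours, NaN while in water
    age_final: np.ndarray
    x_final: np.ndarray  # positions frozen at each particle's fate time
    y_final: np.ndarray
    z_final: np.ndarray
    events: pd.DataFrame
    t_end_h: float
    record_times: np.ndarray | None = None
    traj_x: np.ndarray | None = None  # (n_rec, N) float32, NaN when not in water
    traj_y: np.ndarray | None = None
    traj_z: np.ndarray | None = None

    @property
    def n_replicates(self) -> int:
        return self.fate.shape[0]

    @property
    def origin(self) -> pd.Timestamp:
        return self.plan.season_start

    def fate_counts(self, replicate: int = 0) -> dict:
        f = self.fate[replicate]
        return {name: int(np.sum(f == code)) for code, name in FATE_NAMES.items()}

    def calendar(self) -> pd.DatetimeIndex:
        n_days = int(np.ceil(self.t_end_h / 24.0))
        return pd.date_range(self.origin.normalize(), periods=n_days, freq="D")

    def supply(self, destination: str, replicate: int = 0) -> SupplySeries:
        ev = self.events
        sel = ev[ev["replicate"] == replicate] if len(ev) else ev
        return build_supply_series(sel, destination, self.calendar(), self.origin)


def run_tracker(archive: FieldArchive, plan: ReleasePlan,
                tracker_cfg: TrackerConfig | None = None,
                bio_cfg: BioConfig | None = None,
                mode: str = "invasion",
                growth_table: GrowthTable | None = None,
                mortality_table: MortalityTable | None = None,
                replicate_seeds: tuple = (0,),
                record: bool = False) -> RunResult:
    """Advance all planned larvae through the archive; see module docstring."""
    if mode not in ("base", "invasion"):
        raise ParameterError(f"unknown experiment mode {mode!r}")
    cfg = tracker_cfg or TrackerConfig()
    bio = bio_cfg or BioConfig()
    growth = growth_table or biology.default_growth_table()
    mort = mortality_table or biology.default_mortality_table()
    sampler = FieldSampler(archive)
    grid = archive.grid
    estuaries = plan.estuaries
    y_centers = np.array([e.y_center_km for e in estuaries])
    est_names = np.array([e.name for e in estuaries])

    N = plan.n_total
    R = len(replicate_seeds)
    x = np.zeros(N)
    y = np.zeros(N)
    z = np.zeros(N)
    age = np.zeros(N)
    active = np.zeros(N, dtype=bool)
    fate = np.full((R, N), FATE_IN_WATER, dtype=np.int8)
    t_fate = np.full((R, N), np.nan)
    prev_box = np.full(N, -1, dtype=np.int16)

    phys_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    mort_rngs = [np.random.default_rng(np.random.SeedSequence([int(s), 1]))
                 for s in replicate_seeds]

    dt_h = cfg.dt_hours
    dt_d = cfg.dt_days
    dt_km = cfg.dt_seconds * _KM_PER_M
    t0, t_end = sampler.t_span
    n_steps = int(round((t_end - t0) / dt_h))
    x_off = grid.x_edges[-1]
    y_lo, y_hi = grid.y_edges[0], grid.y_edges[-1]
    x_eps = 0.02 * (grid.x_edges[1] - grid.x_edges[0])

    if record:
        rec_every = max(1, int(round(cfg.record_interval_hours / dt_h)))
        n_rec = n_steps // rec_every + 1
        rec_times = np.empty(n_rec)
        tx = np.full((n_rec, N), np.nan, dtype=np.float32)
        ty = np.full((n_rec, N), np.nan, dtype=np.float32)
        tz = np.full((n_rec, N), np.nan, dtype=np.float32)
        k_rec = 0
    ev_rows: list[tuple] = []

    n_em = 0
    t = t0
    for step in range(n_steps + 1):
        # --- emit larvae due by now ---------------------------------------
        hi = np.searchsorted(plan.t_release_h, t + 1e-9, side="right")
        if hi > n_em:
            sl = slice(n_em, hi)
            x[sl] = plan.x0[sl]
            y[sl] = plan.y0[sl]
            z[sl] = plan.z0[sl]
            age[sl] = 0.0
            active[sl] = True
            prev_box[sl] = box_membership(x[sl], y[sl], estuaries)
            n_em = hi

        if record and step % rec_every == 0:
            rec_times[k_rec] = t
            if n_em:
                liv = active[:n_em]
                tx[k_rec, :n_em] = np.where(liv, x[:n_em], np.nan)
                ty[k_rec, :n_em] = np.where(liv, y[:n_em], np.nan)
                tz[k_rec, :n_em] = np.where(liv, z[:n_em], np.nan)
            k_rec += 1
        if step == n_steps:
            break

        # positional physics draws over all emitted slots keep trajectories
        # aligned across replicates and independent of aliveness
        turb = phys_rng.standard_normal(n_em) if cfg.w_turb_sigma > 0 else None

        act = np.flatnonzero(active[:n_em])
        if act.size == 0:
            t = t0 + (step + 1) * dt_h
            continue
        xa, ya, za = x[act], y[act], z[act]

        u1, v1, w1, T1, S1 = sampler.sample(xa, ya, za, t)
        stage0 = np.minimum(age[act].astype(np.intp), 4)

        # --- Heun horizontal step -----------------------------------------
        xp = xa + u1 * dt_km
        yp = ya + v1 * dt_km
        t2 = min(t + dt_h, t_end)
        u2, v2 = sampler.sample(xp, yp, za, t2, ("u", "v"))
        xn = xa + 0.5 * (u1 + u2) * dt_km
        yn = ya + 0.5 * (v1 + v2) * dt_km

        # --- vertical: advection + DVM + turbulence -----------------------
        depth = grid.depth_at(np.maximum(xn, x_eps), np.clip(yn, y_lo, y_hi))
        if cfg.dvm:
            target = dvm_target_depth(t % 24.0, depth, cfg.dvm_cfg)
        else:
            target = za
        tn = turb[act] if turb is not None else np.zeros(act.size)
        zn = vertical_update(za, w1, target, depth, cfg, tn, dvm_on=cfg.dvm)

        # --- boundaries ----------------------------------------------------
        xn = np.maximum(xn, x_eps)  # onshore overshoot -> nearest wet position
        left = (xn > x_off) | (yn < y_lo) | (yn > y_hi)
        x[act], y[act], z[act] = xn, yn, zn

        t_next = t0 + (step + 1) * dt_h
        if np.any(left):
            slots = act[left]
            for r in range(R):
                m = fate[r, slots] == FATE_IN_WATER
                fate[r, slots[m]] = FATE_LEFT_DOMAIN
                t_fate[r, slots[m]] = t_next
            active[slots] = False

        # --- growth and senescence ----------------------------------------
        new_age, died_age = biology.advance_age(
            age[act], T1, dt_d, bio.growth_mode, growth)
        age[act] = new_age
        if np.any(died_age):
            slots = act[died_age & ~left]
            for r in range(R):
                m = fate[r, slots] == FATE_IN_WATER
                fate[r, slots[m]] = FATE_DIED_AGE
                t_fate[r, slots[m]] = t_next
            active[slots] = False

        # --- physiological mortality (per replicate) ----------------------
        # each replicate's stream is consumed only for its own still-in-water
        # particles, so a replicate's kill set does not depend on which other
        # replicates run alongside it
        if bio.mortality_on:
            p = biology.death_probability(stage0, T1, S1, dt_d, mort)
            for r in range(R):
                cand = fate[r, act] == FATE_IN_WATER
                u_r = mort_rngs[r].uniform(size=int(cand.sum()))
                killed = u_r < p[cand]
                if np.any(killed):
                    slots = act[cand][killed]
                    fate[r, slots] = FATE_DIED_PHYSIOLOGY
                    t_fate[r, slots] = t_next

        # --- recruitment-box crossings ------------------------------------
        boxes = box_membership(x[act], y[act], estuaries)
        entered = (boxes >= 0) & (boxes != prev_box[act])
        competent = (age[act] >= 4.0) & (age[act] < 5.0) & ~left
        cand = entered & competent
        if np.any(cand):
            slots = act[cand]
            dest = boxes[cand]
            for r in range(R):
                ok = fate[r, slots] == FATE_IN_WATER
                for s, d in zip(slots[ok], dest[ok]):
                    si = plan.source_idx[s]
                    ev_rows.append((r, int(s), est_names[si], est_names[d],
                                    t_next, float(age[s]),
                                    y_centers[si], y_centers[d]))
                if mode == "invasion":
                    fate[r, slots[ok]] = FATE_RECRUITED
                    t_fate[r, slots[ok]] = t_next
        prev_box[act] = boxes

        # stop stepping particles resolved in every replicate
        if mode == "invasion":
            unresolved = (fate[:, act] == FATE_IN_WATER).any(axis=0)
            active[act] &= unresolved

        t = t_next

    events = pd.DataFrame(ev_rows, columns=list(EVENT_COLUMNS))
    result = RunResult(plan, mode, tuple(replicate_seeds), fate, t_fate,
                       age.copy(), x.copy(), y.copy(), z.copy(),
                       events, t_end - t0)
    if record:
        result.record_times = rec_times[:k_rec]
        result.traj_x = tx[:k_rec]
        result.traj_y = ty[:k_rec]
        result.traj_z = tz[:k_rec]
    return result
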