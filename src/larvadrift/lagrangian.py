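"""Particle kinematics: field interpolation, advection, vertical behaviour.

Particles are advanced through archived fields with a two-stage
predictor-corrector (Heun) scheme on the horizontal components; vertical
position combines vertical advection, swimming toward the diel vertical
migration (DVM) target depth, and a random-walk parameterisation of
unresolved turbulence, with reflection at the surface and bottom.

The DVM scheme forces larvae to drift at depth between 06 h and 20 h local
time and at the surface between 22 h and 04 h; during the two-hour dusk and
dawn windows the target ramps linearly between the two levels.  The deep
level is the bottom layer where the water column is shallower than 60 m, and
60 m where it is deeper.

All operations are vectorised over particle arrays.  Positions are (x, y) in
km and z in m (depth, positive down); velocities are in m s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .exceptions import ConfigurationError, ParameterError
from .ocean import FieldArchive, ShelfGrid

_KM_PER_M = 1e-3


@njit(cache=True, fastmath=False)
def _gather_quadlinear(A, base0, st, sy, sz,
                       w000, w001, w010, w011, w100, w101, w110, w111, wt,
                       out):  # pragma: no cover - exercised via FieldSampler
    """Two trilinear gathers (bracketing snapshots) blended linearly in time."""
    n = base0.size
    for p in range(n):
        b = base0[p]
        v0 = (w000[p] * A[b] + w001[p] * A[b + 1]
              + w010[p] * A[b + sy] + w011[p] * A[b + sy + 1]
              + w100[p] * A[b + sz] + w101[p] * A[b + sz + 1]
              + w110[p] * A[b + sz + sy] + w111[p] * A[b + sz + sy + 1])
        if wt == 0.0:
            out[p] = v0
        else:
            b = b + st
            v1 = (w000[p] * A[b] + w001[p] * A[b + 1]
                  + w010[p] * A[b + sy] + w011[p] * A[b + sy + 1]
                  + w100[p] * A[b + sz] + w101[p] * A[b + sz + 1]
                  + w110[p] * A[b + sz + sy] + w111[p] * A[b + sz + sy + 1])
            out[p] = (1.0 - wt) * v0 + wt * v1


@dataclass(frozen=True)
class DVMConfig:
    """Diel vertical migration windows (hours, local solar time) and levels."""

    day_start: float = 6.0     # start of at-depth drift
    day_end: float = 20.0      # start of dusk ascent
    night_start: float = 22.0  # start of at-surface drift
    night_end: float = 4.0     # start of dawn descent
    deep_max_m: float = 60.0   # deep level cap where the column is deeper
    surface_depth_m: float = 1.0
    bottom_clearance_m: float = 2.0


@dataclass(frozen=True)
class TrackerConfig:
    """Integration and behaviour parameters for the particle tracker."""

    dt_seconds: float = 300.0
    w_turb_sigma: float = 1e-3   # std of random vertical velocity, m s^-1
    w_swim: float = 0.01         # DVM swimming speed, m s^-1
    dvm: bool = True
    dvm_cfg: DVMConfig = field(default_factory=DVMConfig)
    seed: int = 0
    record_interval_hours: float = 2.0
    boundary_policy_offshore: str = "open"
    boundary_policy_onshore: str = "coast"

    def __post_init__(self):
        if self.dt_seconds <= 0:
            raise ParameterError("dt_seconds must be positive")

    @property
    def dt_hours(self) -> float:
        return self.dt_seconds / 3600.0

    @property
    def dt_days(self) -> float:
        return self.dt_seconds / 86400.0


class FieldSampler:
    """Trilinear-in-space, linear-in-time sampler over an archive.

    Exact at grid nodes and snapshot times; queries outside the cell-center
    envelope are clamped (nearest-edge extrapolation), out-of-domain handling
    being the responsibility of the boundary step.
    """

    _NAMES = ("u", "v", "w", "T", "S")

    def __init__(self, archive: FieldArchive):
        g = archive.grid
        self.grid = g
        self._flat = {n: np.ascontiguousarray(
            getattr(archive, n), dtype=np.float32).ravel() for n in self._NAMES}
        self._t = archive.snapshot_times
        self._nt = self._t.size
        self._nz, self._ny, self._nx = g.nz, g.ny, g.nx
        self._sz = self._ny * self._nx
        self._st = self._nz * self._sz
        xc, yc, zc = g.x_centers, g.y_centers, g.z_centers
        self._x0, self._invdx = xc[0], 1.0 / (xc[1] - xc[0])
        self._y0, self._invdy = yc[0], 1.0 / (yc[1] - yc[0])
        if g.nz > 1:
            self._z0, self._invdz = zc[0], 1.0 / (zc[1] - zc[0])
        else:
            self._z0, self._invdz = zc[0], 0.0
        self._t0 = self._t[0]
        self._invdt = 1.0 / (self._t[1] - self._t[0]) if self._nt > 1 else 0.0
        self.t_span = (float(self._t[0]), float(self._t[-1]))

    @staticmethod
    def _axis(q, q0, inv, n):
        f = np.clip((np.asarray(q, float) - q0) * inv, 0.0, max(n - 1, 0))
        i = np.minimum(f.astype(np.intp), max(n - 2, 0))
        return i, f - i

    def sample(self, x, y, z, t, names=("u", "v", "w", "T", "S")):
        """Sample the named fields at particle positions and a common time.

        ``t`` is a scalar (all particles share the simulation clock); the
        16-point gather runs in a compiled kernel.
        """
        ix, wx = self._axis(x, self._x0, self._invdx, self._nx)
        iy, wy = self._axis(y, self._y0, self._invdy, self._ny)
        iz, wz = self._axis(z, self._z0, self._invdz, self._nz)
        ft = min(max((float(t) - self._t0) * self._invdt, 0.0),
                 max(self._nt - 1, 0))
        it = min(int(ft), max(self._nt - 2, 0))
        wt = ft - it
        base0 = it * self._st + iz * self._sz + iy * self._nx + ix
        # 8 spatial corner weights, shared across variables and time slices
        wx0, wy0, wz0 = 1.0 - wx, 1.0 - wy, 1.0 - wz
        w000 = wz0 * wy0 * wx0
        w001 = wz0 * wy0 * wx
        w010 = wz0 * wy * wx0
        w011 = wz0 * wy * wx
        w100 = wz * wy0 * wx0
        w101 = wz * wy0 * wx
        w110 = wz * wy * wx0
        w111 = wz * wy * wx
        out = []
        for name in names:
            res = np.empty(base0.size)
            _gather_quadlinear(self._flat[name], base0, self._st, self._nx,
                               self._sz, w000, w001, w010, w011, w100, w101,
                               w110, w111, wt, res)
            out.append(res)
        return tuple(out)


def interpolate_fields(archive: FieldArchive, X, t):
    """(u, v, w, T, S) at positions ``X`` (n, 3: x km, y km, z m) and time t (h)."""
    X = np.atleast_2d(np.asarray(X, float))
    sampler = archive if isinstance(archive, FieldSampler) else FieldSampler(archive)
    return sampler.sample(X[:, 0], X[:, 1], X[:, 2], t)


def step_position(X, t, archive, cfg: TrackerConfig):
    """One Heun (predictor-corrector) step of the horizontal motion.

    Predictor: Euler with the velocity at (X, t); corrector: trapezoidal
    average with the velocity at the predicted position and t + dt.  The
    vertical coordinate is untouched (see :func:`apply_vertical`).
    """
    X = np.atleast_2d(np.asarray(X, float)).copy()
    sampler = archive if isinstance(archive, FieldSampler) else FieldSampler(archive)
    x, y, z = X[:, 0], X[:, 1], X[:, 2]
    dt_km = cfg.dt_seconds * _KM_PER_M
    u1, v1 = sampler.sample(x, y, z, t, ("u", "v"))
    xp = x + u1 * dt_km
    yp = y + v1 * dt_km
    t2 = min(t + cfg.dt_hours, sampler.t_span[1])
    u2, v2 = sampler.sample(xp, yp, z, t2, ("u", "v"))
    X[:, 0] = x + 0.5 * (u1 + u2) * dt_km
    X[:, 1] = y + 0.5 * (v1 + v2) * dt_km
    return X


def dvm_target_depth(t_local, local_depth, cfg: DVMConfig | None = None):
    """Target depth (m) of the DVM scheme at local solar time ``t_local`` (h).

    Day: the deep level (bottom layer or ``deep_max_m``, whichever is
    shallower); night: the surface layer; dusk/dawn: a linear ramp between
    the two (the "transit" state).
    """
    cfg = cfg or DVMConfig()
    t = float(t_local) % 24.0
    depth = np.asarray(local_depth, float)
    deep = np.minimum(depth - cfg.bottom_clearance_m, cfg.deep_max_m)
    deep = np.maximum(deep, cfg.surface_depth_m)
    surf = cfg.surface_depth_m
    if cfg.day_start <= t < cfg.day_end:
        return deep
    if t >= cfg.night_start or t < cfg.night_end:
        return np.full_like(deep, surf)
    if cfg.day_end <= t < cfg.night_start:  # dusk ascent
        frac = (t - cfg.day_end) / (cfg.night_start - cfg.day_end)
        return deep + (surf - deep) * frac
    # dawn descent
    frac = (t - cfg.night_end) / (cfg.day_start - cfg.night_end)
    return surf + (deep - surf) * frac


def vertical_update(z, w_adv, target, local_depth, cfg: TrackerConfig,
                    turb_normals, dvm_on: bool = True):
    """Advance depths one step: advection + DVM swimming + turbulence.

    The swim term moves toward ``target`` at speed at most ``w_swim``
    (compensating vertical advection within that capability, so a particle at
    its target holds depth); the turbulence term is a random vertical
    velocity N(0, w_turb_sigma) applied over dt.  Depths reflect at the
    surface and the local bottom.
    """
    z = np.asarray(z, float)
    dt = cfg.dt_seconds
    z_adv = z + np.asarray(w_adv, float) * dt
    if dvm_on:
        swim = np.clip(np.asarray(target, float) - z_adv,
                       -cfg.w_swim * dt, cfg.w_swim * dt)
        z_adv = z_adv + swim
    z_new = z_adv + np.asarray(turb_normals, float) * cfg.w_turb_sigma * dt
    # reflect at surface and bottom
    z_new = np.abs(z_new)
    bottom = np.asarray(local_depth, float)
    over = z_new > bottom
    if np.any(over):
        z_new = np.where(over, 2.0 * bottom - z_new, z_new)
    return np.clip(z_new, 0.0, bottom)


def apply_vertical(X, t, archive, cfg: TrackerConfig, rng):
    """Convenience vertical step for positions ``X`` (n, 3) at time t (h)."""
    X = np.atleast_2d(np.asarray(X, float)).copy()
    sampler = archive if isinstance(archive, FieldSampler) else FieldSampler(archive)
    x, y, z = X[:, 0], X[:, 1], X[:, 2]
    (w,) = sampler.sample(x, y, z, t, ("w",))
    depth = sampler.grid.depth_at(x, y)
    target = dvm_target_depth(t % 24.0, depth, cfg.dvm_cfg) if cfg.dvm else z
    turb = rng.standard_normal(x.size) if cfg.w_turb_sigma > 0 else np.zeros(x.size)
    X[:, 2] = vertical_update(z, w, target, depth, cfg, turb, dvm_on=cfg.dvm)
    return X


def handle_boundary(x, y, grid: ShelfGrid, policy: str):
    """Apply one boundary policy to horizontal positions.

    "open": flag particles beyond the offshore or alongshore edges as having
    left the domain (returns ``(x, y, left_mask)``); "coast": reposition
    onshore overshoots (x < 0) to the nearest wet location (no beaching
    deaths; ``left_mask`` all False).
    """
    x = np.asarray(x, float).copy()
    y = np.asarray(y, float).copy()
    if policy == "open":
        left = ((x > grid.x_edges[-1])
                | (y < grid.y_edges[0]) | (y > grid.y_edges[-1]))
        return x, y, left
    if policy == "coast":
        eps = 0.02 * (grid.x_edges[1] - grid.x_edges[0])
        np.copyto(x, np.maximum(x, eps))
        return x, y, np.zeros(x.shape, dtype=bool)
    raise ConfigurationError(f"unknown boundary policy {policy!r}")
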