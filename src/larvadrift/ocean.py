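"""Idealized wind-driven shelf circulation, archived like stored ocean-model output.

The domain is a straight-coast Cartesian shelf: the coast lies at ``x = 0`` with
``x`` positive offshore (km), ``y`` positive poleward alongshore (km) and ``z``
positive downward (m).  Circulation is *kinematic*: an alongshore wind-stress
series is mapped to velocity, temperature and salinity fields through simple
transfer functions rather than by solving the primitive equations.

The cross-shore/vertical circulation is derived from an overturning
streamfunction :math:`\\psi(x, z)` held on a ghosted cell-center grid, with
``u = D_z psi`` and ``w = -D_x psi`` using the same centered difference
operators as the divergence check.  The discrete divergence
:math:`D_x u + D_z w` then vanishes identically (to rounding) at every
interior cell of every cross-section, and the depth-integrated cross-shore
transport telescopes to zero (a closed overturning cell), so particle
tracking sees a mass-conserving flow.  Under equatorward (upwelling-favourable, ``tau_y < 0``) wind the surface
branch is directed offshore with a compensating onshore return flow at depth;
poleward wind reverses the cell (coastal convergence/downwelling).

Fields are archived on a fixed interval (default 4 h) and written/read as
NetCDF, standing in for stored hydrodynamic-model output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import xarray as xr

from .exceptions import ConfigurationError, FormatError, ParameterError

RHO_SEAWATER = 1025.0  # kg m^-3
CORIOLIS_F = 9.3e-5  # s^-1, mid-latitude eastern-boundary shelf


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShelfGrid:
    """Regular shelf grid; edges in km (x, y) and m (z), bathymetry in m.

    Spacing must be uniform along each axis: the streamfunction construction
    relies on it for exact discrete non-divergence at cell centers.
    """

    x_edges: np.ndarray  # (nx+1,) km, 0 at coast, positive offshore
    y_edges: np.ndarray  # (ny+1,) km, positive poleward
    z_edges: np.ndarray  # (nz+1,) m, 0 at surface, positive down
    bathymetry: np.ndarray  # (ny, nx) m, depth of each water column

    def __post_init__(self):
        for name in ("x_edges", "y_edges", "z_edges"):
            e = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, e)
            if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
                raise ConfigurationError(f"{name} must be strictly increasing 1-D")
            if not np.allclose(np.diff(e), np.diff(e)[0]):
                raise ConfigurationError(f"{name} must be uniformly spaced")
        b = np.asarray(self.bathymetry, dtype=float)
        if b.shape != (self.ny, self.nx):
            raise ConfigurationError(
                f"bathymetry shape {b.shape} != (ny, nx) = {(self.ny, self.nx)}")
        if np.any(b <= 0):
            raise ConfigurationError("bathymetry must be positive everywhere wet")
        if np.any(np.diff(b, axis=1) < -1e-9):
            raise ConfigurationError("bathymetry must be non-decreasing offshore")
        object.__setattr__(self, "bathymetry", b)

    @property
    def nx(self) -> int:
        return self.x_edges.size - 1

    @property
    def ny(self) -> int:
        return self.y_edges.size - 1

    @property
    def nz(self) -> int:
        return self.z_edges.size - 1

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    def depth_at(self, x_km, y_km) -> np.ndarray:
        """Water depth (m) at horizontal positions, by bilinear interpolation
        of the column depths (clamped to the grid interior)."""
        x = np.clip(np.asarray(x_km, float), self.x_centers[0], self.x_centers[-1])
        y = np.clip(np.asarray(y_km, float), self.y_centers[0], self.y_centers[-1])
        fx = (x - self.x_centers[0]) / (self.x_centers[1] - self.x_centers[0])
        fy = (y - self.y_centers[0]) / (self.y_centers[1] - self.y_centers[0])
        ix = np.minimum(np.floor(fx).astype(np.intp), self.nx - 2)
        iy = np.minimum(np.floor(fy).astype(np.intp), self.ny - 2)
        wx, wy = fx - ix, fy - iy
        b = self.bathymetry
        return ((1 - wy) * ((1 - wx) * b[iy, ix] + wx * b[iy, ix + 1])
                + wy * ((1 - wx) * b[iy + 1, ix] + wx * b[iy + 1, ix + 1]))


def default_bathymetry_profile(x_km: np.ndarray) -> np.ndarray:
    """Monotone shelf profile: 40 m at the coast rising to 100 m at 30 km
    offshore, steepening to 500 m by 50 km (shelf break near 43 km), flat
    beyond.  The 40-m coastal depth keeps several vertical cells wet in the
    release boxes so the overturning cell is resolved over the inner shelf."""
    x = np.asarray(x_km, dtype=float)
    inner = 40.0 + 2.0 * x
    slope = 100.0 + 20.0 * (x - 30.0)
    return np.clip(np.where(x <= 30.0, inner, slope), 40.0, 500.0)


def default_grid(x_max_km: float = 60.0, y_max_km: float = 800.0,
                 dx_km: float = 3.0, dy_km: float = 20.0,
                 z_max_m: float = 500.0, dz_m: float = 10.0) -> ShelfGrid:
    """Build the default idealized shelf grid."""
    x_edges = np.arange(0.0, x_max_km + dx_km / 2, dx_km)
    y_edges = np.arange(0.0, y_max_km + dy_km / 2, dy_km)
    z_edges = np.arange(0.0, z_max_m + dz_m / 2, dz_m)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    bathy = np.tile(default_bathymetry_profile(xc), ((y_edges.size - 1), 1))
    return ShelfGrid(x_edges, y_edges, z_edges, bathy)


# ---------------------------------------------------------------------------
# wind
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindSeries:
    """Alongshore wind stress tau_y (N m^-2, positive poleward) on a uniform
    time grid (hours from start)."""

    t: np.ndarray
    tau_y: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, float)
        tau = np.asarray(self.tau_y, float)
        if t.size != tau.size or t.size < 2:
            raise ConfigurationError("wind series needs matching t/tau_y, length >= 2")
        if not np.allclose(np.diff(t), t[1] - t[0]):
            raise ConfigurationError("wind series time spacing must be uniform")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(tau))):
            raise ConfigurationError("wind series must be finite")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "tau_y", tau)

    @property
    def dt_hours(self) -> float:
        return float(self.t[1] - self.t[0])


def generate_wind_series(duration_days: float, event_scale_days: float = 5.0,
                         amplitude: float = 0.05, seed: int = 0,
                         dt_hours: float = 1.0) -> WindSeries:
    """Synthesize an alongshore wind-stress series with alternating
    upwelling/downwelling events.

    An AR(1) process with e-folding decorrelation time ``event_scale_days``
    and stationary standard deviation ``amplitude`` (N m^-2).  Zero mean, so
    equatorward (upwelling) and poleward (downwelling) events alternate on the
    event time scale, as observed over upwelling shelves in spring.
    """
    if duration_days <= 0:
        raise ParameterError("duration_days must be positive")
    if event_scale_days <= 0:
        raise ParameterError("event_scale_days must be positive")
    if amplitude < 0:
        raise ParameterError("amplitude must be non-negative")
    t = np.arange(0.0, duration_days * 24.0 + dt_hours / 2, dt_hours)
    rng = np.random.default_rng(seed)
    phi = np.exp(-dt_hours / (24.0 * event_scale_days))
    eps = rng.standard_normal(t.size)
    tau = np.empty(t.size)
    tau[0] = amplitude * eps[0]
    innov = amplitude * np.sqrt(1.0 - phi * phi)
    for n in range(1, t.size):
        tau[n] = phi * tau[n - 1] + innov * eps[n]
    return WindSeries(t, tau)


# ---------------------------------------------------------------------------
# wind -> fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OceanParams:
    """Transfer-function parameters mapping wind stress to circulation.

    The magnitudes are order-of-magnitude shelf values; all are exposed here
    because no single calibrated set exists for an idealized domain.
    """

    archive_interval_hours: float = 4.0
    adjust_time_days: float = 1.0       # geostrophic adjustment low-pass time scale
    v_gain: float = 2.0                 # alongshore current per unit stress (m s^-1 / N m^-2)
    v_decay_depth_m: float = 80.0       # e-folding depth of the alongshore jet
    background_v: float = -0.03         # mean alongshore drift (m s^-1, negative = equatorward)
    ekman_ramp_km: float = 15.0         # cross-shore ramp of the overturning cell
    rho: float = RHO_SEAWATER
    f: float = CORIOLIS_F
    T_bottom: float = 11.0              # deg C
    T_surface_excess: float = 6.0       # surface minus bottom, deg C
    thermocline_m: float = 80.0
    upwelling_cooling: float = 2.0      # max coastal SST drop per amplitude-scaled event, deg C
    upwelling_tau_ref: float = 0.1      # N m^-2 scaling the cooling response
    cooling_xscale_km: float = 15.0
    cooling_zscale_m: float = 50.0
    S_ocean: float = 35.8               # psu
    plume_anomaly: float = 2.0          # psu freshening at estuary mouths
    plume_xscale_km: float = 10.0
    plume_yscale_km: float = 15.0
    plume_zscale_m: float = 20.0


@dataclass
class FieldArchive:
    """Time-stamped gridded snapshots of u, v, w (m s^-1), T (deg C), S (psu).

    Arrays have shape ``(time, z, y, x)`` at cell centers; snapshot_times are
    hours from the simulation origin.
    """

    grid: ShelfGrid
    snapshot_times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    T: np.ndarray
    S: np.ndarray

    def __post_init__(self):
        self.snapshot_times = np.asarray(self.snapshot_times, dtype=float)
        shape = (self.snapshot_times.size, self.grid.nz, self.grid.ny, self.grid.nx)
        for name in ("u", "v", "w", "T", "S"):
            a = getattr(self, name)
            if a.shape != shape:
                raise ConfigurationError(f"{name} shape {a.shape} != {shape}")

    @property
    def interval_hours(self) -> float:
        return float(self.snapshot_times[1] - self.snapshot_times[0])

    def to_dataset(self) -> xr.Dataset:
        g = self.grid
        coords = {
            "time": ("time", self.snapshot_times,
                     {"units": "h", "long_name": "hours since simulation start"}),
            "z": ("z", g.z_centers, {"units": "m", "positive": "down"}),
            "y": ("y", g.y_centers, {"units": "km", "positive": "poleward"}),
            "x": ("x", g.x_centers, {"units": "km", "positive": "offshore"}),
            "x_edge": ("x_edge", g.x_edges, {"units": "km"}),
            "y_edge": ("y_edge", g.y_edges, {"units": "km"}),
            "z_edge": ("z_edge", g.z_edges, {"units": "m"}),
        }
        dims = ("time", "z", "y", "x")
        data = {
            "u": (dims, self.u, {"units": "m s-1", "long_name": "cross-shore velocity"}),
            "v": (dims, self.v, {"units": "m s-1", "long_name": "alongshore velocity"}),
            "w": (dims, self.w, {"units": "m s-1", "long_name": "vertical velocity, positive down"}),
            "T": (dims, self.T, {"units": "degC", "long_name": "temperature"}),
            "S": (dims, self.S, {"units": "psu", "long_name": "salinity"}),
            "bathymetry": (("y", "x"), self.grid.bathymetry, {"units": "m"}),
        }
        ds = xr.Dataset(data, coords=coords)
        ds.attrs["axis_order"] = "time, z (down), y (poleward), x (offshore)"
        return ds


def _lowpass(tau: np.ndarray, dt_hours: float, time_scale_days: float) -> np.ndarray:
    """First-order exponential filter (geostrophic adjustment of the shelf)."""
    a = dt_hours / (dt_hours + 24.0 * time_scale_days)
    out = np.empty_like(tau)
    acc = tau[0]
    for n, v in enumerate(tau):
        acc += a * (v - acc)
        out[n] = acc
    return out


def overturning_velocities(grid: ShelfGrid, ramp_km: float):
    """(u_unit, w_unit) on cell centers for unit offshore transport.

    A streamfunction psi = F(x) G(z) is evaluated on a ghosted cell-center
    grid and differenced with the centered operators ``u = D_z psi``,
    ``w = -D_x psi`` — the same stencil as the divergence oracle — so the
    discrete cross-section divergence is zero by construction and the
    depth-integrated cross-shore transport telescopes to zero (closed cell).

    F ramps 0 -> 1 over ``ramp_km`` from the coast; G is 0 at the uppermost
    cell center, peaks at the second (the surface Ekman branch) and decays
    linearly to 0 at the deepest wet cell center (the return branch).
    """
    zc, xc = grid.z_centers, grid.x_centers
    dz = zc[1] - zc[0] if grid.nz > 1 else grid.z_edges[1] - grid.z_edges[0]
    dx_km = xc[1] - xc[0]
    dx_m = dx_km * 1e3
    zg = np.concatenate([[zc[0] - dz], zc, [zc[-1] + dz]])
    xg = np.concatenate([[xc[0] - dx_km], xc, [xc[-1] + dx_km]])
    F = np.clip(xg / ramp_km, 0.0, 1.0)
    H = np.interp(xg, xc, grid.bathymetry.min(axis=0))
    z_top = zc[0]
    z_peak = zc[1] if grid.nz > 1 else zc[0] + dz
    z_bot = H - dz / 2.0  # deepest wet cell-center level per column
    Z = zg[:, None]
    rising = np.clip((Z - z_top) / (z_peak - z_top), 0.0, 1.0)
    span = np.maximum(z_bot[None, :] - z_peak, 1e-9)
    falling = np.clip((z_bot[None, :] - Z) / span, 0.0, 1.0)
    G = np.where(z_bot[None, :] <= z_peak, 0.0, np.minimum(rising, falling))
    psi = F[None, :] * G  # (nz+2, nx+2), unit transport
    u_unit = (psi[2:, 1:-1] - psi[:-2, 1:-1]) / (2.0 * dz)
    w_unit = -(psi[1:-1, 2:] - psi[1:-1, :-2]) / (2.0 * dx_m)
    return u_unit, w_unit


def wind_to_fields(wind: WindSeries, grid: ShelfGrid,
                   params: OceanParams | None = None,
                   estuary_positions: list[tuple[float, float]] | None = None,
                   ) -> FieldArchive:
    """Map a wind-stress series onto archived 3-D fields.

    - alongshore ``v``: background drift plus ``v_gain`` times the low-pass
      filtered stress, decaying with depth;
    - cross-shore ``u`` and vertical ``w``: overturning streamfunction scaled
      by the filtered Ekman transport ``-tau_f / (rho f)`` (positive offshore
      at the surface under equatorward stress), non-divergent by construction;
    - ``T`` stratified, with coastal cooling during upwelling events;
    - ``S`` uniform open-ocean value with fixed low-salinity plumes at the
      given estuary mouth positions ``(y_center_km, x=0)``.
    """
    params = params or OceanParams()
    interval = params.archive_interval_hours
    step = interval / wind.dt_hours
    if abs(step - round(step)) > 1e-9 or round(step) < 1:
        raise ConfigurationError(
            "archive_interval_hours must be a positive multiple of the wind time step")
    step = int(round(step))
    tau_f_full = _lowpass(wind.tau_y, wind.dt_hours, params.adjust_time_days)
    times = wind.t[::step]
    tau_f = tau_f_full[::step]
    nt, nz, ny, nx = times.size, grid.nz, grid.ny, grid.nx

    u_unit, w_unit = overturning_velocities(grid, params.ekman_ramp_km)

    transport = -tau_f / (params.rho * params.f)     # m^2 s^-1, positive offshore
    u = (transport[:, None, None] * u_unit[None]).astype(np.float32)
    w = (transport[:, None, None] * w_unit[None]).astype(np.float32)
    u = np.repeat(u[:, :, None, :], ny, axis=2)
    w = np.repeat(w[:, :, None, :], ny, axis=2)

    v_prof = np.exp(-grid.z_centers / params.v_decay_depth_m)  # (nz,)
    v_tz = params.background_v + params.v_gain * tau_f[:, None] * v_prof[None]
    v = np.broadcast_to(v_tz[:, :, None, None].astype(np.float32),
                        (nt, nz, ny, nx)).copy()

    zc = grid.z_centers
    xc = grid.x_centers
    T_base = params.T_bottom + params.T_surface_excess * np.exp(-zc / params.thermocline_m)
    upw = np.maximum(-tau_f, 0.0) / params.upwelling_tau_ref
    cool = (params.upwelling_cooling * upw[:, None, None]
            * np.exp(-zc[None, :, None] / params.cooling_zscale_m)
            * np.exp(-xc[None, None, :] / params.cooling_xscale_km))
    T = (T_base[None, :, None] - cool).astype(np.float32)
    T = np.repeat(T[:, :, None, :], ny, axis=2)

    S_xyz = np.full((nz, ny, nx), params.S_ocean, dtype=np.float64)
    if estuary_positions:
        yc = grid.y_centers
        zfac = np.exp(-zc / params.plume_zscale_m)
        xfac = np.exp(-xc / params.plume_xscale_km)
        for (y0, _x0) in estuary_positions:
            yfac = np.exp(-((yc - y0) / params.plume_yscale_km) ** 2)
            S_xyz -= (params.plume_anomaly * zfac[:, None, None]
                      * yfac[None, :, None] * xfac[None, None, :])
    S = np.broadcast_to(S_xyz[None].astype(np.float32), (nt, nz, ny, nx)).copy()

    return FieldArchive(grid, times, u, v, w, T, S)


# ---------------------------------------------------------------------------
# archive I/O
# ---------------------------------------------------------------------------

_REQUIRED_VARS = ("u", "v", "w", "T", "S", "bathymetry")


def write_archive(archive: FieldArchive, path) -> None:
    """Write the archive as a NetCDF file (scipy backend, NetCDF3)."""
    archive.to_dataset().to_netcdf(Path(path), engine="scipy")


def read_archive(path) -> FieldArchive:
    """Read an archive written by :func:`write_archive`; lossless round-trip."""
    with xr.open_dataset(Path(path), engine="scipy", decode_times=False) as ds:
        ds = ds.load()
    for name in _REQUIRED_VARS:
        if name not in ds:
            raise FormatError(f"archive file missing required variable '{name}'")
    for name in ("x_edge", "y_edge", "z_edge", "time"):
        if name not in ds.coords:
            raise FormatError(f"archive file missing required coordinate '{name}'")
    grid = ShelfGrid(ds["x_edge"].values, ds["y_edge"].values,
                     ds["z_edge"].values, ds["bathymetry"].values)
    return FieldArchive(grid, ds["time"].values,
                        ds["u"].values, ds["v"].values, ds["w"].values,
                        ds["T"].values, ds["S"].values)
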