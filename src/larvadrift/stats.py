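"""Validation and summary statistics for supply series and trajectories.

Supply time series are preprocessed before comparison — a centered 5-day
moving average (edges trimmed, no padding) followed by differencing at a lag
of one day — to reduce noise and remove the strong day-1 autocorrelation of
daily counts.  Cross-correlation between a predicted and an observed series
follows the convention of lagging the observed relative to the predicted
series: *negative* lags mean predicted maxima precede the observations.

Cross-shelf trajectory density accumulates, per cross-shore column of the
grid inside a stated alongshore band, the number of larvae that crossed that
column (entry transitions, matching recruitment's crossing semantics).
Predicted density profiles are compared with observed abundance profiles by
Pearson correlation of log(x+1)-transformed values with Bonferroni-corrected
p-values.

Dispersal accounting assigns each successful recruit a signed alongshore
distance d = y_source - y_destination (negative for southern origins,
positive for northern); the survival budget splits hatched larvae into
recruited, dead of physiological stress, and wastage (the complement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .biology import FATE_DIED_PHYSIOLOGY, FATE_RECRUITED
from .exceptions import ParameterError
from .release import Estuary

MA_WINDOW = 5  # days, centered


@dataclass(frozen=True)
class ProcessedSeries:
    """A supply series after MA-5 smoothing and lag-1 differencing."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, float))


def preprocess(series, provenance: str = "") -> ProcessedSeries:
    """Centered moving average of window 5 (edges trimmed), then first
    difference; output length = n - (window - 1) - 1."""
    v = np.asarray(getattr(series, "counts", series), float)
    if v.size <= MA_WINDOW + 1:
        raise ParameterError(
            f"series too short to preprocess (need > {MA_WINDOW + 1} points)")
    kernel = np.ones(MA_WINDOW) / MA_WINDOW
    smooth = np.convolve(v, kernel, mode="valid")
    return ProcessedSeries(np.diff(smooth),
                           provenance or "MA-5 then lag-1 difference")


@dataclass(frozen=True)
class CrossCorrelation:
    lags: np.ndarray
    r: np.ndarray
    best_lag: int
    best_r: float
    significance_bound: float  # approximate 95% bound, 1.96 / sqrt(N_eff)


def cross_correlation(observed, predicted, max_lag: int) -> CrossCorrelation:
    """Pearson r between predicted and observed at integer lags.

    Sign convention: ``r[k]`` correlates ``predicted[t]`` with
    ``observed[t - k]``, so the best lag is negative when predicted maxima
    precede the observations.  Zero-variance overlaps yield NaN at that lag.
    """
    obs = np.asarray(getattr(observed, "values", observed), float)
    pred = np.asarray(getattr(predicted, "values", predicted), float)
    if obs.size != pred.size:
        raise ParameterError("series must have equal length")
    n = obs.size
    if n < 3:
        raise ParameterError("series too short for cross-correlation")
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.full(lags.size, np.nan)
    for i, k in enumerate(lags):
        if k >= 0:
            a, b = pred[k:], obs[:n - k]
        else:
            a, b = pred[:n + k], obs[-k:]
        if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
            continue
        r[i] = np.corrcoef(a, b)[0, 1]
    if np.all(np.isnan(r)):
        raise ParameterError("no lag had a defined correlation")
    best = int(np.nanargmax(r))
    return CrossCorrelation(lags, r, int(lags[best]), float(r[best]),
                            1.96 / np.sqrt(n))


@dataclass(frozen=True)
class TrajectoryDensityGrid:
    """Accumulated larval crossing counts per cross-shore column."""

    x_edges: np.ndarray  # cross-shore column edges (km)
    counts: np.ndarray   # (nx,)
    band: tuple          # alongshore (y_min, y_max) km

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x_km": self.x_centers, "count": self.counts,
                             "y_min_km": self.band[0], "y_max_km": self.band[1]})


def trajectory_density(traj_x, traj_y, band: tuple,
                       x_edges) -> TrajectoryDensityGrid:
    """Count trajectory entries into each cross-shore column within a band.

    ``traj_x``/``traj_y`` are (n_times, n_particles) recorded positions (NaN
    when a particle is not in the water).  A particle contributes one count
    to a column each time it enters it while inside the alongshore band;
    its first in-band appearance counts as an entry to its current column.
    """
    x = np.asarray(traj_x, float)
    y = np.asarray(traj_y, float)
    x_edges = np.asarray(x_edges, float)
    nx = x_edges.size - 1
    y0, y1 = band
    valid = np.isfinite(x) & np.isfinite(y) & (y >= y0) & (y <= y1) \
        & (x >= x_edges[0]) & (x <= x_edges[-1])
    col = np.full(x.shape, -1, dtype=np.int64)
    ci = np.clip(np.searchsorted(x_edges, x[valid], side="right") - 1, 0, nx - 1)
    col[valid] = ci
    counts = np.zeros(nx)
    prev = np.full(x.shape[1], -1, dtype=np.int64)
    for k in range(x.shape[0]):
        c = col[k]
        entered = (c >= 0) & (c != prev)
        if np.any(entered):
            np.add.at(counts, c[entered], 1.0)
        prev = c
    return TrajectoryDensityGrid(x_edges, counts, (float(y0), float(y1)))


def compare_density_profiles(predicted_profile, observed_profile,
                             n_comparisons: int = 1):
    """Pearson r of log(x+1)-transformed cross-shore profiles, with the
    p-value Bonferroni-multiplied by the batch size (capped at 1)."""
    p_ = np.log1p(np.asarray(predicted_profile, float))
    o_ = np.log1p(np.asarray(observed_profile, float))
    if p_.size != o_.size:
        raise ParameterError("profiles must have equal length")
    r, p = sps.pearsonr(p_, o_)
    return float(r), float(min(1.0, n_comparisons * p))


@dataclass(frozen=True)
class DispersalSummary:
    """Signed realized-dispersal statistics for recruits at one destination."""

    destination: str
    n_recruits: int
    distances_km: np.ndarray       # signed, y_source - y_destination
    mean_south_km: float           # mean over d < 0 (NaN if none)
    mean_north_km: float           # mean over d > 0
    max_south_km: float            # signed extreme (most negative)
    max_north_km: float            # signed extreme (most positive)
    self_recruitment_fraction: float
    daily_contribution: pd.Series  # mean events per day, by source estuary


def dispersal_summary(events: pd.DataFrame, estuaries: list[Estuary],
                      destination: str, n_days: int | None = None,
                      replicate: int | None = None) -> DispersalSummary:
    """Realized-dispersal accounting for recruits at ``destination``.

    d = y_source - y_destination: negative for larvae supplied from the
    south, positive from the north, zero for self-recruitment.
    """
    ev = events
    if replicate is not None and len(ev):
        ev = ev[ev["replicate"] == replicate]
    sel = ev[ev["destination"] == destination] if len(ev) else ev
    d = (sel["y_source_km"] - sel["y_destination_km"]).to_numpy(float) \
        if len(sel) else np.empty(0)
    south, north = d[d < 0], d[d > 0]
    if n_days is None:
        n_days = max(1, int(np.ceil(sel["time_h"].max() / 24.0)) if len(sel) else 1)
    names = [e.name for e in estuaries]
    per_source = (sel.groupby("source").size() if len(sel) else pd.Series(dtype=float))
    daily = per_source.reindex(names, fill_value=0).astype(float) / n_days
    return DispersalSummary(
        destination=destination,
        n_recruits=len(sel),
        distances_km=d,
        mean_south_km=float(np.mean(south)) if south.size else float("nan"),
        mean_north_km=float(np.mean(north)) if north.size else float("nan"),
        max_south_km=float(np.min(south)) if south.size else float("nan"),
        max_north_km=float(np.max(north)) if north.size else float("nan"),
        self_recruitment_fraction=float(np.mean(d == 0)) if d.size else float("nan"),
        daily_contribution=daily,
    )


@dataclass(frozen=True)
class SurvivalSummary:
    """Fate budget as percentages of the total number hatched."""

    n_hatched: int
    pct_recruited: float
    pct_died_physiology: float
    pct_wastage: float  # 100 - recruited% - physiological mortality%


def survival_summary(fates) -> SurvivalSummary:
    """Percent recruited / dead of physiological stress / wastage.

    Wastage is the complement of recruitment plus physiological mortality:
    larvae lost offshore, dead of old age, or still in the water at the end.
    """
    f = np.asarray(fates)
    n = f.size
    if n == 0:
        raise ParameterError("no fates to summarize")
    rec = 100.0 * np.sum(f == FATE_RECRUITED) / n
    phys = 100.0 * np.sum(f == FATE_DIED_PHYSIOLOGY) / n
    return SurvivalSummary(n, float(rec), float(phys), float(100.0 - rec - phys))
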