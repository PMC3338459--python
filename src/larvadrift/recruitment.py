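"""Recruitment detection and larval supply accounting.

Supply to an estuary is the number of competent megalopae that *cross* the
12 x 12 km shelf box adjacent to its mouth.  A crossing is an entry
transition — the particle was outside every box at the previous step and
inside one now — so a slow particle lingering in a box is counted once per
passage, not once per time step.

Two experiment modes cover the stepwise validation design:

- **Base**: megalopae are never removed; every distinct entry of a competent
  megalopa is logged (a particle drifting in and out repeatedly generates
  repeated events).
- **Invasion**: a competent megalopa recruits on first entry — it enters the
  estuary, its fate becomes ``recruited``, and it is not counted afterwards.

Daily supply series are built per destination estuary, and mortality
replicates are combined by pointwise averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParameterError
from .release import Estuary

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ("replicate", "particle", "source", "destination",
                 "time_h", "age", "y_source_km", "y_destination_km")


def box_membership(x, y, estuaries: list[Estuary]):
    """Index of the estuary box containing each position, or -1.

    Boxes extend from the coast to ``box_cross_km`` offshore and span
    ``box_along_km`` alongshore around the estuary mouth; any depth within
    the box's water column counts.  Boxes must not overlap.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    out = np.full(x.shape, -1, dtype=np.int16)
    for j, est in enumerate(estuaries):
        inside = (x >= 0.0) & (x <= est.box_cross_km) \
            & (y >= est.y_min) & (y <= est.y_max)
        if np.any(inside & (out >= 0)):
            raise ConfigurationError("estuary boxes overlap")
        out[inside] = j
    return out


def check_recruitment(x_track, y_track, age_track, times_h,
                      estuaries: list[Estuary], mode: str,
                      source: str = "", particle: int = 0,
                      replicate: int = 0) -> pd.DataFrame:
    """Scan one particle trajectory for recruitment events.

    Entry transitions into a box while the particle is a competent megalopa
    (4 <= age < 5) are logged; in Invasion mode only the first such event
    counts (the particle recruits and is removed).  Used for single-particle
    audits and as the engine's reference semantics.
    """
    if mode not in ("base", "invasion"):
        raise ParameterError(f"unknown experiment mode {mode!r}")
    boxes = box_membership(x_track, y_track, estuaries)
    age = np.asarray(age_track, float)
    rows = []
    prev = boxes[0]
    y_src = next((e.y_center_km for e in estuaries if e.name == source), np.nan)
    for k in range(1, boxes.size):
        b = boxes[k]
        if b >= 0 and b != prev and 4.0 <= age[k] < 5.0:
            est = estuaries[b]
            rows.append((replicate, particle, source, est.name,
                         float(times_h[k]), float(age[k]), y_src, est.y_center_km))
            if mode == "invasion":
                break
        prev = b
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


@dataclass
class SupplySeries:
    """Daily counts of recruitment events at one destination estuary."""

    dates: pd.DatetimeIndex
    counts: np.ndarray
    estuary: str

    def __post_init__(self):
        self.counts = np.asarray(self.counts, float)
        if self.counts.size != self.dates.size:
            raise ParameterError("dates and counts must have equal length")
        if np.any(self.counts < 0):
            raise ParameterError("supply counts must be non-negative")

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=self.dates, name=self.estuary)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "estuary": self.estuary,
                             "count": self.counts})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SupplySeries":
        df = pd.read_csv(path, parse_dates=["date"])
        est = df["estuary"].iloc[0] if len(df) else ""
        return cls(pd.DatetimeIndex(df["date"]), df["count"].to_numpy(float), est)


def build_supply_series(events: pd.DataFrame, destination: str,
                        calendar: pd.DatetimeIndex,
                        origin: pd.Timestamp) -> SupplySeries:
    """Daily event counts at ``destination`` over ``calendar`` (zero-filled).

    ``origin`` anchors the event clock (``time_h`` hours after midnight of
    origin); events outside the calendar are excluded with a warning.
    """
    sel = events[events["destination"] == destination] if len(events) else events
    counts = np.zeros(calendar.size)
    if len(sel):
        days = (pd.Timestamp(origin).normalize()
                + pd.to_timedelta(np.floor(sel["time_h"].to_numpy() / 24.0), "D"))
        pos = calendar.get_indexer(days)
        n_out = int(np.sum(pos < 0))
        if n_out:
            logger.warning("%d supply events fall outside the calendar span "
                           "and were excluded", n_out)
        np.add.at(counts, pos[pos >= 0], 1.0)
    return SupplySeries(calendar, counts, destination)


def average_replicates(series_list: list[SupplySeries]) -> SupplySeries:
    """Pointwise mean of replicate supply series (equal calendars required)."""
    if not series_list:
        raise ParameterError("no series to average")
    first = series_list[0]
    for s in series_list[1:]:
        if not s.dates.equals(first.dates):
            raise ParameterError("replicate series have different calendars")
        if s.estuary != first.estuary:
            raise ParameterError("replicate series are for different estuaries")
    mean = np.mean([s.counts for s in series_list], axis=0)
    return SupplySeries(first.dates, mean, first.estuary)
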