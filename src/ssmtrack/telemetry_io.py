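"""Ingestion of telemetry tables and construction of the regular time grid.

Three plain-CSV input streams are supported: Argos location fixes,
haulout event records (start/end), and 6-h binned dive summaries.
Column names can be remapped via a ``dialect`` mapping so that vendor
exports (e.g. SMRU SRDL tables) can be read without editing the files.

All timestamps are handled in UTC.  Grid intervals are half-open
``[t0 + k*dt, t0 + (k+1)*dt)``: a boundary instant belongs to the later
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArgosObservation",
    "HauloutRecord",
    "DiveSummary",
    "RegularGrid",
    "FormatError",
    "InsufficientDataError",
    "LC_QUALITY",
    "read_argos_table",
    "read_haulout_records",
    "read_dive_summaries",
    "write_argos_table",
    "write_haulout_records",
    "write_dive_summaries",
    "build_regular_grid",
    "merge_intervals",
    "aggregate_haulout_proportion",
]

#: Argos location classes ordered from best to worst quality.
LC_QUALITY = ("3", "2", "1", "0", "A", "B")
_LC_RANK = {lc: i for i, lc in enumerate(LC_QUALITY)}


class FormatError(ValueError):
    """Raised when an input table violates the expected format."""


class InsufficientDataError(ValueError):
    """Raised when too few observations are available to build a grid."""


@dataclass(frozen=True)
class ArgosObservation:
    """One irregular, error-prone satellite fix with a quality class."""

    animal_id: str
    time: pd.Timestamp
    lon: float
    lat: float
    lc: str

    def __post_init__(self) -> None:
        if self.lc not in _LC_RANK:
            raise FormatError(f"unknown Argos location class {self.lc!r}")
        if not -90.0 <= self.lat <= 90.0:
            raise FormatError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise FormatError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class HauloutRecord:
    """A haulout event delivered by the tag (pre-detected on board)."""

    animal_id: str
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise FormatError(
                f"haulout record for {self.animal_id}: end {self.end} "
                f"not after start {self.start}"
            )


@dataclass(frozen=True)
class DiveSummary:
    """Proportion of time spent diving in one fixed summary bin."""

    animal_id: str
    bin_start: pd.Timestamp
    bin_hours: float
    prop_diving: float | None

    def __post_init__(self) -> None:
        p = self.prop_diving
        if p is not None and not (0.0 <= p <= 1.0):
            raise FormatError(f"prop_diving {p} outside [0, 1]")


@dataclass
class RegularGrid:
    """Regular 6-h state grid for one animal plus each fix's (k, j) slot.

    ``obs_index[i]`` is the interval index k of observation i and
    ``obs_frac[i]`` its fractional position j in [0, 1) within that
    interval, so that the fix time is ``t0 + (k + j) * dt``.
    """

    animal_id: str
    t0: pd.Timestamp
    dt_hours: float
    n_steps: int
    obs_index: np.ndarray = field(repr=False)
    obs_frac: np.ndarray = field(repr=False)

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.t0 + pd.to_timedelta(
            np.arange(self.n_steps) * self.dt_hours, unit="h"
        )


# ---------------------------------------------------------------------------
# readers / writers

_ARGOS_COLS = {"animal_id", "time", "lc", "lon", "lat"}
_HAULOUT_COLS = {"animal_id", "start", "end"}
_DIVE_COLS = {"animal_id", "bin_start", "prop_diving"}


def _load_csv(path, required: set[str], dialect: Mapping[str, str] | None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    missing = required - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    return df


def _parse_times(df: pd.DataFrame, col: str, path) -> pd.Series:
    parsed = pd.to_datetime(df[col], utc=True, errors="coerce", format="mixed")
    bad = parsed.isna() & df[col].notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise FormatError(
            f"{path}: unparseable timestamp {df[col][bad].iloc[0]!r} on line {line}"
        )
    if parsed.isna().any():
        line = int(np.flatnonzero(parsed.isna().to_numpy())[0]) + 2
        raise FormatError(f"{path}: empty timestamp on line {line}")
    return parsed


def read_argos_table(
    path, dialect: Mapping[str, str] | None = None
) -> list[ArgosObservation]:
    """Read Argos fixes from CSV, sort by (animal, time) and de-duplicate.

    Exact-time duplicates within an animal are collapsed keeping the
    better location class (3 > 2 > 1 > 0 > A > B); ties keep the first
    row encountered.
    """
    df = _load_csv(path, _ARGOS_COLS, dialect)
    if df.empty:
        return []
    df = df.copy()
    df["time"] = _parse_times(df, "time", path)
    df["lc"] = df["lc"].astype(str).str.strip().str.upper()
    df["_rank"] = df["lc"].map(_LC_RANK)
    if df["_rank"].isna().any():
        bad = df.loc[df["_rank"].isna(), "lc"].iloc[0]
        raise FormatError(f"{path}: unknown Argos location class {bad!r}")
    # stable sort keeps first row among equal-quality duplicates
    df = df.sort_values(["animal_id", "time", "_rank"], kind="stable")
    df = df.drop_duplicates(subset=["animal_id", "time"], keep="first")
    return [
        ArgosObservation(
            animal_id=str(r.animal_id),
            time=r.time,
            lon=float(r.lon),
            lat=float(r.lat),
            lc=r.lc,
        )
        for r in df.itertuples()
    ]


def read_haulout_records(
    path, dialect: Mapping[str, str] | None = None
) -> list[HauloutRecord]:
    """Read haulout events.  Records with ``end <= start`` are rejected."""
    df = _load_csv(path, _HAULOUT_COLS, dialect)
    if df.empty:
        return []
    df = df.copy()
    df["start"] = _parse_times(df, "start", path)
    df["end"] = _parse_times(df, "end", path)
    df = df.sort_values(["animal_id", "start"], kind="stable")
    return [
        HauloutRecord(animal_id=str(r.animal_id), start=r.start, end=r.end)
        for r in df.itertuples()
    ]


def read_dive_summaries(
    path, dialect: Mapping[str, str] | None = None, bin_hours: float = 6.0
) -> list[DiveSummary]:
    """Read 6-h dive summaries.  Empty proportion cells become missing."""
    df = _load_csv(path, _DIVE_COLS, dialect)
    if df.empty:
        return []
    df = df.copy()
    df["bin_start"] = _parse_times(df, "bin_start", path)
    out = []
    for r in df.itertuples():
        p = r.prop_diving
        prop = None if pd.isna(p) else float(p)
        out.append(
            DiveSummary(
                animal_id=str(r.animal_id),
                bin_start=r.bin_start,
                bin_hours=bin_hours,
                prop_diving=prop,
            )
        )
    return out


def write_argos_table(obs: Sequence[ArgosObservation], path) -> None:
    pd.DataFrame(
        {
            "animal_id": [o.animal_id for o in obs],
            "time": [o.time.isoformat() for o in obs],
            "lc": [o.lc for o in obs],
            "lon": [o.lon for o in obs],
            "lat": [o.lat for o in obs],
        }
    ).to_csv(path, index=False)


def write_haulout_records(records: Sequence[HauloutRecord], path) -> None:
    pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "start": [r.start.isoformat() for r in records],
            "end": [r.end.isoformat() for r in records],
        }
    ).to_csv(path, index=False)


def write_dive_summaries(summaries: Sequence[DiveSummary], path) -> None:
    pd.DataFrame(
        {
            "animal_id": [d.animal_id for d in summaries],
            "bin_start": [d.bin_start.isoformat() for d in summaries],
            "prop_diving": [
                "" if d.prop_diving is None else d.prop_diving for d in summaries
            ],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# regular grid

def floor_to_boundary(t: pd.Timestamp, dt_hours: float) -> pd.Timestamp:
    """Floor a timestamp to the nearest dt boundary of the UTC day."""
    day = t.normalize()
    hours = (t - day) / pd.Timedelta(hours=1)
    k = int(np.floor(hours / dt_hours))
    return day + pd.Timedelta(hours=k * dt_hours)


def build_regular_grid(
    observations: Sequence[ArgosObservation],
    dt_hours: float = 6.0,
    t0_rule: str | Callable[[pd.Timestamp], pd.Timestamp] = "floor_day_boundary",
) -> RegularGrid:
    """Build the regular state grid for one animal's observations.

    The default ``t0_rule`` floors the first fix time to the nearest
    dt-hour boundary of the UTC day (00/06/12/18 for dt=6) so that grid
    intervals align with SRDL summary bins.  ``t0_rule="first_obs"``
    starts the grid exactly at the first fix.

    Requires at least 4 observations (the two-step movement process
    needs >= 3 grid states to be informed).
    """
    if len(observations) < 4:
        raise InsufficientDataError(
            f"need >= 4 observations to build a grid, got {len(observations)}"
        )
    ids = {o.animal_id for o in observations}
    if len(ids) != 1:
        raise FormatError(f"grid must be built per animal, got ids {sorted(ids)}")
    times = pd.DatetimeIndex([o.time for o in observations])
    if not times.is_monotonic_increasing:
        raise FormatError("observations must be sorted by time")

    if callable(t0_rule):
        t0 = t0_rule(times[0])
    elif t0_rule == "floor_day_boundary":
        t0 = floor_to_boundary(times[0], dt_hours)
    elif t0_rule == "first_obs":
        t0 = times[0]
    else:
        raise ValueError(f"unknown t0_rule {t0_rule!r}")

    dt = pd.Timedelta(hours=dt_hours)
    rel = (times - t0) / dt
    k = np.floor(rel.to_numpy()).astype(int)
    j = rel.to_numpy() - k
    # states must exist at k+1 for every observation's interpolation
    n_steps = int(k.max()) + 2
    return RegularGrid(
        animal_id=observations[0].animal_id,
        t0=t0,
        dt_hours=dt_hours,
        n_steps=n_steps,
        obs_index=k,
        obs_frac=j,
    )


# ---------------------------------------------------------------------------
# haulout aggregation

def merge_intervals(
    records: Iterable[HauloutRecord],
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Union of (possibly overlapping) haulout intervals, sorted."""
    ivals = sorted((r.start, r.end) for r in records)
    merged: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    for start, end in ivals:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def aggregate_haulout_proportion(records: Sequence[HauloutRecord], grid: RegularGrid):
    """Proportion of each 6-h grid interval covered by haulout records.

    Overlapping records are merged first.  Intervals with no overlap get
    proportion 0 (the tag record may be incomplete; absence of a record
    is treated as not hauled out, not as missing).
    """
    from .activity_mapping import AncillarySeries

    merged = merge_intervals(r for r in records if r.animal_id == grid.animal_id)
    dt = pd.Timedelta(hours=grid.dt_hours)
    props = np.zeros(grid.n_steps)
    for start, end in merged:
        k_lo = max(0, int(np.floor((start - grid.t0) / dt)))
        k_hi = min(grid.n_steps - 1, int(np.floor((end - grid.t0) / dt)))
        for k in range(k_lo, k_hi + 1):
            lo = grid.t0 + k * dt
            hi = lo + dt
            overlap = (min(end, hi) - max(start, lo)) / dt
            if overlap > 0:
                props[k] += overlap
    np.clip(props, 0.0, 1.0, out=props)
    return AncillarySeries(
        animal_id=grid.animal_id, values=props, kind="haulout", missing=None
    )


def align_dive_summaries(summaries: Sequence[DiveSummary], grid: RegularGrid):
    """Place 6-h dive summaries onto the grid; uncovered bins are missing.

    Summary bins are matched to grid intervals by their start time
    (which must fall on a grid boundary to within 1 s).
    """
    from .activity_mapping import AncillarySeries

    dt = pd.Timedelta(hours=grid.dt_hours)
    values = np.zeros(grid.n_steps)
    missing = np.ones(grid.n_steps, dtype=bool)
    for d in summaries:
        if d.animal_id != grid.animal_id:
            continue
        rel = (d.bin_start - grid.t0) / dt
        k = int(round(rel))
        if abs(rel - k) * grid.dt_hours * 3600 > 1.0:
            raise FormatError(
                f"dive bin start {d.bin_start} not aligned with the grid"
            )
        if 0 <= k < grid.n_steps and d.prop_diving is not None:
            values[k] = d.prop_diving
            missing[k] = False
    return AncillarySeries(
        animal_id=grid.animal_id, values=values, kind="diving", missing=missing
    )
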