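"""Result layer: activity budgets, fitted-track statistics, diel analyses.

Budgets are computed per posterior draw (the proportion of steps in
each state within a draw) and then summarized by the median and 95%
highest-posterior-density interval across draws; where a state is
forced by ancillary data this yields degenerate intervals, as expected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .activity_mapping import AncillarySeries
from .mcmc_engine import PosteriorResult, hpdi

__all__ = [
    "TimeBudget",
    "MostProbableTrack",
    "time_budget",
    "most_probable_track",
    "step_lengths_km",
    "turn_angles_deg",
    "state_vs_observed_crosstab",
    "inactive_acf_periodogram",
    "solar_phase",
    "solar_elevation_deg",
    "diel_split",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = math.pi * EARTH_RADIUS_KM / 180.0


@dataclass
class TimeBudget:
    """Per-state proportion of 6-h steps: median and 95% HPDI."""

    median: np.ndarray  # (K,)
    hpdi_lo: np.ndarray
    hpdi_hi: np.ndarray
    draws: np.ndarray  # (n_draws, K)

    def to_frame(self) -> pd.DataFrame:
        K = self.median.size
        return pd.DataFrame(
            {
                "state": np.arange(1, K + 1),
                "median": self.median,
                "hpdi_lo": self.hpdi_lo,
                "hpdi_hi": self.hpdi_hi,
            }
        )


@dataclass
class MostProbableTrack:
    """Per-step posterior point estimates used for derived statistics."""

    lon: np.ndarray
    lat: np.ndarray
    modal_state: np.ndarray
    step_in_animal: np.ndarray
    animal_index: np.ndarray
    animal_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": [self.animal_ids[a] for a in self.animal_index],
                "step": self.step_in_animal,
                "lon": self.lon,
                "lat": self.lat,
                "modal_state": self.modal_state,
            }
        )


def time_budget(result: PosteriorResult, mass: float = 0.95) -> TimeBudget:
    """Median and HPDI of per-draw state proportions (pooled animals)."""
    K = result.K
    n = result.states.shape[1]
    draws = np.stack(
        [(result.states == k).sum(axis=1) / n for k in range(1, K + 1)], axis=1
    )
    lo = np.empty(K)
    hi = np.empty(K)
    for k in range(K):
        lo[k], hi[k] = hpdi(draws[:, k], mass)
    return TimeBudget(
        median=np.median(draws, axis=0), hpdi_lo=lo, hpdi_hi=hi, draws=draws
    )


def most_probable_track(result: PosteriorResult) -> MostProbableTrack:
    """Per-step coordinate medians and modal states across draws.

    Modal state is the most frequent state over retained draws; ties go
    to the lower state index.
    """
    pos = result.positions.astype(float)
    lon = np.median(pos[:, :, 0], axis=0)
    lat = np.median(pos[:, :, 1], axis=0)
    K = result.K
    counts = np.stack(
        [(result.states == k).sum(axis=0) for k in range(1, K + 1)], axis=1
    )
    modal = counts.argmax(axis=1) + 1  # argmax takes the first (lowest) max
    d = result.data
    n_anim = len(d.animal_ids)
    bounds = list(d.offsets) + [d.n_steps]
    animal_index = np.empty(d.n_steps, dtype=int)
    for a in range(n_anim):
        animal_index[bounds[a] : bounds[a + 1]] = a
    return MostProbableTrack(
        lon=lon,
        lat=lat,
        modal_state=modal.astype(int),
        step_in_animal=d.step_in_animal.copy(),
        animal_index=animal_index,
        animal_ids=list(d.animal_ids),
    )


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance (haversine, R = 6371 km), vectorized."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def step_lengths_km(track: MostProbableTrack) -> tuple[np.ndarray, pd.DataFrame]:
    """Great-circle displacement per step plus per-state mean and sd.

    Returns ``(dist, stats)`` where ``dist[t]`` is the displacement
    into step t (NaN at each animal's first step) and ``stats`` has one
    row per state with the mean and sd of the displacements grouped by
    the state of the destination step.
    """
    n = track.lon.size
    dist = np.full(n, np.nan)
    m = track.step_in_animal >= 1
    idx = np.flatnonzero(m)
    dist[idx] = haversine_km(
        track.lon[idx - 1], track.lat[idx - 1], track.lon[idx], track.lat[idx]
    )
    rows = []
    for k in np.unique(track.modal_state):
        sel = (track.modal_state == k) & ~np.isnan(dist)
        d = dist[sel]
        rows.append(
            {
                "state": int(k),
                "n": int(d.size),
                "mean_km": float(d.mean()) if d.size else np.nan,
                "sd_km": float(d.std(ddof=1)) if d.size > 1 else np.nan,
            }
        )
    return dist, pd.DataFrame(rows)


def turn_angles_deg(track: MostProbableTrack) -> tuple[np.ndarray, pd.DataFrame]:
    """Turn angle per step in [0, 360), counterclockwise positive.

    The angle at step t is between the displacement vectors into steps
    t-1..t and t..t+1... more precisely between consecutive
    displacements (x_{t-1}->x_t is compared with x_{t-2}->x_{t-1}),
    computed in a local planar approximation (km east/north).  0 means
    straight continuation.  NaN for each animal's first two steps.
    """
    n = track.lon.size
    ang = np.full(n, np.nan)
    idx = np.flatnonzero(track.step_in_animal >= 2)
    lat_mid = np.radians(track.lat[idx - 1])
    v1e = (track.lon[idx - 1] - track.lon[idx - 2]) * np.cos(lat_mid) * KM_PER_DEG
    v1n = (track.lat[idx - 1] - track.lat[idx - 2]) * KM_PER_DEG
    v2e = (track.lon[idx] - track.lon[idx - 1]) * np.cos(lat_mid) * KM_PER_DEG
    v2n = (track.lat[idx] - track.lat[idx - 1]) * KM_PER_DEG
    cross = v1e * v2n - v1n * v2e
    dot = v1e * v2e + v1n * v2n
    ang[idx] = np.degrees(np.arctan2(cross, dot)) % 360.0
    rows = []
    for k in np.unique(track.modal_state):
        sel = (track.modal_state == k) & ~np.isnan(ang)
        a = ang[sel]
        hist, edges = np.histogram(a, bins=36, range=(0, 360))
        rows.append({"state": int(k), "n": int(a.size), "histogram": hist})
    return ang, pd.DataFrame(rows)


def state_vs_observed_crosstab(
    results: Mapping[str, PosteriorResult] | PosteriorResult,
    observed: np.ndarray | AncillarySeries,
    bins: tuple = (0.0, 0.45, 0.55, 1.0),
) -> pd.DataFrame:
    """Percentage of all steps per (observed-proportion bin x modal state).

    ``observed`` is the per-step observed ancillary proportion aligned
    with the model grid.  Rows are model names plus an "Observed" row
    giving the percentage of steps per bin.  Cells are percentages of
    all steps, so each model row sums to ~100.
    """
    if isinstance(results, PosteriorResult):
        results = {"model": results}
    vals = observed.values if isinstance(observed, AncillarySeries) else np.asarray(observed, dtype=float)
    edges = np.asarray(bins, dtype=float)
    nbin = edges.size - 1
    which = np.clip(np.digitize(vals, edges[1:-1], right=False), 0, nbin - 1)
    n = vals.size
    out_rows = []
    obs_row: dict = {"model": "Observed"}
    for b in range(nbin):
        label = f"{edges[b]:g}-{edges[b+1]:g}"
        obs_row[f"bin {label}"] = 100.0 * (which == b).sum() / n
    out_rows.append(obs_row)
    for name, res in results.items():
        modal = most_probable_track(res).modal_state
        if modal.size != n:
            raise ValueError("observed series length does not match model steps")
        row: dict = {"model": name}
        for b in range(nbin):
            label = f"{edges[b]:g}-{edges[b+1]:g}"
            for k in range(1, res.K + 1):
                row[f"bin {label} s{k}"] = (
                    100.0 * ((which == b) & (modal == k)).sum() / n
                )
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def inactive_acf_periodogram(
    indicator: np.ndarray, max_lag: int = 12
) -> tuple[np.ndarray, float]:
    """Sample ACF of a binary inactive indicator plus its dominant
    periodogram frequency (cycles per step, excluding frequency zero).
    """
    z = np.asarray(indicator, dtype=float).ravel()
    n = z.size
    if n < 4:
        raise ValueError("series too short")
    zc = z - z.mean()
    denom = float((zc**2).sum())
    if denom == 0.0:
        raise ValueError("constant series: ACF undefined (zero variance)")
    max_lag = min(max_lag, n - 1)
    acf = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        acf[lag] = float((zc[: n - lag] * zc[lag:]).sum()) / denom
    from scipy.signal import periodogram

    freqs, power = periodogram(zc, fs=1.0, detrend=False)
    pos = freqs > 0
    peak = float(freqs[pos][np.argmax(power[pos])])
    return acf, peak


# ---------------------------------------------------------------------------
# solar position

def _solar_coords(when: pd.Timestamp) -> tuple[float, float, float]:
    """(declination rad, right ascension deg, GMST deg) at a UTC time.

    Low-precision solar ephemeris (accurate to ~0.01 deg), standard
    astronomical almanac formulas.
    """
    when = pd.Timestamp(when)
    if when.tzinfo is None:
        when = when.tz_localize("UTC")
    jd = when.to_julian_date()
    n = jd - 2451545.0
    L = math.radians((280.460 + 0.9856474 * n) % 360.0)
    g = math.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = L + math.radians(1.915) * math.sin(g) + math.radians(0.020) * math.sin(2 * g)
    eps = math.radians(23.439 - 4.0e-7 * n)
    decl = math.asin(math.sin(eps) * math.sin(lam))
    ra = math.degrees(math.atan2(math.cos(eps) * math.sin(lam), math.cos(lam)))
    gmst = (280.46061837 + 360.98564736629 * n) % 360.0
    return decl, ra, gmst


def solar_elevation_deg(lat: float, lon: float, when) -> float:
    """Solar elevation angle (degrees) above the horizon."""
    decl, ra, gmst = _solar_coords(when)
    H = math.radians((gmst + lon - ra) % 360.0)
    phi = math.radians(lat)
    sin_elev = math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.cos(H)
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_elev))))


def solar_phase(lat: float, lon: float, when, twilight_deg: float = -6.0) -> str:
    """Classify an instant as day / dawn / dusk / night.

    Elevation >= 0 is day; between the civil-twilight threshold and 0
    it is dawn if the sun is ascending, else dusk; below the threshold
    it is night.
    """
    e = solar_elevation_deg(lat, lon, when)
    if e >= 0.0:
        return "day"
    if e < twilight_deg:
        return "night"
    e2 = solar_elevation_deg(lat, lon, pd.Timestamp(when) + pd.Timedelta(minutes=5))
    return "dawn" if e2 > e else "dusk"


def diel_split(
    track: MostProbableTrack,
    grids,
    inactive_state: int = 3,
) -> dict:
    """Fraction of inactive-state steps in day/dawn vs dusk/night.

    Each inactive-modal step is classified by solar phase at its 6-h
    interval midpoint and fitted position.  ``grids`` is the list of
    per-animal RegularGrid objects (in animal order).
    """
    phases = []
    for t in np.flatnonzero(track.modal_state == inactive_state):
        a = track.animal_index[t]
        grid = grids[a]
        k = track.step_in_animal[t]
        mid = grid.t0 + pd.Timedelta(hours=(k + 0.5) * grid.dt_hours)
        phases.append(solar_phase(track.lat[t], track.lon[t], mid))
    phases_arr = np.asarray(phases)
    n = max(len(phases_arr), 1)
    day_dawn = float(np.isin(phases_arr, ["day", "dawn"]).sum()) / n
    return {
        "n_inactive_steps": len(phases_arr),
        "day_dawn": day_dawn,
        "dusk_night": 1.0 - day_dawn if len(phases_arr) else 0.0,
        "phases": phases_arr,
    }


def plot_track(track: MostProbableTrack, ax=None):
    """Quick colored map of the fitted track by modal state."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {1: "tab:blue", 2: "tab:red", 3: "tab:green"}
    for a in range(len(track.animal_ids)):
        m = track.animal_index == a
        ax.plot(track.lon[m], track.lat[m], color="0.7", lw=0.5, zorder=1)
    for k, c in colors.items():
        m = track.modal_state == k
        if m.any():
            ax.scatter(track.lon[m], track.lat[m], s=6, color=c, label=f"state {k}")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.legend()
    return ax
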