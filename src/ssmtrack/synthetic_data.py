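"""Forward simulation of tracks, Argos-like fixes and ancillary streams.

Generates data with the same statistical structure the fitting pipeline
consumes: a switching CRW track per animal, irregular heavy-tailed
Argos fixes, and a coupled ancillary series (haulout events for the
haulout formulation, 6-h dive-proportion summaries for the activity
formulation).

States are simulated from a full K x K Markov transition matrix; for
the ancillary-informed formulations the ancillary stream is then
derived from the simulated states (haulout proportion ~1 exactly on
activity-state steps; dive proportion 0 exactly on inactive steps), so
the fitted forcing reproduces the simulated state-3 allocation.

Two presets anchor recovery experiments: ``weddell_t2`` (haulout
formulation) and ``afs_t2`` (activity formulation), with movement
parameters set to the case studies' published posterior medians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .activity_mapping import (
    ActivityProbability,
    AncillarySeries,
    haulout_status,
    inactive_prob_from_diving,
)
from .movement_model import (
    ModelData,
    MovementParams,
    ObservationErrorTable,
    build_model_data,
    n_states,
)
from .telemetry_io import (
    LC_QUALITY,
    ArgosObservation,
    DiveSummary,
    HauloutRecord,
    RegularGrid,
    write_argos_table,
    write_dive_summaries,
    write_haulout_records,
)

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "preset",
    "PRESETS",
    "simulate_states_and_track",
    "simulate_argos_observations",
    "simulate_ancillary_series",
    "simulate_dataset",
]


@dataclass
class SimulationSpec:
    """Ground truth and sampling design for one synthetic dataset."""

    formulation: str
    params: MovementParams
    phi: np.ndarray  # full K x K simulation transition matrix
    n_animals: int = 1
    n_steps: int = 200
    obs_rate: float = 1.5  # expected fixes per 6-h interval
    class_mix: dict = field(
        default_factory=lambda: {
            "3": 0.05, "2": 0.08, "1": 0.12, "0": 0.15, "A": 0.25, "B": 0.35,
        }
    )
    seed: int = 0
    t0: str = "2011-01-01T00:00:00Z"
    dt_hours: float = 6.0
    lon0: float = 78.0
    lat0: float = -68.0
    animal_spacing_deg: float = 1.0
    # ancillary coupling
    dive_missing_rate: float = 0.1
    dive_max: float = 0.9
    dive_beta_resident: tuple = (5.0, 2.0)
    dive_beta_directed: tuple = (1.5, 2.5)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        K = n_states(self.formulation)
        if self.phi.shape != (K, K):
            raise ValueError(f"phi must be {K}x{K} for {self.formulation}")
        if np.any(self.phi < 0) or np.any(np.abs(self.phi.sum(axis=1) - 1) > 1e-9):
            raise ValueError("phi rows must be simplexes")
        if self.n_steps < 10:
            raise ValueError("n_steps must be >= 10")


def preset(name: str, **overrides) -> SimulationSpec:
    """Named truth presets for recovery experiments."""
    if name == "weddell_t2":
        h = 0.15
        spec = SimulationSpec(
            formulation="haulout",
            params=MovementParams(
                gamma=[0.72, 0.48, 0.24],
                theta=[0.01, 3.16, 3.04],
                sigma_lon=0.06,
                sigma_lat=0.04,
                rho=0.0,
                psi=1.0,
            ),
            phi=np.array(
                [
                    [(1 - h) * 0.66, (1 - h) * 0.34, h],
                    [(1 - h) * 0.19, (1 - h) * 0.81, h],
                    [(1 - h) * 0.19, (1 - h) * 0.81, h],
                ]
            ),
            n_animals=7,
            n_steps=450,
            obs_rate=1.5,
            lon0=78.0,
            lat0=-68.0,
        )
    elif name == "afs_t2":
        spec = SimulationSpec(
            formulation="activity",
            params=MovementParams(
                gamma=[0.85, 0.04, 0.04],
                theta=[-0.06 % (2 * np.pi), 2.84, 0.56],
                sigma_lon=0.08,
                sigma_lat=0.05,
                rho=0.0,
                psi=1.0,
            ),
            phi=np.array(
                [
                    [0.92, 0.04, 0.04],
                    [0.02, 0.55, 0.43],
                    [0.02, 0.48, 0.50],
                ]
            ),
            n_animals=5,
            n_steps=300,
            obs_rate=2.0,
            lon0=73.0,
            lat0=-53.0,
        )
    else:
        raise KeyError(f"unknown preset {name!r}")
    for k, v in overrides.items():
        setattr(spec, k, v)
    spec.__post_init__()
    return spec


PRESETS = ("weddell_t2", "afs_t2")


def _animal_rng(spec: SimulationSpec, animal: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, animal])


def simulate_states_and_track(
    spec: SimulationSpec, animal: int = 0, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one animal's state sequence and true track.

    States follow the spec's Markov matrix; positions follow the
    switching CRW around them.  Reproducible: the RNG stream is derived
    from (seed, animal index).
    """
    rng = rng or _animal_rng(spec, animal)
    K = spec.phi.shape[0]
    n = spec.n_steps
    p = spec.params
    s = np.empty(n, dtype=int)
    # initial state from the stationary-ish uniform draw
    s[0] = rng.integers(K) + 1
    for t in range(1, n):
        s[t] = rng.choice(K, p=spec.phi[s[t - 1] - 1]) + 1
    x = np.empty((n, 2))
    x[0] = (spec.lon0 + animal * spec.animal_spacing_deg, spec.lat0)
    chol = np.linalg.cholesky(p.Sigma)
    noise = (chol @ rng.standard_normal((2, n)).reshape(2, n)).T
    x[1] = x[0] + noise[1]
    for t in range(2, n):
        g = p.gamma[s[t] - 1]
        th = p.theta[s[t] - 1]
        d = x[t - 1] - x[t - 2]
        c, sn = np.cos(th), np.sin(th)
        mean = x[t - 1] + g * np.array(
            [c * d[0] - sn * d[1], sn * d[0] + c * d[1]]
        )
        x[t] = mean + noise[t]
    return s, x


def simulate_argos_observations(
    track: np.ndarray,
    grid: RegularGrid,
    table: ObservationErrorTable,
    rate: float,
    class_mix: dict,
    rng: np.random.Generator,
    psi: float = 1.0,
    noise_scale: float = 1.0,
) -> list[ArgosObservation]:
    """Irregular Argos-like fixes from a true track.

    Per 6-h interval the number of fixes is Poisson(rate), times are
    uniform in the interval, and positions are the interpolated truth
    plus Student-t noise with the sampled class's scales (classes A/B
    inflated by ``psi``).  ``noise_scale=0`` gives exact fixes.
    """
    if rate <= 0:
        warnings.warn("observation rate <= 0: returning no observations", stacklevel=2)
        return []
    classes = list(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    n = grid.n_steps
    obs: list[tuple[float, str, float, float]] = []
    for k in range(n - 1):
        n_k = rng.poisson(rate)
        if k == 0 and n_k == 0:
            n_k = 1  # anchor the grid at the first interval
        for u in np.sort(rng.uniform(size=n_k)):
            obs.append((k + u, None, None, None))  # fill below
    out = []
    dt = pd.Timedelta(hours=grid.dt_hours)
    for pos, _, _, _ in obs:
        k = int(pos)
        j = pos - k
        lc = classes[rng.choice(len(classes), p=probs)]
        ci = LC_QUALITY.index(lc)
        infl = psi if lc in ("A", "B") else 1.0
        true_lon = (1 - j) * track[k, 0] + j * track[k + 1, 0]
        true_lat = (1 - j) * track[k, 1] + j * track[k + 1, 1]
        elon = rng.standard_t(table.nu_lon[ci]) * table.tau_lon[ci] * infl
        elat = rng.standard_t(table.nu_lat[ci]) * table.tau_lat[ci] * infl
        lon = float(np.clip(true_lon + noise_scale * elon, -180.0, 180.0))
        lat = float(np.clip(true_lat + noise_scale * elat, -90.0, 90.0))
        out.append(
            ArgosObservation(
                animal_id=grid.animal_id,
                time=grid.t0 + pos * dt,
                lon=lon,
                lat=lat,
                lc=lc,
            )
        )
    return out


def simulate_ancillary_series(
    states: np.ndarray,
    spec: SimulationSpec,
    rng: np.random.Generator,
    animal_id: str = "sim",
) -> AncillarySeries:
    """Ancillary stream coupled to the simulated states.

    Haulout kind: proportion 1 exactly where s = 3, else 0.  Diving
    kind: dive proportion 0 exactly where s = 3 (inactive), drawn from
    per-state beta distributions elsewhere, with uniform missingness at
    ``dive_missing_rate``.
    """
    n = states.size
    if spec.formulation == "haulout":
        vals = (states == 3).astype(float)
        return AncillarySeries(animal_id=animal_id, values=vals, kind="haulout")
    vals = np.zeros(n)
    m1 = states == 1
    m2 = states == 2
    a, b = spec.dive_beta_directed
    vals[m1] = rng.beta(a, b, size=int(m1.sum())) * spec.dive_max
    a, b = spec.dive_beta_resident
    vals[m2] = rng.beta(a, b, size=int(m2.sum())) * spec.dive_max
    missing = rng.uniform(size=n) < spec.dive_missing_rate
    return AncillarySeries(
        animal_id=animal_id, values=vals, kind="diving", missing=missing
    )


@dataclass
class SimulatedDataset:
    """All simulated pieces plus helpers to fit or export them."""

    spec: SimulationSpec
    grids: list[RegularGrid]
    observations: list[list[ArgosObservation]]
    ancillary: list[AncillarySeries | None]
    activity: list[ActivityProbability | None]
    states: list[np.ndarray]
    tracks: list[np.ndarray]
    error_table: ObservationErrorTable

    def model_data(self) -> ModelData:
        animals = [
            (g, o, a)
            for g, o, a in zip(self.grids, self.observations, self.activity)
        ]
        return build_model_data(
            self.spec.formulation, animals, error_table=self.error_table
        )

    def haulout_records(self) -> list[HauloutRecord]:
        """Haulout events reconstructed from the state-3 runs."""
        recs = []
        for grid, s in zip(self.grids, self.states):
            dt = pd.Timedelta(hours=grid.dt_hours)
            in_run = False
            start_k = 0
            for k in range(s.size + 1):
                on = k < s.size and s[k] == 3
                if on and not in_run:
                    in_run, start_k = True, k
                elif not on and in_run:
                    in_run = False
                    recs.append(
                        HauloutRecord(
                            animal_id=grid.animal_id,
                            start=grid.t0 + start_k * dt,
                            end=grid.t0 + k * dt,
                        )
                    )
        return recs

    def dive_summaries(self) -> list[DiveSummary]:
        out = []
        for grid, series in zip(self.grids, self.ancillary):
            if series is None or series.kind != "diving":
                continue
            miss = series.missing_mask
            for k in range(series.values.size):
                out.append(
                    DiveSummary(
                        animal_id=grid.animal_id,
                        bin_start=grid.t0 + pd.Timedelta(hours=k * grid.dt_hours),
                        bin_hours=grid.dt_hours,
                        prop_diving=None if miss[k] else float(series.values[k]),
                    )
                )
        return out

    def write_csvs(self, directory) -> dict:
        """Write the three input CSVs plus truth.csv; returns the paths."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {"observations": d / "observations.csv"}
        write_argos_table(
            [o for obs in self.observations for o in obs], paths["observations"]
        )
        if self.spec.formulation == "haulout":
            paths["haulout"] = d / "haulout.csv"
            write_haulout_records(self.haulout_records(), paths["haulout"])
        elif self.spec.formulation == "activity":
            paths["dives"] = d / "dives.csv"
            write_dive_summaries(self.dive_summaries(), paths["dives"])
        truth_rows = []
        for grid, s, x in zip(self.grids, self.states, self.tracks):
            for k in range(s.size):
                truth_rows.append(
                    {
                        "animal_id": grid.animal_id,
                        "step": k,
                        "time": (
                            grid.t0 + pd.Timedelta(hours=k * grid.dt_hours)
                        ).isoformat(),
                        "state": int(s[k]),
                        "lon": x[k, 0],
                        "lat": x[k, 1],
                    }
                )
        p = self.spec.params
        truth = pd.DataFrame(truth_rows)
        for i in range(p.n_states):
            truth[f"gamma_{i+1}"] = p.gamma[i]
            truth[f"theta_{i+1}"] = p.theta[i]
        paths["truth"] = d / "truth.csv"
        truth.to_csv(paths["truth"], index=False)
        return paths


def simulate_dataset(
    spec: SimulationSpec, error_table: ObservationErrorTable | None = None
) -> SimulatedDataset:
    """Simulate the full multi-animal dataset for a spec."""
    table = error_table or ObservationErrorTable.default()
    t0 = pd.Timestamp(spec.t0)
    if t0.tzinfo is None:
        t0 = t0.tz_localize("UTC")
    grids, obs_all, anc_all, act_all, s_all, x_all = [], [], [], [], [], []
    for a in range(spec.n_animals):
        rng = _animal_rng(spec, a)
        aid = f"sim{a:02d}"
        s, x = simulate_states_and_track(spec, animal=a, rng=rng)
        grid = RegularGrid(
            animal_id=aid,
            t0=t0,
            dt_hours=spec.dt_hours,
            n_steps=spec.n_steps,
            obs_index=np.empty(0, dtype=int),
            obs_frac=np.empty(0),
        )
        obs = simulate_argos_observations(
            x, grid, table, spec.obs_rate, spec.class_mix, rng, psi=spec.params.psi
        )
        dt = pd.Timedelta(hours=spec.dt_hours)
        pos = np.array([(o.time - t0) / dt for o in obs])
        grid.obs_index = np.floor(pos).astype(int)
        grid.obs_frac = pos - grid.obs_index
        if spec.formulation in ("haulout", "activity"):
            series = simulate_ancillary_series(s, spec, rng, animal_id=aid)
            if spec.formulation == "haulout":
                act = haulout_status(series)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    act = inactive_prob_from_diving(series)
        else:
            series, act = None, None
        grids.append(grid)
        obs_all.append(obs)
        anc_all.append(series)
        act_all.append(act)
        s_all.append(s)
        x_all.append(x)
    return SimulatedDataset(
        spec=spec,
        grids=grids,
        observations=obs_all,
        ancillary=anc_all,
        activity=act_all,
        states=s_all,
        tracks=x_all,
        error_table=table,
    )
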