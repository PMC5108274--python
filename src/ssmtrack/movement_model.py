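"""Switching correlated-random-walk process and Argos observation model.

The movement process is a first-order correlated random walk in raw
lon/lat degrees.  Conditional on the behavioral state ``s_t`` of step t,

    x_t ~ N2( x_{t-1} + gamma_s * T(theta_s) (x_{t-1} - x_{t-2}), Sigma )

where ``T`` is a rotation matrix, ``gamma_s`` the per-state movement
persistence and ``theta_s`` the per-state mean turning angle.  States
follow a Markov chain whose transition structure depends on the chosen
formulation:

``two_state``
    Directed (1) / resident (2), full 2x2 transition matrix.
``three_state``
    Adds an activity state (3), full 3x3 matrix, movement-only.
``haulout``
    The activity state is forced by the ancillary status: steps with
    ``a_status = 1`` are in state 3 with probability one, all other
    steps distribute over states 1-2; switches into state 3 are
    structural zeros of the transition matrix.
``activity``
    Switches into the directed state come from the movement data
    (column 1 of the matrix); the remaining probability mass is split
    between resident and activity states by the per-step ``pr_A``.

Irregular Argos fixes relate to the grid through linear interpolation
between the bracketing states, with heavy-tailed (Student-t) errors per
location class; the scales of the worst classes (A and B) are inflated
by a factor ``psi``.

Positions are modeled in raw longitude/latitude degrees, as adequate at
the spatial scales of typical pinniped tracks; this degrades near the
poles and the antimeridian (longitudes can be recentered upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .activity_mapping import (
    STATUS_ACTIVITY,
    STATUS_OTHER,
    STATUS_UNFORCED,
    ActivityProbability,
)
from .telemetry_io import LC_QUALITY, ArgosObservation, RegularGrid

__all__ = [
    "FORMULATIONS",
    "n_states",
    "MovementParams",
    "ObservationErrorTable",
    "PriorConfig",
    "ModelData",
    "build_model_data",
    "rotation_step_mean",
    "transition_distribution",
    "observation_prediction",
    "observation_loglik",
    "prior_logdensity",
    "log_posterior",
]

FORMULATIONS = ("two_state", "three_state", "haulout", "activity")

#: Argos classes whose error scale is inflated by psi.
PSI_CLASSES = ("A", "B")

TWO_PI = 2.0 * np.pi


def n_states(formulation: str) -> int:
    if formulation not in FORMULATIONS:
        raise ValueError(f"unknown formulation {formulation!r}")
    return 2 if formulation == "two_state" else 3


@dataclass
class MovementParams:
    """Continuous movement parameters shared across animals.

    gamma and theta have one entry per behavioral state.  The process
    noise covariance is parameterized by its lon/lat standard
    deviations and correlation.  ``psi >= 0`` inflates the observation
    error scale of classes A and B.
    """

    gamma: np.ndarray
    theta: np.ndarray
    sigma_lon: float
    sigma_lat: float
    rho: float = 0.0
    psi: float = 1.0

    def __post_init__(self) -> None:
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if self.gamma.shape != self.theta.shape:
            raise ValueError("gamma and theta must have the same length")

    @property
    def n_states(self) -> int:
        return self.gamma.size

    @property
    def Sigma(self) -> np.ndarray:
        c = self.rho * self.sigma_lon * self.sigma_lat
        return np.array(
            [[self.sigma_lon**2, c], [c, self.sigma_lat**2]]
        )

    def in_support(self) -> bool:
        return bool(
            np.all((self.gamma >= 0) & (self.gamma < 1))
            and self.sigma_lon > 0
            and self.sigma_lat > 0
            and abs(self.rho) < 1
            and self.psi >= 0
        )

    def copy(self) -> "MovementParams":
        return replace(
            self, gamma=self.gamma.copy(), theta=self.theta.copy()
        )


@dataclass
class ObservationErrorTable:
    """Per-Argos-class Student-t error scales (degrees) and dfs."""

    tau_lon: np.ndarray  # indexed by LC_QUALITY order
    tau_lat: np.ndarray
    nu_lon: np.ndarray
    nu_lat: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tau_lon", "tau_lat", "nu_lon", "nu_lat"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(LC_QUALITY),) or np.any(arr <= 0):
                raise ValueError(f"{name} must be {len(LC_QUALITY)} positive values")
            setattr(self, name, arr)

    @classmethod
    def from_csv(cls, path) -> "ObservationErrorTable":
        df = pd.read_csv(path)
        df["class"] = df["class"].astype(str).str.strip().str.upper()
        df = df.set_index("class").reindex(list(LC_QUALITY))
        if df.isna().any().any():
            raise ValueError(f"{path}: error table must cover classes {LC_QUALITY}")
        return cls(
            tau_lon=df["tau_lon"].to_numpy(),
            tau_lat=df["tau_lat"].to_numpy(),
            nu_lon=df["nu_lon"].to_numpy(),
            nu_lat=df["nu_lat"].to_numpy(),
        )

    @classmethod
    def default(cls) -> "ObservationErrorTable":
        with resources.as_file(
            resources.files("ssmtrack.data") / "argos_errors.csv"
        ) as p:
            return cls.from_csv(p)

    def class_index(self, lc: str) -> int:
        try:
            return LC_QUALITY.index(lc)
        except ValueError:
            raise KeyError(f"Argos class {lc!r} not in error table") from None


@dataclass
class PriorConfig:
    """Prior hyper-parameters.

    Defaults are weak: gamma ~ U(0,1), theta ~ U(0, 2pi), transition
    rows ~ Dirichlet(1,...,1), sigma components ~ half-normal,
    rho ~ U(-1,1), psi ~ U(0, psi_max).  ``theta2_informative`` turns on
    a wrapped-normal(pi, theta2_sd) prior for the resident-state turn
    angle, used to prevent state flipping in highly localized tracks.
    ``order_gamma`` enforces gamma_1 > gamma_2 (directed = most
    persistent) as a label-switching guard.
    """

    sigma_scale: float = 0.1
    psi_max: float = 10.0
    theta2_informative: bool = False
    theta2_mean: float = np.pi
    theta2_sd: float = 0.5
    order_gamma: bool = True
    init_sd: float = 1.0  # diffuse prior sd (deg) for the first two positions


# ---------------------------------------------------------------------------
# elementary model operations

def rotation_step_mean(x_prev, x_prev2, gamma_i: float, theta_i: float):
    """CRW process mean: previous position plus a damped, rotated copy
    of the previous displacement."""
    x_prev = np.asarray(x_prev, dtype=float)
    d = x_prev - np.asarray(x_prev2, dtype=float)
    c, s = np.cos(theta_i), np.sin(theta_i)
    rotated = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
    return x_prev + gamma_i * rotated


def transition_distribution(
    s_prev: int,
    phi: np.ndarray,
    formulation: str,
    pr_A: float | None = None,
    a_status: int | None = None,
) -> np.ndarray:
    """State distribution at step t given the state at t-1.

    States are 1-based (1 directed, 2 resident, 3 activity).
    """
    phi = np.asarray(phi, dtype=float)
    K = n_states(formulation)
    if not 1 <= s_prev <= phi.shape[0]:
        raise ValueError(f"invalid state index {s_prev}")
    row = phi[s_prev - 1]
    if formulation in ("two_state", "three_state"):
        return row.copy()
    if formulation == "haulout":
        if a_status == STATUS_ACTIVITY:
            return np.array([0.0, 0.0, 1.0])
        p12 = row[:2] / row[:2].sum()
        return np.array([p12[0], p12[1], 0.0])
    # activity
    if pr_A is None:
        raise ValueError("activity formulation requires pr_A")
    p1 = row[0]
    rest = 1.0 - p1
    return np.array([p1, rest * (1.0 - pr_A), rest * pr_A])


def observation_prediction(x_k, x_k1, j: float):
    """Interpolated true position at an observation's fractional slot."""
    return (1.0 - j) * np.asarray(x_k, dtype=float) + j * np.asarray(
        x_k1, dtype=float
    )


def _t_logpdf(x, df, scale):
    """Student-t log density, vectorized (location 0)."""
    z = np.asarray(x) / scale
    return (
        gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
        - (df + 1.0) / 2.0 * np.log1p(z * z / df)
    )


def observation_loglik(
    y: ArgosObservation,
    pred,
    table: ObservationErrorTable,
    psi: float = 1.0,
) -> float:
    """Log density of one Argos fix around its predicted position."""
    c = table.class_index(y.lc)
    infl = psi if y.lc in PSI_CLASSES else 1.0
    pred = np.asarray(pred, dtype=float)
    ll = _t_logpdf(y.lon - pred[0], table.nu_lon[c], table.tau_lon[c] * infl)
    ll += _t_logpdf(y.lat - pred[1], table.nu_lat[c], table.tau_lat[c] * infl)
    return float(ll)


def _wrapped_normal_logpdf(x, mean, sd, n_wrap: int = 3):
    """Wrapped-normal log density on [0, 2pi)."""
    x = np.asarray(x, dtype=float)
    ks = np.arange(-n_wrap, n_wrap + 1)
    diffs = x[..., None] - mean + ks * TWO_PI
    dens = np.exp(-0.5 * (diffs / sd) ** 2).sum(axis=-1) / (
        sd * np.sqrt(TWO_PI)
    )
    return np.log(dens)


def prior_logdensity(
    params: MovementParams,
    phi: np.ndarray,
    formulation: str,
    config: PriorConfig | None = None,
) -> float:
    """Joint log prior.  Returns -inf outside the support."""
    config = config or PriorConfig()
    K = n_states(formulation)
    if not params.in_support() or params.psi > config.psi_max:
        return -np.inf
    if config.order_gamma and K >= 2 and not params.gamma[0] > params.gamma[1]:
        return -np.inf
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < -1e-12) or np.any(np.abs(phi.sum(axis=1) - 1.0) > 1e-9):
        return -np.inf
    if formulation == "haulout" and np.any(np.abs(phi[:, 2]) > 1e-12):
        return -np.inf

    lp = 0.0
    # gamma ~ U(0,1): density 1
    # theta ~ U(0, 2pi)
    lp += -params.theta.size * np.log(TWO_PI)
    if config.theta2_informative and K >= 2:
        th2 = np.mod(params.theta[1], TWO_PI)
        lp += float(
            _wrapped_normal_logpdf(th2, config.theta2_mean, config.theta2_sd)
        ) + np.log(TWO_PI)  # replaces the uniform factor for theta_2
    # sigma ~ half-normal(scale)
    for s in (params.sigma_lon, params.sigma_lat):
        lp += (
            np.log(2.0)
            - 0.5 * np.log(TWO_PI)
            - np.log(config.sigma_scale)
            - 0.5 * (s / config.sigma_scale) ** 2
        )
    lp += -np.log(2.0)  # rho ~ U(-1, 1)
    lp += -np.log(config.psi_max)  # psi ~ U(0, psi_max)
    # Dirichlet(1,..,1) rows: density Gamma(m) on the (m-1)-simplex
    if formulation in ("two_state", "three_state"):
        m = K
        lp += phi.shape[0] * float(gammaln(m))
    elif formulation == "haulout":
        lp += 0.0  # three Dirichlet(1,1) rows over states 1-2
    else:  # activity: Beta(1,1) on each row's column 1
        lp += 0.0
    return float(lp)


# ---------------------------------------------------------------------------
# vectorized model bundle

@dataclass
class ModelData:
    """Concatenated multi-animal data in sampler-ready arrays.

    All per-step arrays have length ``n_steps`` (the total over
    animals); ``step_in_animal`` restarts at 0 for each animal so that
    process terms (``step_in_animal >= 2``) and transitions
    (``>= 1``) never straddle animals.
    """

    formulation: str
    animal_ids: list[str]
    offsets: np.ndarray  # start index of each animal's block
    step_in_animal: np.ndarray
    anchor: np.ndarray  # (n_steps, 2) first-fix position per animal
    pr_A: np.ndarray
    a_status: np.ndarray
    obs_site: np.ndarray  # global index k; interpolation uses k and k+1
    obs_frac: np.ndarray
    obs_lon: np.ndarray
    obs_lat: np.ndarray
    obs_tau_lon: np.ndarray
    obs_tau_lat: np.ndarray
    obs_nu_lon: np.ndarray
    obs_nu_lat: np.ndarray
    obs_is_psi: np.ndarray  # bool: class A/B, scale inflated by psi
    error_table: ObservationErrorTable
    grids: list[RegularGrid] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return self.step_in_animal.size

    @property
    def n_obs(self) -> int:
        return self.obs_site.size

    @property
    def K(self) -> int:
        return n_states(self.formulation)

    @property
    def forced_state3(self) -> np.ndarray:
        """Steps whose state is forced to 3 (haulout formulation only)."""
        if self.formulation != "haulout":
            return np.zeros(self.n_steps, dtype=bool)
        return self.a_status == STATUS_ACTIVITY

    @property
    def proc_valid(self) -> np.ndarray:
        return self.step_in_animal >= 2

    @property
    def trans_valid(self) -> np.ndarray:
        return self.step_in_animal >= 1


def build_model_data(
    formulation: str,
    animals: Sequence[tuple[RegularGrid, Sequence[ArgosObservation], ActivityProbability | None]],
    error_table: ObservationErrorTable | None = None,
) -> ModelData:
    """Assemble the sampler-ready bundle from per-animal pieces.

    Each element of ``animals`` is ``(grid, observations, activity)``;
    ``activity`` may be None for the two- and three-state formulations.
    """
    K = n_states(formulation)
    table = error_table or ObservationErrorTable.default()
    ids, offs, sia, anchors, prs, stats = [], [], [], [], [], []
    ok, ofrac, olon, olat, ocls = [], [], [], [], []
    grids = []
    offset = 0
    for grid, obs, act in animals:
        n = grid.n_steps
        if len(obs) != grid.obs_index.size:
            raise ValueError(
                f"{grid.animal_id}: observation count does not match grid"
            )
        if formulation in ("haulout", "activity"):
            if act is None:
                raise ValueError(
                    f"{formulation} formulation requires an activity series "
                    f"for animal {grid.animal_id}"
                )
            if act.pr_A.size != n:
                raise ValueError(
                    f"{grid.animal_id}: activity series length {act.pr_A.size} "
                    f"!= grid n_steps {n}"
                )
            prs.append(act.pr_A)
            stats.append(act.a_status)
        else:
            prs.append(np.zeros(n))
            stats.append(np.full(n, STATUS_UNFORCED, dtype=np.int8))
        ids.append(grid.animal_id)
        offs.append(offset)
        sia.append(np.arange(n))
        anchors.append(np.tile([obs[0].lon, obs[0].lat], (n, 1)))
        ok.append(grid.obs_index + offset)
        ofrac.append(grid.obs_frac)
        olon.append([o.lon for o in obs])
        olat.append([o.lat for o in obs])
        ocls.append([table.class_index(o.lc) for o in obs])
        grids.append(grid)
        offset += n

    cls_idx = np.concatenate([np.asarray(c, dtype=int) for c in ocls])
    psi_cls = np.array([LC_QUALITY.index(c) for c in PSI_CLASSES])
    return ModelData(
        formulation=formulation,
        animal_ids=ids,
        offsets=np.asarray(offs, dtype=int),
        step_in_animal=np.concatenate(sia),
        anchor=np.concatenate(anchors),
        pr_A=np.concatenate(prs),
        a_status=np.concatenate(stats).astype(np.int8),
        obs_site=np.concatenate(ok).astype(int),
        obs_frac=np.concatenate(ofrac),
        obs_lon=np.concatenate([np.asarray(v, dtype=float) for v in olon]),
        obs_lat=np.concatenate([np.asarray(v, dtype=float) for v in olat]),
        obs_tau_lon=table.tau_lon[cls_idx],
        obs_tau_lat=table.tau_lat[cls_idx],
        obs_nu_lon=table.nu_lon[cls_idx],
        obs_nu_lat=table.nu_lat[cls_idx],
        obs_is_psi=np.isin(cls_idx, psi_cls),
        error_table=table,
        grids=grids,
    )


# ---------------------------------------------------------------------------
# vectorized likelihood terms (used by the sampler and by oracles)

def process_terms(
    x: np.ndarray, s: np.ndarray, params: MovementParams, data: ModelData
) -> np.ndarray:
    """Per-step CRW log densities; zero where no process term applies."""
    n = data.n_steps
    out = np.zeros(n)
    v = data.proc_valid
    g = params.gamma[s - 1]
    th = params.theta[s - 1]
    c, sn = np.cos(th), np.sin(th)
    # displacement entering step t is x[t-1] - x[t-2]
    disp = np.zeros_like(x)
    disp[2:] = x[1:-1] - x[:-2]
    mean = np.empty_like(x)
    mean[:] = 0.0
    mean[1:, 0] = x[:-1, 0]
    mean[1:, 1] = x[:-1, 1]
    mean[:, 0] += g * (c * disp[:, 0] - sn * disp[:, 1])
    mean[:, 1] += g * (sn * disp[:, 0] + c * disp[:, 1])
    r = x - mean
    s1, s2, rho = params.sigma_lon, params.sigma_lat, params.rho
    det = (s1 * s2) ** 2 * (1 - rho**2)
    inv11 = 1.0 / (s1**2 * (1 - rho**2))
    inv22 = 1.0 / (s2**2 * (1 - rho**2))
    inv12 = -rho / (s1 * s2 * (1 - rho**2))
    q = inv11 * r[:, 0] ** 2 + 2 * inv12 * r[:, 0] * r[:, 1] + inv22 * r[:, 1] ** 2
    ll = -np.log(TWO_PI) - 0.5 * np.log(det) - 0.5 * q
    out[v] = ll[v]
    return out


def init_position_terms(
    x: np.ndarray, data: ModelData, config: PriorConfig
) -> np.ndarray:
    """Diffuse-normal log densities for each animal's first two states."""
    out = np.zeros(data.n_steps)
    m = data.step_in_animal < 2
    sd = config.init_sd
    r = (x[m] - data.anchor[m]) / sd
    out[m] = (-0.5 * np.log(TWO_PI) - np.log(sd) - 0.5 * r**2).sum(axis=1)
    return out


def observation_terms(x: np.ndarray, psi: float, data: ModelData) -> np.ndarray:
    """Per-observation Student-t log densities given latent positions."""
    k, j = data.obs_site, data.obs_frac
    pred_lon = (1 - j) * x[k, 0] + j * x[k + 1, 0]
    pred_lat = (1 - j) * x[k, 1] + j * x[k + 1, 1]
    infl = np.where(data.obs_is_psi, psi, 1.0)
    ll = _t_logpdf(data.obs_lon - pred_lon, data.obs_nu_lon, data.obs_tau_lon * infl)
    ll += _t_logpdf(data.obs_lat - pred_lat, data.obs_nu_lat, data.obs_tau_lat * infl)
    return ll


def build_transition_tensor(phi: np.ndarray, data: ModelData) -> np.ndarray:
    """Q[t, i, j] = Pr(s_t = j+1 | s_{t-1} = i+1) for every step t."""
    n, K = data.n_steps, data.K
    phi = np.asarray(phi, dtype=float)
    if data.formulation in ("two_state", "three_state"):
        return np.broadcast_to(phi, (n, K, K)).copy()
    Q = np.zeros((n, K, K))
    if data.formulation == "haulout":
        row12 = phi[:, :2] / phi[:, :2].sum(axis=1, keepdims=True)
        forced = data.a_status == STATUS_ACTIVITY
        Q[~forced, :, 0] = row12[None, :, 0]
        Q[~forced, :, 1] = row12[None, :, 1]
        Q[forced, :, 2] = 1.0
    else:  # activity
        p1 = phi[:, 0]
        rest = 1.0 - p1
        pr = data.pr_A
        Q[:, :, 0] = p1[None, :]
        Q[:, :, 1] = rest[None, :] * (1.0 - pr[:, None])
        Q[:, :, 2] = rest[None, :] * pr[:, None]
    return Q


def initial_state_distribution(data: ModelData, t_idx: np.ndarray) -> np.ndarray:
    """Forcing-aware initial state distribution for given steps.

    Deliberately free of the transition matrix so that the matrix's
    full conditional stays conjugate: uniform over the states available
    at the step (haulout forcing restricts availability; the other
    formulations are uniform over all states).
    """
    K = data.K
    m = t_idx.size
    pi0 = np.full((m, K), 1.0 / K)
    if data.formulation == "haulout":
        forced = data.a_status[t_idx] == STATUS_ACTIVITY
        pi0[forced] = [0.0, 0.0, 1.0]
        pi0[~forced] = [0.5, 0.5, 0.0]
    return pi0


def transition_terms(s: np.ndarray, Q: np.ndarray, data: ModelData) -> np.ndarray:
    """Per-step log transition probabilities (and initial-state terms)."""
    n = data.n_steps
    out = np.zeros(n)
    tv = data.trans_valid
    idx = np.arange(n)
    prev = np.empty(n, dtype=int)
    prev[1:] = s[:-1]
    prev[0] = 1
    p = Q[idx[tv], prev[tv] - 1, s[tv] - 1]
    with np.errstate(divide="ignore"):
        out[tv] = np.log(p)
    first = ~tv
    pi0 = initial_state_distribution(data, idx[first])
    with np.errstate(divide="ignore"):
        out[first] = np.log(pi0[np.arange(first.sum()), s[first] - 1])
    return out


def log_posterior(
    x: np.ndarray,
    s: np.ndarray,
    params: MovementParams,
    phi: np.ndarray,
    data: ModelData,
    config: PriorConfig | None = None,
) -> float:
    """Full joint log posterior density (up to data-independent constants)."""
    config = config or PriorConfig()
    lp = prior_logdensity(params, phi, data.formulation, config)
    if not np.isfinite(lp):
        return -np.inf
    Q = build_transition_tensor(phi, data)
    lp += transition_terms(s, Q, data).sum()
    lp += process_terms(x, s, params, data).sum()
    lp += init_position_terms(x, data, config).sum()
    lp += observation_terms(x, params.psi, data).sum()
    return float(lp)


def deviance(x: np.ndarray, psi: float, data: ModelData) -> float:
    """-2 x observation log likelihood (the monitored deviance)."""
    return float(-2.0 * observation_terms(x, psi, data).sum())
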