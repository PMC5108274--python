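"""Metropolis-within-Gibbs sampler for the switching CRW models.

Per sweep the blocks are updated in order: latent positions
(single-site random-walk Metropolis over three interleaved residue
classes, so simultaneously updated sites never share a likelihood
term), discrete behavioral states (exact categorical full conditionals
over two parity classes), the continuous movement parameters
(Metropolis), and the transition matrix rows (conjugate Dirichlet draws
from the transition counts, respecting each formulation's structural
zeros).

Proposal scales adapt toward a target acceptance rate during burn-in
only and are frozen afterwards, preserving detailed balance for the
retained draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .activity_mapping import STATUS_ACTIVITY, STATUS_OTHER
from .movement_model import (
    ModelData,
    MovementParams,
    PriorConfig,
    TWO_PI,
    build_transition_tensor,
    deviance as _deviance,
    init_position_terms,
    initial_state_distribution,
    n_states,
    observation_terms,
    prior_logdensity,
    process_terms,
    transition_terms,
)

__all__ = [
    "SamplerConfig",
    "PosteriorResult",
    "fit_model",
    "gelman_rubin",
    "hpdi",
    "dic",
]


@dataclass
class SamplerConfig:
    """MCMC protocol settings.

    The full protocol is 2 chains x 40,000 iterations, burn-in 20,000,
    thinning 20 (2,000 retained draws).  ``desk()`` gives a scaled-down
    preset for tests and quick runs.
    """

    n_chains: int = 2
    n_iter: int = 40_000
    n_burn: int = 20_000
    thin: int = 20
    seed: int = 0
    scales: dict = field(
        default_factory=lambda: {
            "x": 0.03,
            "gamma": 0.08,
            "theta": 0.15,
            "sigma": 0.15,
            "psi": 0.3,
        }
    )
    adapt: bool = True
    adapt_interval: int = 50
    target_accept: float = 0.3

    def __post_init__(self) -> None:
        if not self.n_burn < self.n_iter:
            raise ValueError("n_burn must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def draws_per_chain(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin

    @classmethod
    def full(cls, seed: int = 0, **kw) -> "SamplerConfig":
        return cls(seed=seed, **kw)

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "SamplerConfig":
        kw.setdefault("n_iter", 5_000)
        kw.setdefault("n_burn", 2_500)
        kw.setdefault("thin", 5)
        return cls(seed=seed, **kw)


class InitializationError(RuntimeError):
    """Raised when the log posterior is non-finite at initialization."""


# ---------------------------------------------------------------------------
# diagnostics

def gelman_rubin(chains) -> float:
    """Potential scale reduction factor r-hat for one scalar parameter.

    ``chains`` is (m, n): m >= 2 chains of equal length n >= 10.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("gelman_rubin needs >= 2 chains of equal length")
    m, n = chains.shape
    if n < 10:
        raise ValueError("chains too short for r-hat")
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def hpdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * n)`` sorted samples.

    Among equally short windows the first (lowest) one is returned.
    """
    s = np.sort(np.asarray(samples, dtype=float).ravel())
    if s.size == 0:
        raise ValueError("hpdi of empty sample")
    n = s.size
    m = min(n, int(np.ceil(mass * n)))
    if m == n:
        return float(s[0]), float(s[-1])
    widths = s[m - 1 :] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def dic(deviance_draws, point_deviance: float) -> tuple[float, float, float]:
    """Deviance information criterion pieces: (D-bar, pD, DIC).

    D-bar is the posterior mean deviance, pD = D-bar - D(point
    estimate), DIC = D-bar + pD.
    """
    d = np.asarray(deviance_draws, dtype=float)
    dbar = float(d.mean())
    pd_ = dbar - float(point_deviance)
    return dbar, pd_, dbar + pd_


# ---------------------------------------------------------------------------
# posterior container

@dataclass
class PosteriorResult:
    """Thinned posterior draws plus convergence and fit summaries."""

    data: ModelData
    config: SamplerConfig
    priors: PriorConfig
    gamma: np.ndarray  # (N, K)
    theta: np.ndarray  # (N, K)
    sigma: np.ndarray  # (N, 3): sigma_lon, sigma_lat, rho
    psi: np.ndarray  # (N,)
    phi: np.ndarray  # (N, K, K)
    states: np.ndarray  # (N, n_steps) int8
    positions: np.ndarray  # (N, n_steps, 2) float32
    deviance_draws: np.ndarray  # (N,)
    chain: np.ndarray  # (N,)
    rhat: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.psi.size

    @property
    def K(self) -> int:
        return self.gamma.shape[1]

    def param_draws(self) -> dict:
        """Scalar parameter draws keyed by name (theta recentered so
        summaries are not split across the circular boundary)."""
        out = {}
        for i in range(self.K):
            out[f"gamma[{i+1}]"] = self.gamma[:, i]
            out[f"theta[{i+1}]"] = _recenter_angles(self.theta[:, i])
        out["sigma_lon"] = self.sigma[:, 0]
        out["sigma_lat"] = self.sigma[:, 1]
        out["rho"] = self.sigma[:, 2]
        out["psi"] = self.psi
        for i in range(self.K):
            for j in range(self.K):
                if self._phi_free(i, j):
                    out[f"phi[{i+1},{j+1}]"] = self.phi[:, i, j]
        return out

    def _phi_free(self, i: int, j: int) -> bool:
        f = self.data.formulation
        if f in ("two_state", "three_state"):
            return True
        if f == "haulout":
            return j < 2
        return j == 0  # activity: only switches into state 1 are estimated

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        rows = []
        for name, draws in self.param_draws().items():
            lo, hi = hpdi(draws, mass)
            rows.append(
                {
                    "parameter": name,
                    "median": float(np.median(draws)),
                    "hpdi_lo": lo,
                    "hpdi_hi": hi,
                    "rhat": self.rhat.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def point_deviance(self) -> float:
        """Deviance at the posterior mean positions and psi."""
        x_hat = self.positions.astype(float).mean(axis=0)
        return _deviance(x_hat, float(self.psi.mean()), self.data)

    def dic(self) -> tuple[float, float, float]:
        return dic(self.deviance_draws, self.point_deviance())

    def save(self, directory) -> None:
        """Persist draws and summaries as CSVs in ``directory``."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.param_draws()).assign(
            chain=self.chain, deviance=self.deviance_draws
        ).to_csv(d / "param_draws.csv", index=False)
        self.summary().to_csv(d / "summary.csv", index=False)
        np.savetxt(d / "state_draws.csv", self.states, fmt="%d", delimiter=",")
        med = np.median(self.positions.astype(float), axis=0)
        pd.DataFrame(
            {"lon_median": med[:, 0], "lat_median": med[:, 1]}
        ).to_csv(d / "positions_median.csv", index=False)


def _recenter_angles(draws: np.ndarray) -> np.ndarray:
    """Wrap angle draws into a window centered on their circular mean."""
    mean = np.arctan2(np.sin(draws).mean(), np.cos(draws).mean())
    return np.mod(draws - mean + np.pi, TWO_PI) + mean - np.pi


# ---------------------------------------------------------------------------
# the sampler

class _GibbsSampler:
    def __init__(
        self,
        data: ModelData,
        config: SamplerConfig,
        priors: PriorConfig,
        rng: np.random.Generator,
    ):
        self.data = data
        self.cfg = config
        self.priors = priors
        self.rng = rng
        self.K = data.K
        n = data.n_steps
        self.scales = dict(config.scales)

        # --- initialization
        self.x = self._init_positions()
        self.s = self._init_states()
        g0 = np.array([0.6, 0.3, 0.2])[: self.K]
        th0 = np.array([0.0, np.pi, np.pi])[: self.K]
        self.params = MovementParams(
            gamma=g0, theta=th0, sigma_lon=0.1, sigma_lat=0.1, rho=0.0, psi=1.0
        )
        self.phi = self._init_phi()
        self._check_init()

        # --- static structure for the residue-class position sweeps
        idx = np.arange(n)
        self.u_valid = np.flatnonzero(data.proc_valid)
        self._pos_classes = []
        for r in range(3):
            sites = idx[idx % 3 == r]
            owner_u = self.u_valid - ((self.u_valid - r) % 3)
            k = data.obs_site
            owner_obs = np.where(
                k % 3 == r, k, np.where((k + 1) % 3 == r, k + 1, -1)
            )
            self._pos_classes.append((sites, owner_u, owner_obs))

        self._state_classes = []
        unforced = ~data.forced_state3
        for parity in range(2):
            sites = idx[(idx % 2 == parity) & unforced]
            self._state_classes.append(sites)

        self._acc = {k: [0, 0] for k in ("x", "gamma", "theta", "sigma", "psi")}

    # -- initialization helpers

    def _init_positions(self) -> np.ndarray:
        d = self.data
        x = np.zeros((d.n_steps, 2))
        bounds = list(d.offsets) + [d.n_steps]
        obs_pos = d.obs_site + d.obs_frac
        for a in range(len(d.animal_ids)):
            lo, hi = bounds[a], bounds[a + 1]
            m = (d.obs_site >= lo) & (d.obs_site < hi)
            t_obs = obs_pos[m] - lo
            order = np.argsort(t_obs)
            grid_t = np.arange(hi - lo)
            x[lo:hi, 0] = np.interp(grid_t, t_obs[order], d.obs_lon[m][order])
            x[lo:hi, 1] = np.interp(grid_t, t_obs[order], d.obs_lat[m][order])
        return x

    def _init_states(self) -> np.ndarray:
        d = self.data
        s = np.full(d.n_steps, 2, dtype=int)
        s[d.forced_state3] = 3
        if d.formulation == "activity":
            # zero-probability inits would make the chain unstartable:
            # pr_A = 1 excludes state 2, pr_A = 0 excludes state 3
            s[d.pr_A > 0.5] = 3
        return s

    def _init_phi(self) -> np.ndarray:
        K = self.K
        f = self.data.formulation
        if f in ("two_state", "three_state"):
            return np.full((K, K), 1.0 / K)
        if f == "haulout":
            phi = np.zeros((3, 3))
            phi[:, :2] = 0.5
            return phi
        phi = np.zeros((3, 3))
        phi[:, 0] = 0.2
        phi[:, 1] = 0.8
        return phi

    def _check_init(self) -> None:
        pieces = {
            "prior": prior_logdensity(
                self.params, self.phi, self.data.formulation, self.priors
            ),
            "transition": transition_terms(
                self.s, build_transition_tensor(self.phi, self.data), self.data
            ).sum(),
            "process": process_terms(self.x, self.s, self.params, self.data).sum(),
            "initial-position": init_position_terms(
                self.x, self.data, self.priors
            ).sum(),
            "observation": observation_terms(
                self.x, self.params.psi, self.data
            ).sum(),
        }
        for name, val in pieces.items():
            if not np.isfinite(val):
                raise InitializationError(
                    f"non-finite {name} log density at initialization ({val})"
                )

    # -- likelihood helpers

    def _crw_ll(self, T: np.ndarray, x: np.ndarray, g, th) -> np.ndarray:
        """CRW log densities at steps T (all must have a process term)."""
        p = self.params
        disp = x[T - 1] - x[T - 2]
        c, sn = np.cos(th), np.sin(th)
        mlon = x[T - 1, 0] + g * (c * disp[:, 0] - sn * disp[:, 1])
        mlat = x[T - 1, 1] + g * (sn * disp[:, 0] + c * disp[:, 1])
        return self._bivnorm_ll(
            x[T, 0] - mlon, x[T, 1] - mlat, p.sigma_lon, p.sigma_lat, p.rho
        )

    @staticmethod
    def _bivnorm_ll(r1, r2, s1, s2, rho):
        det = (s1 * s2) ** 2 * (1 - rho**2)
        i11 = 1.0 / (s1**2 * (1 - rho**2))
        i22 = 1.0 / (s2**2 * (1 - rho**2))
        i12 = -rho / (s1 * s2 * (1 - rho**2))
        q = i11 * r1**2 + 2 * i12 * r1 * r2 + i22 * r2**2
        return -np.log(TWO_PI) - 0.5 * np.log(det) - 0.5 * q

    # -- block updates

    def update_positions(self) -> None:
        d, rng = self.data, self.rng
        n = d.n_steps
        scale = self.scales["x"]
        for sites, owner_u, owner_obs in self._pos_classes:
            x_prop = self.x.copy()
            x_prop[sites] += scale * rng.standard_normal((sites.size, 2))
            proc_old = process_terms(self.x, self.s, self.params, d)
            proc_new = process_terms(x_prop, self.s, self.params, d)
            delta = np.bincount(
                owner_u,
                weights=(proc_new - proc_old)[self.u_valid],
                minlength=n,
            )
            init_old = init_position_terms(self.x, d, self.priors)
            init_new = init_position_terms(x_prop, d, self.priors)
            delta += init_new - init_old
            obs_old = observation_terms(self.x, self.params.psi, d)
            obs_new = observation_terms(x_prop, self.params.psi, d)
            m = owner_obs >= 0
            delta += np.bincount(
                owner_obs[m], weights=(obs_new - obs_old)[m], minlength=n
            )
            acc = np.log(rng.uniform(size=sites.size)) < delta[sites]
            self.x[sites[acc]] = x_prop[sites[acc]]
            self._acc["x"][0] += int(acc.sum())
            self._acc["x"][1] += sites.size

    def update_states(self) -> None:
        d, rng, K = self.data, self.rng, self.K
        Q = build_transition_tensor(self.phi, d)
        logQ = np.log(np.where(Q > 0, Q, 1e-300))
        sia = d.step_in_animal
        p = self.params
        for sites in self._state_classes:
            if sites.size == 0:
                continue
            L = np.zeros((sites.size, K))
            has_prev = sia[sites] >= 1
            tp = sites[has_prev]
            L[has_prev] += logQ[tp, self.s[tp - 1] - 1, :]
            t0 = sites[~has_prev]
            if t0.size:
                pi0 = initial_state_distribution(d, t0)
                L[~has_prev] += np.log(np.where(pi0 > 0, pi0, 1e-300))
            nxt = sites + 1
            has_next = nxt < d.n_steps
            hn = np.zeros(sites.size, dtype=bool)
            hn[has_next] = sia[nxt[has_next]] == sia[sites[has_next]] + 1
            tn = nxt[hn]
            L[hn] += logQ[tn, :, self.s[tn] - 1]
            pv = sia[sites] >= 2
            T = sites[pv]
            if T.size:
                for j in range(K):
                    L[pv, j] += self._crw_ll(
                        T, self.x, p.gamma[j], p.theta[j]
                    )
            L -= L.max(axis=1, keepdims=True)
            w = np.exp(L)
            w /= w.sum(axis=1, keepdims=True)
            u = rng.uniform(size=sites.size)
            snew = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)
            self.s[sites] = snew + 1

    def _proc_subset_for_state(self, i: int) -> np.ndarray:
        return self.u_valid[self.s[self.u_valid] == i + 1]

    def update_gamma_theta(self) -> None:
        p, rng = self.params, self.rng
        for i in range(self.K):
            T = self._proc_subset_for_state(i)
            # gamma_i
            prop = p.gamma[i] + self.scales["gamma"] * rng.standard_normal()
            ok = 0.0 <= prop < 1.0
            if ok and self.priors.order_gamma and self.K >= 2:
                g = p.gamma.copy()
                g[i] = prop
                ok = g[0] > g[1]
            if ok:
                delta = 0.0
                if T.size:
                    old = self._crw_ll(T, self.x, p.gamma[i], p.theta[i])
                    new = self._crw_ll(T, self.x, prop, p.theta[i])
                    delta = float((new - old).sum())
                if np.log(rng.uniform()) < delta:
                    p.gamma[i] = prop
                    self._acc["gamma"][0] += 1
            self._acc["gamma"][1] += 1
            # theta_i (circular proposal)
            prop = np.mod(
                p.theta[i] + self.scales["theta"] * rng.standard_normal(), TWO_PI
            )
            delta = 0.0
            if T.size:
                old = self._crw_ll(T, self.x, p.gamma[i], p.theta[i])
                new = self._crw_ll(T, self.x, p.gamma[i], prop)
                delta = float((new - old).sum())
            if self.priors.theta2_informative and i == 1:
                delta += float(
                    _wn_logpdf(prop, self.priors.theta2_mean, self.priors.theta2_sd)
                    - _wn_logpdf(
                        np.mod(p.theta[i], TWO_PI),
                        self.priors.theta2_mean,
                        self.priors.theta2_sd,
                    )
                )
            if np.log(rng.uniform()) < delta:
                p.theta[i] = prop
                self._acc["theta"][0] += 1
            self._acc["theta"][1] += 1

    def update_sigma(self) -> None:
        p, rng = self.params, self.rng
        T = self.u_valid
        z = np.array(
            [np.log(p.sigma_lon), np.log(p.sigma_lat), np.arctanh(p.rho)]
        )
        zp = z + self.scales["sigma"] * rng.standard_normal(3) * np.array(
            [1.0, 1.0, 0.5]
        )
        s1, s2 = np.exp(zp[0]), np.exp(zp[1])
        rho = np.tanh(zp[2])
        g = p.gamma[self.s[T] - 1]
        th = p.theta[self.s[T] - 1]
        disp = self.x[T - 1] - self.x[T - 2]
        c, sn = np.cos(th), np.sin(th)
        r1 = self.x[T, 0] - (self.x[T - 1, 0] + g * (c * disp[:, 0] - sn * disp[:, 1]))
        r2 = self.x[T, 1] - (self.x[T - 1, 1] + g * (sn * disp[:, 0] + c * disp[:, 1]))
        old = self._bivnorm_ll(r1, r2, p.sigma_lon, p.sigma_lat, p.rho).sum()
        new = self._bivnorm_ll(r1, r2, s1, s2, rho).sum()
        # half-normal prior on sigmas; Jacobians of log / atanh transforms
        sc = self.priors.sigma_scale
        dprior = -0.5 * ((s1**2 + s2**2) - (p.sigma_lon**2 + p.sigma_lat**2)) / sc**2
        djac = (zp[0] + zp[1]) - (z[0] + z[1])
        djac += np.log1p(-rho**2) - np.log1p(-p.rho**2)
        if np.log(rng.uniform()) < new - old + dprior + djac:
            p.sigma_lon, p.sigma_lat, p.rho = float(s1), float(s2), float(rho)
            self._acc["sigma"][0] += 1
        self._acc["sigma"][1] += 1

    def update_psi(self) -> None:
        p, rng, d = self.params, self.rng, self.data
        m = d.obs_is_psi
        prop = p.psi + self.scales["psi"] * rng.standard_normal()
        if 0.0 <= prop <= self.priors.psi_max:
            if m.any():
                old = observation_terms(self.x, p.psi, d)[m].sum()
                new = observation_terms(self.x, prop, d)[m].sum()
                delta = float(new - old)
            else:
                delta = 0.0
            if np.log(rng.uniform()) < delta:
                p.psi = float(prop)
                self._acc["psi"][0] += 1
        self._acc["psi"][1] += 1

    def update_phi(self) -> None:
        d, rng, K = self.data, self.rng, self.K
        tv = np.flatnonzero(d.trans_valid)
        prev = self.s[tv - 1] - 1
        cur = self.s[tv] - 1
        f = d.formulation
        if f in ("two_state", "three_state"):
            counts = np.zeros((K, K))
            np.add.at(counts, (prev, cur), 1.0)
            for i in range(K):
                self.phi[i] = rng.dirichlet(1.0 + counts[i])
        elif f == "haulout":
            free = d.a_status[tv] == STATUS_OTHER  # target step unforced
            counts = np.zeros((3, 2))
            np.add.at(counts, (prev[free], cur[free]), 1.0)
            for i in range(3):
                row = rng.dirichlet(1.0 + counts[i])
                self.phi[i, :2] = row
                self.phi[i, 2] = 0.0
        else:  # activity: Beta on switches into state 1
            n1 = np.zeros(3)
            nrest = np.zeros(3)
            np.add.at(n1, prev[cur == 0], 1.0)
            np.add.at(nrest, prev[cur != 0], 1.0)
            for i in range(3):
                p1 = rng.beta(1.0 + n1[i], 1.0 + nrest[i])
                self.phi[i] = [p1, 1.0 - p1, 0.0]

    def sweep(self) -> None:
        self.update_positions()
        self.update_states()
        self.update_gamma_theta()
        self.update_sigma()
        self.update_psi()
        self.update_phi()

    def adapt(self) -> None:
        for key, (acc, tot) in self._acc.items():
            if tot == 0:
                continue
            rate = acc / tot
            factor = np.exp(
                np.clip(rate - self.cfg.target_accept, -0.5, 0.5)
            )
            self.scales[key] = float(
                np.clip(self.scales[key] * factor, 1e-5, 50.0)
            )
            self._acc[key] = [0, 0]


def _wn_logpdf(x, mean, sd):
    from .movement_model import _wrapped_normal_logpdf

    return _wrapped_normal_logpdf(np.asarray(x, dtype=float), mean, sd)


def fit_model(
    data: ModelData,
    config: SamplerConfig | None = None,
    priors: PriorConfig | None = None,
) -> PosteriorResult:
    """Fit the formulation encoded in ``data`` by Metropolis-within-Gibbs.

    Runs ``config.n_chains`` chains sequentially with per-chain RNG
    streams derived from the master seed; retains post-burn-in thinned
    draws from all chains and computes per-parameter r-hat across
    chains.
    """
    config = config or SamplerConfig()
    priors = priors or PriorConfig()
    K = data.K
    per_chain: list[dict] = []
    for chain in range(config.n_chains):
        rng = np.random.default_rng([config.seed, chain])
        smp = _GibbsSampler(data, config, priors, rng)
        n_keep = config.draws_per_chain
        rec = {
            "gamma": np.empty((n_keep, K)),
            "theta": np.empty((n_keep, K)),
            "sigma": np.empty((n_keep, 3)),
            "psi": np.empty(n_keep),
            "phi": np.empty((n_keep, K, K)),
            "states": np.empty((n_keep, data.n_steps), dtype=np.int8),
            "positions": np.empty((n_keep, data.n_steps, 2), dtype=np.float32),
            "deviance": np.empty(n_keep),
        }
        kept = 0
        for it in range(1, config.n_iter + 1):
            smp.sweep()
            if config.adapt and it <= config.n_burn:
                if it % config.adapt_interval == 0:
                    smp.adapt()
            if it > config.n_burn and (it - config.n_burn) % config.thin == 0:
                if kept < n_keep:
                    p = smp.params
                    rec["gamma"][kept] = p.gamma
                    rec["theta"][kept] = np.mod(p.theta, TWO_PI)
                    rec["sigma"][kept] = (p.sigma_lon, p.sigma_lat, p.rho)
                    rec["psi"][kept] = p.psi
                    rec["phi"][kept] = smp.phi
                    rec["states"][kept] = smp.s
                    rec["positions"][kept] = smp.x
                    rec["deviance"][kept] = _deviance(smp.x, p.psi, data)
                    kept += 1
        per_chain.append(rec)

    def cat(key):
        return np.concatenate([r[key] for r in per_chain], axis=0)

    n_keep = config.draws_per_chain
    result = PosteriorResult(
        data=data,
        config=config,
        priors=priors,
        gamma=cat("gamma"),
        theta=cat("theta"),
        sigma=cat("sigma"),
        psi=cat("psi"),
        phi=cat("phi"),
        states=cat("states"),
        positions=cat("positions"),
        deviance_draws=cat("deviance"),
        chain=np.repeat(np.arange(config.n_chains), n_keep),
    )
    if config.n_chains >= 2 and n_keep >= 10:
        rhat = {}
        for name, draws in result.param_draws().items():
            chains = draws.reshape(config.n_chains, n_keep)
            rhat[name] = gelman_rubin(chains)
        rhat["deviance"] = gelman_rubin(
            result.deviance_draws.reshape(config.n_chains, n_keep)
        )
        result.rhat = rhat
    return result
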