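import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ssmtrack import movement_model as mm
from ssmtrack import synthetic_data as sd
from ssmtrack.activity_mapping import STATUS_ACTIVITY, STATUS_OTHER
from ssmtrack.telemetry_io import ArgosObservation

import pandas as pd


class TestRotationStepMean:
    def test_gamma_zero_is_simple_random_walk(self):
        out = mm.rotation_step_mean((1.0, 2.0), (0.0, 0.0), 0.0, 1.234)
        np.testing.assert_allclose(out, [1.0, 2.0])

    def test_pure_continuation(self):
        out = mm.rotation_step_mean((1.0, 0.0), (0.0, 0.0), 1.0, 0.0)
        np.testing.assert_allclose(out, [2.0, 0.0])

    def test_half_reversal(self):
        out = mm.rotation_step_mean((1.0, 0.0), (0.0, 0.0), 0.5, np.pi)
        np.testing.assert_allclose(out, [0.5, 0.0], atol=1e-12)

    def test_quarter_turn_ccw(self):
        out = mm.rotation_step_mean((1.0, 0.0), (0.0, 0.0), 1.0, np.pi / 2)
        np.testing.assert_allclose(out, [1.0, 1.0], atol=1e-12)


class TestTransitionDistribution:
    def test_haulout_forced(self):
        phi = np.array([[0.7, 0.3, 0.0], [0.2, 0.8, 0.0], [0.5, 0.5, 0.0]])
        out = mm.transition_distribution(1, phi, "haulout", a_status=STATUS_ACTIVITY)
        np.testing.assert_allclose(out, [0, 0, 1])

    def test_haulout_unforced_renormalizes(self):
        phi = np.array([[0.35, 0.35, 0.3]] * 3)
        out = mm.transition_distribution(1, phi, "haulout", a_status=STATUS_OTHER)
        np.testing.assert_allclose(out, [0.5, 0.5, 0.0])

    def test_activity_certain_inactivity(self):
        phi = np.array([[0.0, 1.0, 0.0]] * 3)
        out = mm.transition_distribution(1, phi, "activity", pr_A=1.0)
        np.testing.assert_allclose(out, [0, 0, 1])

    def test_activity_split_arithmetic(self):
        phi = np.array([[0.2, 0.8, 0.0]] * 3)
        out = mm.transition_distribution(1, phi, "activity", pr_A=0.25)
        np.testing.assert_allclose(out, [0.2, 0.6, 0.2])

    def test_two_state_row_passthrough(self):
        phi = np.array([[0.9, 0.1], [0.4, 0.6]])
        np.testing.assert_allclose(
            mm.transition_distribution(2, phi, "two_state"), [0.4, 0.6]
        )

    def test_invalid_state_index(self):
        with pytest.raises(ValueError):
            mm.transition_distribution(5, np.eye(3), "three_state")

    @settings(max_examples=80, deadline=None)
    @given(
        form=st.sampled_from(mm.FORMULATIONS),
        pr=st.floats(min_value=0.0, max_value=1.0),
        a=st.sampled_from([STATUS_ACTIVITY, STATUS_OTHER]),
        raw=st.lists(
            st.floats(min_value=0.01, max_value=1.0), min_size=3, max_size=3
        ),
        s_prev=st.integers(min_value=1, max_value=3),
    )
    def test_always_simplex(self, form, pr, a, raw, s_prev):
        K = mm.n_states(form)
        if s_prev > K:
            return
        row = np.asarray(raw[:K])
        row = row / row.sum()
        if form == "haulout":
            row = np.array([raw[0], raw[1], 0.0])
            row = row / row.sum()
        phi = np.tile(row, (K, 1))
        out = mm.transition_distribution(s_prev, phi, form, pr_A=pr, a_status=a)
        assert out.shape == (K,)
        assert np.all(out >= 0)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)


class TestObservationPrediction:
    def test_j_zero(self):
        np.testing.assert_allclose(
            mm.observation_prediction((3.0, 4.0), (9.0, 9.0), 0.0), [3, 4]
        )

    def test_midpoint(self):
        np.testing.assert_allclose(
            mm.observation_prediction((0.0, 0.0), (2.0, 4.0), 0.5), [1, 2]
        )

    def test_quarter(self):
        np.testing.assert_allclose(
            mm.observation_prediction((0.0, 0.0), (4.0, 0.0), 0.25), [1, 0]
        )


def _obs(lon, lat, lc):
    return ArgosObservation("x", pd.Timestamp("2011-01-01", tz="UTC"), lon, lat, lc)


class TestObservationLoglik:
    def test_maximum_at_zero_residual(self):
        table = mm.ObservationErrorTable.default()
        at_mode = mm.observation_loglik(_obs(70.0, -68.0, "3"), (70.0, -68.0), table)
        off = mm.observation_loglik(_obs(70.0, -68.0, "3"), (70.01, -68.0), table)
        assert at_mode > off

    def test_wider_scale_lowers_density_near_mode(self):
        table = mm.ObservationErrorTable.default()
        wide = mm.ObservationErrorTable(
            tau_lon=table.tau_lon * 2, tau_lat=table.tau_lat * 2,
            nu_lon=table.nu_lon, nu_lat=table.nu_lat,
        )
        y = _obs(70.001, -68.0, "3")
        assert mm.observation_loglik(y, (70.0, -68.0), table) > mm.observation_loglik(
            y, (70.0, -68.0), wide
        )
        # agreement with direct scipy t evaluation
        c = table.class_index("3")
        expect = stats.t.logpdf(0.001, table.nu_lon[c], scale=table.tau_lon[c]) + stats.t.logpdf(
            0.0, table.nu_lat[c], scale=table.tau_lat[c]
        )
        assert mm.observation_loglik(y, (70.0, -68.0), table) == pytest.approx(
            float(expect), abs=1e-10
        )

    def test_psi_scopes_only_low_quality_classes(self):
        table = mm.ObservationErrorTable.default()
        y3 = _obs(70.001, -68.0, "3")
        yB = _obs(70.001, -68.0, "B")
        assert mm.observation_loglik(y3, (70, -68), table, psi=1.0) == pytest.approx(
            mm.observation_loglik(y3, (70, -68), table, psi=2.0)
        )
        assert mm.observation_loglik(yB, (70, -68), table, psi=1.0) != pytest.approx(
            mm.observation_loglik(yB, (70, -68), table, psi=2.0)
        )

    def test_unknown_class_rejected(self):
        table = mm.ObservationErrorTable.default()
        with pytest.raises(Exception):
            table.class_index("Z")


class TestPrior:
    def _params(self, **kw):
        base = dict(
            gamma=[0.7, 0.3], theta=[0.0, np.pi], sigma_lon=0.1, sigma_lat=0.1,
            rho=0.0, psi=1.0,
        )
        base.update(kw)
        return mm.MovementParams(**base)

    def test_uniform_dirichlet_constant_in_phi(self):
        p = self._params()
        cfg = mm.PriorConfig()
        a = mm.prior_logdensity(p, np.array([[0.5, 0.5], [0.5, 0.5]]), "two_state", cfg)
        b = mm.prior_logdensity(p, np.array([[0.9, 0.1], [0.2, 0.8]]), "two_state", cfg)
        assert a == pytest.approx(b)

    def test_gamma_out_of_support(self):
        p = self._params(gamma=[1.2, 0.3])
        assert mm.prior_logdensity(
            p, np.full((2, 2), 0.5), "two_state", mm.PriorConfig()
        ) == -np.inf

    def test_gamma_order_guard(self):
        p = self._params(gamma=[0.2, 0.6])
        assert mm.prior_logdensity(
            p, np.full((2, 2), 0.5), "two_state", mm.PriorConfig(order_gamma=True)
        ) == -np.inf

    def test_informative_theta2_favors_pi(self):
        cfg = mm.PriorConfig(theta2_informative=True)
        at_pi = mm.prior_logdensity(
            self._params(theta=[0.0, np.pi]), np.full((2, 2), 0.5), "two_state", cfg
        )
        at_zero = mm.prior_logdensity(
            self._params(theta=[0.0, 0.01]), np.full((2, 2), 0.5), "two_state", cfg
        )
        assert at_pi > at_zero


def _tiny_data(formulation, seed=5, n_steps=10):
    name = "weddell_t2" if formulation in ("haulout", "two_state", "three_state") else "afs_t2"
    spec = sd.preset(name, n_animals=1, n_steps=n_steps, seed=seed)
    spec.formulation = formulation
    K = mm.n_states(formulation)
    if formulation == "two_state":
        spec.phi = np.array([[0.8, 0.2], [0.3, 0.7]])
        spec.params = mm.MovementParams(
            gamma=spec.params.gamma[:2], theta=spec.params.theta[:2],
            sigma_lon=spec.params.sigma_lon, sigma_lat=spec.params.sigma_lat,
        )
    spec.__post_init__()
    return sd.simulate_dataset(spec)


def _random_state_config(data, rng, K):
    """Random positions and a state sequence with positive probability."""
    x = rng.normal(size=(data.n_steps, 2)) * 0.2 + data.anchor
    s = rng.integers(1, min(K, 2) + 1, size=data.n_steps)
    if data.formulation == "three_state":
        s = rng.integers(1, 4, size=data.n_steps)
    s[data.forced_state3] = 3
    if data.formulation == "activity":
        s[data.pr_A > 0.5] = 3  # state 2 impossible where pr_A = 1
    return x, s


def _oracle_log_posterior(x, s, params, phi, data, cfg):
    """Term-by-term brute force using scipy densities and the scalar ops."""
    from ssmtrack.movement_model import initial_state_distribution

    total = mm.prior_logdensity(params, phi, data.formulation, cfg)
    Sigma = params.Sigma
    for t in range(data.n_steps):
        sia = data.step_in_animal[t]
        if sia >= 2:
            mean = mm.rotation_step_mean(
                x[t - 1], x[t - 2], params.gamma[s[t] - 1], params.theta[s[t] - 1]
            )
            total += stats.multivariate_normal.logpdf(x[t], mean=mean, cov=Sigma)
        else:
            total += stats.norm.logpdf(
                x[t], loc=data.anchor[t], scale=cfg.init_sd
            ).sum()
        if sia >= 1:
            p = mm.transition_distribution(
                int(s[t - 1]), phi, data.formulation,
                pr_A=float(data.pr_A[t]), a_status=int(data.a_status[t]),
            )[s[t] - 1]
            total += np.log(p)
        else:
            pi0 = initial_state_distribution(data, np.array([t]))[0]
            total += np.log(pi0[s[t] - 1])
    for i in range(data.n_obs):
        k, j = data.obs_site[i], data.obs_frac[i]
        pred = mm.observation_prediction(x[k], x[k + 1], j)
        infl = params.psi if data.obs_is_psi[i] else 1.0
        total += stats.t.logpdf(
            data.obs_lon[i] - pred[0], data.obs_nu_lon[i],
            scale=data.obs_tau_lon[i] * infl,
        )
        total += stats.t.logpdf(
            data.obs_lat[i] - pred[1], data.obs_nu_lat[i],
            scale=data.obs_tau_lat[i] * infl,
        )
    return float(total)


@pytest.mark.parametrize("formulation", mm.FORMULATIONS)
def test_log_posterior_matches_brute_force(formulation, rng):
    ds = _tiny_data(formulation)
    data = ds.model_data()
    K = data.K
    x, s = _random_state_config(data, rng, K)
    params = ds.spec.params.copy()
    params.psi = 1.3
    phi = ds.spec.phi.copy()
    if formulation == "haulout":
        phi = np.array([[0.6, 0.4, 0.0], [0.25, 0.75, 0.0], [0.5, 0.5, 0.0]])
    cfg = mm.PriorConfig(order_gamma=False)
    fast = mm.log_posterior(x, s, params, phi, data, cfg)
    slow = _oracle_log_posterior(x, s, params, phi, data, cfg)
    assert fast == pytest.approx(slow, abs=1e-10)


def test_haulout_without_forcing_reduces_to_two_state(rng):
    """With every step unforced, the haulout model's joint density differs
    from the two-state model's only by parameter-independent constants."""
    ds2 = _tiny_data("two_state", seed=9, n_steps=12)
    data2 = ds2.model_data()
    # same observations, haulout structure with no forced steps
    from ssmtrack.movement_model import build_model_data
    from ssmtrack.activity_mapping import ActivityProbability, STATUS_OTHER

    animals3 = []
    for grid, obs in zip(ds2.grids, ds2.observations):
        act = ActivityProbability(
            pr_A=np.zeros(grid.n_steps),
            a_status=np.full(grid.n_steps, STATUS_OTHER, dtype=np.int8),
        )
        animals3.append((grid, obs, act))
    data3 = build_model_data("haulout", animals3, error_table=ds2.error_table)

    cfg = mm.PriorConfig(order_gamma=False)
    deltas2, deltas3 = [], []
    prev2 = prev3 = None
    for _ in range(4):
        x = rng.normal(size=(data2.n_steps, 2)) * 0.1 + data2.anchor
        s = rng.integers(1, 3, size=data2.n_steps)
        g = np.sort(rng.uniform(0.0, 1.0, size=2))[::-1]
        th = rng.uniform(0, 2 * np.pi, size=2)
        p = rng.uniform(0.1, 0.9, size=2)
        params2 = mm.MovementParams(g, th, 0.08, 0.06, 0.0, 1.0)
        params3 = mm.MovementParams(
            np.append(g, 0.5), np.append(th, 1.0), 0.08, 0.06, 0.0, 1.0
        )
        phi2 = np.array([[p[0], 1 - p[0]], [p[1], 1 - p[1]]])
        phi3 = np.array(
            [[p[0], 1 - p[0], 0.0], [p[1], 1 - p[1], 0.0], [0.5, 0.5, 0.0]]
        )
        lp2 = mm.log_posterior(x, s, params2, phi2, data2, cfg)
        lp3 = mm.log_posterior(x, s, params3, phi3, data3, cfg)
        if prev2 is not None:
            deltas2.append(lp2 - prev2)
            deltas3.append(lp3 - prev3)
        prev2, prev3 = lp2, lp3
    np.testing.assert_allclose(deltas2, deltas3, atol=1e-8)


def test_gamma_zero_collapses_to_driftless_walk():
    spec = sd.preset("weddell_t2", n_animals=1, n_steps=2000, seed=21)
    spec.params.gamma[:] = 0.0
    s, x = sd.simulate_states_and_track(spec, animal=0)
    steps = np.diff(x, axis=0)
    mean_step = steps.mean(axis=0)
    assert np.all(np.abs(mean_step) < 5 * spec.params.sigma_lon / np.sqrt(len(steps)))


def test_single_site_locality_matches_full_difference(rng):
    """A one-site position change alters exactly the terms the sampler
    attributes to that site; the summed local delta equals the full
    log-posterior difference."""
    ds = _tiny_data("haulout", seed=3, n_steps=12)
    data = ds.model_data()
    x, s = _random_state_config(data, rng, 3)
    params = ds.spec.params.copy()
    phi = np.array([[0.6, 0.4, 0.0], [0.25, 0.75, 0.0], [0.5, 0.5, 0.0]])
    cfg = mm.PriorConfig(order_gamma=False)
    for t in [0, 1, 5, data.n_steps - 1]:
        x2 = x.copy()
        x2[t] += rng.normal(size=2) * 0.05
        full_delta = mm.log_posterior(x2, s, params, phi, data, cfg) - mm.log_posterior(
            x, s, params, phi, data, cfg
        )
        local = 0.0
        proc_old = mm.process_terms(x, s, params, data)
        proc_new = mm.process_terms(x2, s, params, data)
        for u in (t, t + 1, t + 2):
            if u < data.n_steps:
                local += proc_new[u] - proc_old[u]
        local += (
            mm.init_position_terms(x2, data, cfg) - mm.init_position_terms(x, data, cfg)
        ).sum()
        obs_old = mm.observation_terms(x, params.psi, data)
        obs_new = mm.observation_terms(x2, params.psi, data)
        m = (data.obs_site == t) | (data.obs_site == t - 1)
        local += (obs_new[m] - obs_old[m]).sum()
        assert local == pytest.approx(full_delta, abs=1e-8)
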