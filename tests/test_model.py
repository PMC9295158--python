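"""Toggle-switch model: Hill kinetics, vector field, simulation, equilibria."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import root

from cbcswitch.model import (
    InputSchedule,
    STOICHIOMETRY,
    ToggleParams,
    ToggleState,
    Trajectory,
    find_equilibria,
    hill,
    jacobian,
    propensities,
    simulate_ode,
    simulate_sde,
    steady_state,
    toggle_rhs,
    _rhs4,
)


class TestHill:
    def test_limits_and_threshold(self, params):
        assert hill(0.0, 11.65, 2.0) == 1.0
        assert hill(11.65, 11.65, 2.0) == pytest.approx(0.5)

    def test_table_value(self):
        # independent scalar evaluation of 1/(1 + (25/11.65)^2)
        expected = 1.0 / (1.0 + (25.0 / 11.65) ** 2)
        assert hill(25.0, 11.65, 2.0) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", [(-1.0, 1.0, 1.0), (1.0, 0.0, 1.0), (1.0, 1.0, -2.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            hill(*bad)

    @given(x1=st.floats(0, 100), dx=st.floats(0.1, 100),
           theta=st.floats(0.1, 100), eta=st.floats(1, 4))
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing(self, x1, dx, theta, eta):
        assert hill(x1 + dx, theta, eta) < hill(x1, theta, eta)


class TestParams:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            ToggleParams(kLm=-1.0)

    def test_yaml_round_trip(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        params.to_yaml(path)
        assert ToggleParams.from_yaml(path) == params


class TestRhs:
    def test_zero_state_full_derepression(self, params):
        d = toggle_rhs(np.zeros(6), 0.0, 0.0, params)
        assert d[0] == pytest.approx(params.kLm0 + params.kLm)
        assert d[1] == pytest.approx(params.kTm0 + params.kTm)

    def test_equal_inducer_no_exchange(self, params):
        x = np.array([1.0, 1.0, 50.0, 50.0, 25.0, 0.3])
        d = toggle_rhs(x, 25.0, 0.3, params)
        assert d[4] == 0.0 and d[5] == 0.0

    def test_exchange_rate_selection(self, params):
        x = np.array([1.0, 1.0, 50.0, 50.0, 10.0, 0.5])
        d = toggle_rhs(x, 25.0, 0.1, params)  # aTc influx, IPTG efflux
        assert d[4] == pytest.approx(params.kaTcin * 15.0)
        assert d[5] == pytest.approx(params.kIPTGout * -0.4)

    def test_vanishes_at_independent_root(self, params):
        # root found by an independent multidimensional root-finder
        sol = root(lambda y: _rhs4(y, 25.0, 0.1, params),
                   np.array([50.0, 1.0, 3000.0, 70.0]), method="lm")
        assert sol.success
        x = np.concatenate([sol.x, [25.0, 0.1]])
        assert np.linalg.norm(toggle_rhs(x, 25.0, 0.1, params)) < 1e-7


class TestPropensities:
    def test_zero_state_only_transcription(self, params):
        a = propensities(np.zeros(6), params)
        assert (a[:2] > 0).all() and (a[2:] == 0).all()

    def test_negative_state_rejected(self, params):
        with pytest.raises(ValueError):
            propensities(np.array([-1.0, 0, 0, 0, 0, 0]), params)

    def test_linear_mass_action(self, params):
        x = np.array([0.0, 0.0, 100.0, 0.0, 25.0, 0.0])
        a = propensities(x, params)
        assert a[6] == pytest.approx(params.gLp * 100.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_drift_identity_with_rhs(self, params, seed):
        # S @ a(x) must equal the biochemical block of the ODE right side
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, 6) * np.array([50, 15, 3000, 1000, 25, 1])
        drift = STOICHIOMETRY @ propensities(x, params)
        assert drift == pytest.approx(toggle_rhs(x, x[4], x[5], params)[:4])


class TestSimulateOde:
    def test_equilibrium_invariance(self, params):
        x0 = steady_state(params, 25.0, 0.0)
        traj = simulate_ode(params, InputSchedule(aTc=25.0, IPTG=0.0), x0, 300.0)
        assert np.allclose(traj.states, x0, rtol=1e-4, atol=1e-5)

    def test_converges_to_root_finder_equilibrium(self, params):
        x0 = np.array([1.0, 1.0, 10.0, 10.0, 25.0, 0.0])
        traj = simulate_ode(params, InputSchedule(aTc=25.0, IPTG=0.0), x0, 4000.0)
        target = steady_state(params, 25.0, 0.0)
        assert traj.states[-1] == pytest.approx(target, rel=1e-4)

    def test_sampling_consistency(self, params):
        x0 = np.array([1.0, 1.0, 10.0, 10.0, 25.0, 0.0])
        sched = InputSchedule(aTc=25.0, IPTG=0.2)
        coarse = simulate_ode(params, sched, x0, 100.0, sample_period=5.0)
        fine = simulate_ode(params, sched, x0, 100.0, sample_period=2.5)
        assert fine.states[::2] == pytest.approx(coarse.states, rel=1e-5, abs=1e-6)

    def test_nonnegative_states(self, params):
        x0 = np.zeros(6)
        traj = simulate_ode(params, InputSchedule(aTc=25.0, IPTG=1.0), x0, 500.0)
        assert (traj.states >= 0).all()


class TestSimulateSde:
    def test_seed_reproducibility(self, params):
        x0 = steady_state(params, 25.0, 0.0)
        sched = InputSchedule(aTc=25.0, IPTG=0.5)
        a = simulate_sde(params, sched, x0, 100.0, seed=42)
        b = simulate_sde(params, sched, x0, 100.0, seed=42)
        assert (a.states == b.states).all()

    def test_zero_noise_matches_euler_ode(self, params):
        x0 = steady_state(params, 25.0, 0.0)
        sched = InputSchedule(aTc=25.0, IPTG=0.0)
        traj = simulate_sde(params, sched, x0, 200.0, seed=0, noise_scale=0.0)
        # x0 is an equilibrium, so the deterministic Euler path stays put
        assert np.allclose(traj.states, x0, rtol=1e-6, atol=1e-8)

    def test_ensemble_mean_tracks_ode(self, params):
        # deeply monostable regime (no inducer): the CLE ensemble mean of a
        # relaxation transient stays near the deterministic path
        x0 = steady_state(params, 25.0, 0.0)
        x0[3] *= 2.0  # perturb TetR and watch the relaxation
        sched = InputSchedule(aTc=25.0, IPTG=0.0)
        det = simulate_ode(params, sched, x0, 200.0)
        finals = [simulate_sde(params, sched, x0, 200.0, seed=s).states[-1, 3]
                  for s in range(24)]
        mean = np.mean(finals)
        sem = np.std(finals) / np.sqrt(len(finals))
        assert abs(mean - det.states[-1, 3]) < max(5 * sem, 0.1 * det.states[-1, 3])

    def test_nonnegativity(self, params):
        x0 = np.zeros(6)
        traj = simulate_sde(params, InputSchedule(aTc=25.0, IPTG=1.0), x0, 200.0, seed=3)
        assert (traj.states >= 0).all()


class TestJacobian:
    def test_degradation_diagonal(self, params):
        x = np.array([10.0, 5.0, 500.0, 300.0, 25.0, 0.3])
        J = jacobian(x, 25.0, 0.3, params)
        assert np.diag(J)[:4] == pytest.approx(
            [-params.gLm, -params.gTm, -params.gLp, -params.gTp])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_central_differences(self, params, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 1, 6) * np.array([50, 15, 3000, 1000, 20, 0.8])
        J = jacobian(x, 30.0, 0.9, params)
        Jfd = np.empty((6, 6))
        for j in range(6):
            h = 1e-5 * max(1.0, x[j])
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            Jfd[:, j] = (toggle_rhs(xp, 30.0, 0.9, params)
                         - toggle_rhs(xm, 30.0, 0.9, params)) / (2 * h)
        assert J == pytest.approx(Jfd, rel=1e-5, abs=1e-8)

    def test_stable_equilibrium_spectrum(self, params):
        x = steady_state(params, 25.0, 0.0)
        J = jacobian(x, 25.0, 0.0, params)
        assert np.linalg.eigvals(J).real.max() < 0


class TestSteadyState:
    def test_residual_contract_and_inducer_equality(self, params):
        x = steady_state(params, 25.0, 0.3)
        assert np.linalg.norm(toggle_rhs(x, 25.0, 0.3, params)) < 1e-9
        assert x[4] == 25.0 and x[5] == 0.3

    def test_matches_long_ode_limit(self, params):
        x = steady_state(params, 25.0, 0.0)
        traj = simulate_ode(params, InputSchedule(aTc=25.0, IPTG=0.0),
                            np.array([1.0, 1, 10, 10, 25, 0.0]), 5000.0)
        assert traj.states[-1] == pytest.approx(x, rel=1e-4)

    def test_two_roots_in_bistable_window(self, params):
        lo = steady_state(params, 25.0, 0.3,
                          guess=np.array([50.0, 1.0, 3000.0, 70.0]))
        hi = steady_state(params, 25.0, 0.3,
                          guess=np.array([1.0, 15.0, 100.0, 1100.0]))
        assert abs(lo[3] - hi[3]) > 100

    def test_multistart_root_counts(self, params):
        assert len(find_equilibria(params, 25.0, 0.05)) == 1
        assert len(find_equilibria(params, 25.0, 0.30)) == 3


class TestContainers:
    def test_trajectory_round_trip(self, params, tmp_path):
        x0 = steady_state(params, 25.0, 0.0)
        traj = simulate_ode(params, InputSchedule(aTc=25.0, IPTG=0.2), x0, 50.0)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert back.states == pytest.approx(traj.states)
        assert back.inputs == pytest.approx(traj.inputs)

    def test_state_named_tuple(self):
        s = ToggleState(1, 2, 3, 4, 25, 0.1)
        assert ToggleState.from_array(s.as_array()) == s

    def test_schedule_lookup(self):
        sched = InputSchedule(aTc=[25.0, 30.0], IPTG=0.1, period=5.0)
        assert sched.at(0.0) == (25.0, 0.1)
        assert sched.at(5.0) == (30.0, 0.1)
        assert sched.at(500.0) == (30.0, 0.1)
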