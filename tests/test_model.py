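"""Core ODE model: vector field, conservation, simulation, observables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ulkswitch.model import (
    RATE_NAMES,
    RateConstants,
    SystemState,
    TotalLevels,
    Trajectory,
    apply_treatment,
    jacobian,
    load_params,
    rhs,
    save_params,
    simulate,
    steady_state,
    to_observables,
)

from conftest import random_rates


def symmetric_rates() -> RateConstants:
    return RateConstants(
        ka_m=1, ki_m=1, ka_u=1, ki_u=1, ka_p=1, ki_p=1,
        k_a=0, k_b=0, k_c=0, k_d=0, k_e=0, k_f=0,
    )


class TestVectorField:
    def test_empty_pools_produce_pure_activation(self, ref_rates):
        """At zero active form every sink vanishes: dx/dt = ka·XT."""
        totals = TotalLevels(mTORT=0.8, ULK1T=0.6, PP2AT=0.4)
        dm, du, dp = rhs(SystemState(0, 0, 0), ref_rates, totals)
        assert dm == pytest.approx(ref_rates.ka_m * totals.mTORT)
        assert du == pytest.approx(ref_rates.ka_u * totals.ULK1T)
        assert dp == pytest.approx(ref_rates.ka_p * totals.PP2AT)

    def test_fully_active_pools_can_only_decay(self, ref_rates):
        totals = TotalLevels()
        derivs = rhs(SystemState(1, 1, 1), ref_rates, totals)
        assert all(d <= 0 for d in derivs)

    def test_symmetric_uncoupled_balance(self):
        """Equal on/off rates with no coupling balance at half activation."""
        derivs = rhs(SystemState(0.5, 0.5, 0.5), symmetric_rates(), TotalLevels())
        assert derivs == pytest.approx((0.0, 0.0, 0.0), abs=1e-15)

    def test_rejects_non_finite_state(self, ref_rates):
        with pytest.raises(ValueError):
            rhs(SystemState(np.nan, 0.1, 0.1), ref_rates, TotalLevels())

    def test_jacobian_matches_finite_differences(self, ref_rates):
        state = SystemState(0.4, 0.3, 0.2)
        totals = TotalLevels(mTORT=0.9, ULK1T=0.8, PP2AT=0.7)
        J = jacobian(state, ref_rates, totals)
        h = 1e-6
        y0 = state.as_array()
        for j in range(3):
            plus = y0.copy()
            minus = y0.copy()
            plus[j] += h
            minus[j] -= h
            fd = (
                np.array(rhs(SystemState.from_array(plus), ref_rates, totals))
                - np.array(rhs(SystemState.from_array(minus), ref_rates, totals))
            ) / (2 * h)
            assert J[:, j] == pytest.approx(fd, abs=1e-6)


class TestDomainTypes:
    def test_exactly_twelve_free_rate_constants(self):
        assert len(RATE_NAMES) == 12
        r = symmetric_rates()
        assert r.as_array().shape == (12,)

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            symmetric_rates().replace(ka_m=0.0)  # basal rates must be > 0
        with pytest.raises(ValueError):
            symmetric_rates().replace(k_a=-1.0)

    def test_totals_validation(self):
        with pytest.raises(ValueError):
            TotalLevels(mTORT=0.0)
        with pytest.raises(ValueError):
            TotalLevels(PP2AT=1.5)

    def test_trajectory_requires_increasing_times(self):
        with pytest.raises(ValueError):
            Trajectory(times=np.array([0.0, 0.0, 1.0]), states=np.zeros((3, 3)))


class TestSimulate:
    def test_steady_start_stays_constant(self, ref_rates, phys_state):
        traj = simulate(
            phys_state, ref_rates, TotalLevels(), np.linspace(0, 500, 11)
        )
        assert np.allclose(traj.states, phys_state.as_array()[None, :], atol=1e-6)

    def test_rapamycin_flips_the_switch(self, ref_rates, phys_state):
        """Dropping the mTORC1 pool activates ULK1 and PP2A late in the hour."""
        totals = TotalLevels(mTORT=0.1)
        init = apply_treatment(phys_state, totals)
        traj = simulate(init, ref_rates, totals, np.arange(0.0, 241.0, 10.0))
        assert traj.u_act[-1] > phys_state.u_act
        assert traj.p_act[-1] > phys_state.p_act
        assert traj.m_act[-1] < phys_state.m_act

    def test_oa_leaves_ulk1_inactive(self, ref_rates, phys_state):
        """With PP2A depleted, mTORC1 keeps ULK1 phosphorylated."""
        totals = TotalLevels(PP2AT=0.1)
        init = apply_treatment(phys_state, totals)
        traj = simulate(init, ref_rates, totals, np.arange(0.0, 241.0, 10.0))
        assert traj.u_act[-1] <= phys_state.u_act + 1e-9
        assert traj.m_act[-1] > 0.5 * totals.mTORT

    def test_grid_must_start_at_zero(self, ref_rates, phys_state):
        with pytest.raises(ValueError):
            simulate(phys_state, ref_rates, TotalLevels(), [10.0, 20.0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_conservation_bounds_hold(self, data):
        """0 ≤ X_act ≤ XT at all output times, for random rates and starts."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        rates = random_rates(rng)
        totals = TotalLevels(*rng.uniform(0.05, 1.0, 3).tolist())
        frac = rng.uniform(0.0, 1.0, 3)
        init = SystemState.from_array(frac * totals.as_array())
        traj = simulate(init, rates, totals, np.linspace(0.0, 300.0, 31))
        assert np.all(traj.states >= -1e-7)
        assert np.all(traj.states <= totals.as_array()[None, :] + 1e-7)


class TestSteadyStates:
    def test_physiological_state_is_a_tight_fixed_point(self, ref_rates, phys_state):
        derivs = np.array(rhs(phys_state, ref_rates, TotalLevels()))
        assert np.linalg.norm(derivs) < 1e-8

    def test_physiological_state_is_non_autophagy(self, phys_state):
        assert phys_state.m_act > phys_state.u_act

    def test_matches_equilibrium_finder_root(self, ref_rates, phys_state):
        from ulkswitch.phaseplane import find_equilibria

        eqs = find_equilibria(ref_rates, TotalLevels())
        dists = [
            np.linalg.norm(e.state.as_array() - phys_state.as_array()) for e in eqs
        ]
        assert min(dists) < 1e-6

    def test_uncoupled_closed_form(self, uncoupled_rates):
        """Without coupling each steady fraction is ka/(ka+ki) exactly."""
        totals = TotalLevels(mTORT=0.7, ULK1T=0.5, PP2AT=0.9)
        ss = steady_state(
            uncoupled_rates, totals, SystemState(0, 0, 0)
        ).as_array()
        r = uncoupled_rates
        expected = np.array(
            [
                r.ka_m / (r.ka_m + r.ki_m) * totals.mTORT,
                r.ka_u / (r.ka_u + r.ki_u) * totals.ULK1T,
                r.ka_p / (r.ka_p + r.ki_p) * totals.PP2AT,
            ]
        )
        assert ss == pytest.approx(expected, abs=1e-6)

    def test_monotone_lever_response(self, ref_rates):
        """Steady ULK1 activity falls with mTORT and rises with PP2AT."""
        u_of_mtort = []
        for mt in [1.0, 0.7, 0.4, 0.2, 0.1]:
            totals = TotalLevels(mTORT=mt)
            ss = steady_state(
                ref_rates, totals, SystemState(totals.mTORT, 0.0, 0.0)
            )
            u_of_mtort.append(ss.u_act)
        assert all(
            b >= a - 1e-9 for a, b in zip(u_of_mtort, u_of_mtort[1:])
        )
        u_of_pp2at = []
        for pt in [0.05, 0.1, 0.3, 0.6, 1.0]:
            totals = TotalLevels(PP2AT=pt)
            ss = steady_state(
                ref_rates, totals, SystemState(totals.mTORT, 0.0, 0.0)
            )
            u_of_pp2at.append(ss.u_act)
        assert all(
            b >= a - 1e-9 for a, b in zip(u_of_pp2at, u_of_pp2at[1:])
        )


class TestObservables:
    def test_phospho_pool_complements(self, ref_rates):
        totals = TotalLevels()
        traj = Trajectory(
            times=np.array([0.0, 1.0]),
            states=np.array([[0.2, totals.ULK1T, 0.1], [0.3, 0.0, 0.2]]),
        )
        obs = to_observables(traj, totals)
        assert obs["ulk1_757P"][0] == pytest.approx(0.0)
        assert obs["ulk1_757P"][1] == pytest.approx(totals.ULK1T)
        assert np.allclose(obs["ulk1_757P"] + traj.u_act, totals.ULK1T)
        assert np.allclose(obs["pp2a_P"] + traj.p_act, totals.PP2AT)

    def test_rapamycin_dephosphorylates_all_three_readouts(
        self, ref_rates, phys_state
    ):
        totals = TotalLevels(mTORT=0.1)
        init = apply_treatment(phys_state, totals)
        traj = simulate(init, ref_rates, totals, np.arange(0.0, 61.0, 10.0))
        obs = to_observables(traj, totals)
        assert obs["ulk1_757P"][-1] < obs["ulk1_757P"][0]
        assert obs["pp2a_P"][-1] < obs["pp2a_P"][0]
        assert obs["p70S6K_P"][-1] < phys_state.m_act


class TestConfigIO:
    def test_roundtrip(self, tmp_path, ref_rates):
        path = tmp_path / "params.yaml"
        totals = TotalLevels(mTORT=0.5)
        save_params(path, ref_rates, totals, metadata={"note": "test"})
        rates2, totals2 = load_params(path)
        assert rates2 == ref_rates
        assert totals2 == totals

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("ka_m: 1.0\nnot_a_rate: 2.0\n")
        with pytest.raises(ValueError, match="unknown parameter"):
            load_params(path)
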