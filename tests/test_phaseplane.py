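"""Phase-plane reduction, balance curves, equilibria, stability."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ulkswitch.model import (
    SystemState,
    TotalLevels,
    rhs,
    steady_state,
)
from ulkswitch.phaseplane import (
    balance_curve,
    bifurcation_scan,
    classify_stability,
    find_equilibria,
    label_state,
    pp2a_qss,
)


class TestPP2AQuasiSteadyState:
    def test_uncoupled_limit_is_basal_balance(self, ref_rates):
        r = ref_rates.replace(k_d=0.0, k_f=0.0)
        totals = TotalLevels(PP2AT=0.8)
        expected = r.ka_p * totals.PP2AT / (r.ka_p + r.ki_p)
        for u, m in [(0.0, 0.0), (0.5, 0.9), (1.0, 0.2)]:
            assert pp2a_qss(u, m, r, totals) == pytest.approx(expected)

    def test_saturates_at_total_pool_for_large_ulk1(self, ref_rates):
        totals = TotalLevels()
        assert pp2a_qss(1e9, 0.5, ref_rates, totals) == pytest.approx(
            totals.PP2AT, rel=1e-6
        )

    def test_agrees_with_clamped_relaxation(self, ref_rates):
        """ODE oracle: integrate dp/dt alone at clamped (u, m) to t → ∞."""
        totals = TotalLevels()
        r = ref_rates
        for u, m in [(0.1, 0.8), (0.9, 0.05), (0.4, 0.4)]:
            def dp(_t, p):
                return (r.ka_p + r.k_d * u) * (totals.PP2AT - p) - (
                    r.ki_p + r.k_f * m
                ) * p

            sol = solve_ivp(dp, (0, 5e4), [0.0], rtol=1e-10, atol=1e-12)
            assert pp2a_qss(u, m, r, totals) == pytest.approx(
                sol.y[0, -1], abs=1e-7
            )


class TestBalanceCurves:
    def test_uncoupled_curves_are_straight_lines(self, uncoupled_rates):
        totals = TotalLevels()
        r = uncoupled_rates
        ulk1 = balance_curve("ULK1", r, totals, resolution=100)
        u_star = r.ka_u / (r.ka_u + r.ki_u) * totals.ULK1T
        assert np.allclose(ulk1.points[:, 1], u_star, atol=1e-9)
        mtor = balance_curve("mTORC1", r, totals, resolution=100)
        m_star = r.ka_m / (r.ka_m + r.ki_m) * totals.mTORT
        assert np.allclose(mtor.points[:, 0], m_star, atol=1e-9)

    def test_curves_pass_through_equilibria(self, ref_rates):
        """Every equilibrium lies on both balance curves."""
        totals = TotalLevels()
        eqs = find_equilibria(ref_rates, totals)
        curves = {
            w: balance_curve(w, ref_rates, totals, resolution=300).points
            for w in ("ULK1", "mTORC1")
        }
        for eq in eqs:
            pt = np.array([eq.state.m_act, eq.state.u_act])
            for w, pts in curves.items():
                d = np.min(np.linalg.norm(pts - pt[None, :], axis=1))
                assert d < 0.01, f"{w} curve misses equilibrium {pt}"

    def test_oa_shifts_ulk1_curve_left(self, ref_rates):
        """Partial PP2A loss lowers the ULK1 nullcline at every mTORC1 level."""
        c_phys = balance_curve("ULK1", ref_rates, TotalLevels(), resolution=120)
        c_oa = balance_curve(
            "ULK1", ref_rates, TotalLevels(PP2AT=0.3), resolution=120
        )

        def max_u_by_m(curve):
            out = {}
            for m, u in curve.points:
                key = round(m, 9)
                out[key] = max(out.get(key, 0.0), u)
            return out

        u_phys, u_oa = max_u_by_m(c_phys), max_u_by_m(c_oa)
        common = sorted(set(u_phys) & set(u_oa))
        assert len(common) >= 100
        assert all(u_oa[m] < u_phys[m] for m in common)

    def test_resolution_floor(self, ref_rates):
        with pytest.raises(ValueError):
            balance_curve("ULK1", ref_rates, TotalLevels(), resolution=50)


class TestEquilibria:
    def test_all_roots_are_tight(self, ref_rates):
        for totals in (TotalLevels(), TotalLevels(mTORT=0.1), TotalLevels(PP2AT=0.3)):
            for eq in find_equilibria(ref_rates, totals):
                assert np.linalg.norm(rhs(eq.state, ref_rates, totals)) < 1e-9

    def test_enumeration_invariant_to_seeding_density(self, ref_rates):
        """Counts are stable from coarse grids up to a 200×200 seeding."""
        for totals in (TotalLevels(), TotalLevels(PP2AT=0.3)):
            counts = {
                res: len(find_equilibria(ref_rates, totals, seed_resolution=res))
                for res in (20, 45, 200)
            }
            assert len(set(counts.values())) == 1, counts

    def test_forward_simulation_lands_on_an_enumerated_equilibrium(
        self, ref_rates
    ):
        totals = TotalLevels()
        states = np.array(
            [e.state.as_array() for e in find_equilibria(ref_rates, totals)]
        )
        for corner in [(0, 0, 0), (1, 0, 0), (0, 1, 1), (1, 1, 1)]:
            ss = steady_state(
                ref_rates, totals, SystemState(*[float(c) for c in corner])
            )
            assert np.min(
                np.linalg.norm(states - ss.as_array()[None, :], axis=1)
            ) < 1e-6


class TestStability:
    def test_uncoupled_eigenvalues_are_basal_turnover_rates(self, uncoupled_rates):
        totals = TotalLevels()
        eqs = find_equilibria(uncoupled_rates, totals)
        assert len(eqs) == 1
        stability, eigs, marginal = classify_stability(
            eqs[0].state, uncoupled_rates, totals
        )
        r = uncoupled_rates
        expected = sorted(
            [-(r.ka_m + r.ki_m), -(r.ka_u + r.ki_u), -(r.ka_p + r.ki_p)]
        )
        assert sorted(e.real for e in eigs) == pytest.approx(expected)
        assert stability == "stable" and not marginal

    def test_middle_equilibrium_is_the_unstable_one(self, ref_rates):
        eqs = find_equilibria(ref_rates, TotalLevels())
        eqs = sorted(eqs, key=lambda e: e.state.u_act)
        assert [e.stability for e in eqs] == ["stable", "unstable", "stable"]


class TestLabels:
    @pytest.mark.parametrize(
        "m_frac,u_frac,expected",
        [
            (0.9, 0.05, "non-autophagy"),
            (0.05, 0.9, "autophagy"),
            (0.5, 0.5, "non-autophagy"),  # tie breaks to non-autophagy
        ],
    )
    def test_label_by_active_fractions(self, m_frac, u_frac, expected):
        totals = TotalLevels(mTORT=0.4, ULK1T=0.8)
        state = SystemState(m_frac * totals.mTORT, u_frac * totals.ULK1T, 0.1)
        assert label_state(state, totals) == expected

    def test_rapamycin_equilibrium_is_autophagy(self, ref_rates):
        eqs = find_equilibria(ref_rates, TotalLevels(mTORT=0.1))
        assert len(eqs) == 1 and eqs[0].label == "autophagy"


class TestBifurcationScan:
    def test_mtort_scan_matches_figure_panels(self, ref_rates):
        table = bifurcation_scan("mTORT", [1.0, 0.1], ref_rates)
        assert table.loc[table.lever_value == 1.0, "n_equilibria"].item() == 3
        assert table.loc[table.lever_value == 0.1, "n_equilibria"].item() == 1

    def test_pp2at_0p3_keeps_two_stable_states(self, ref_rates):
        table = bifurcation_scan("PP2AT", [0.3], ref_rates)
        assert table.n_stable.item() == 2

    def test_saddle_nodes_change_count_by_two(self, ref_rates):
        """Along a fine mTORT scan the equilibrium count jumps in twos."""
        values = np.linspace(1.0, 0.05, 40)
        table = bifurcation_scan("mTORT", values, ref_rates)
        diffs = np.diff(table.n_equilibria.to_numpy())
        assert set(np.abs(diffs)) <= {0, 2}
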