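"""Cascade model: rate laws, conservation, integration, steady states."""

import numpy as np
import pytest

from erkpop import cascade as cas
from erkpop.cascade import (CascadeState, KineticParameters, ProteinTotals,
                            feedback_gain, ode_rhs, reaction_rates,
                            simulate_timecourse, steady_state,
                            sweep_steady_states)


def oracle_rates(y, ras, p):
    """Straight-line transcription of the published rate table (per second)."""
    M3K, pM3K, M2K, pM2K, ppM2K, MK, pMK, ppMK = y
    g = (1 + p.Fa * (ppMK / p.Ka) ** 2) / (1 + (ppMK / p.Ka) ** 2)
    return np.array([
        p.k1cat * ras * (M3K / p.Km1) / (1 + M3K / p.Km1) * g,
        p.Vmax2 * (pM3K / p.Km2) / (1 + pM3K / p.Km2),
        p.k3cat * pM3K * (M2K / p.Km3) / (1 + M2K / p.Km3 + pM2K / p.Km4),
        p.k4cat * pM3K * (pM2K / p.Km4) / (1 + M2K / p.Km3 + pM2K / p.Km4),
        p.Vmax5 * (ppM2K / p.Km5) / (1 + ppM2K / p.Km5 + pM2K / p.Km6 + M2K / p.Ki1),
        p.Vmax6 * (pM2K / p.Km6) / (1 + ppM2K / p.Km5 + pM2K / p.Km6 + M2K / p.Ki1),
        p.k7cat * ppM2K * (MK / p.Km7) / (1 + MK / p.Km7 + pMK / p.Km8),
        p.k8cat * ppM2K * (pMK / p.Km8) / (1 + MK / p.Km7 + pMK / p.Km8),
        p.Vmax9 * (ppMK / p.Km9) / (1 + ppMK / p.Km9 + pMK / p.Km10 + MK / p.Ki2),
        p.Vmax10 * (pMK / p.Km10) / (1 + ppMK / p.Km9 + pMK / p.Km10 + MK / p.Ki2),
    ])


def random_state(rng, totals):
    """Random conservation-respecting state."""
    f3 = rng.dirichlet(np.ones(2)) * totals.MAP3K_total
    f2 = rng.dirichlet(np.ones(3)) * totals.MAP2K_total
    fk = rng.dirichlet(np.ones(3)) * totals.MAPK_total
    return np.concatenate([f3, f2, fk])


class TestFeedbackGain:
    @pytest.mark.parametrize("fa", [0.5, 1.0, 5.0])
    def test_no_active_erk_gives_unit_gain(self, fa):
        assert feedback_gain(0.0, KineticParameters(Fa=fa)) == 1.0

    def test_fa_one_is_identically_one(self):
        p = KineticParameters(Fa=1.0)
        for x in (0.0, 17.3, 100.0, 1e4):
            assert feedback_gain(x, p) == pytest.approx(1.0)

    def test_half_saturation_point(self):
        # at ppMAPK = Ka the gain is (1 + Fa)/2
        assert feedback_gain(100.0, KineticParameters(Fa=5.0)) == pytest.approx(3.0)

    def test_asymptote_is_fa(self):
        assert feedback_gain(1e9, KineticParameters(Fa=0.5)) == pytest.approx(0.5, abs=1e-6)

    def test_bounded_and_monotone(self):
        x = np.linspace(0, 1000, 200)
        for fa in (0.5, 5.0):
            p = KineticParameters(Fa=fa)
            g = np.array([feedback_gain(v, p) for v in x])
            assert np.all(g >= min(1, fa) - 1e-12) and np.all(g <= max(1, fa) + 1e-12)
            dg = np.diff(g)
            assert np.all(dg >= -1e-12) if fa > 1 else np.all(dg <= 1e-12)

    def test_negative_ppmapk_rejected(self):
        with pytest.raises(ValueError):
            feedback_gain(-1.0, KineticParameters())


class TestReactionRates:
    def test_dephosphorylation_half_saturation(self, totals):
        # pMAP3K = Km2 -> v2 = Vmax2/2 = 2.5 nM/s with defaults
        p = KineticParameters()
        y = [10.0, 50.0, totals.MAP2K_total, 0, 0, totals.MAPK_total, 0, 0]
        v = reaction_rates(y, 10.0, p)
        assert v[1] == pytest.approx(2.5)

    def test_no_ras_no_first_step(self, totals):
        v = reaction_rates(CascadeState.unphosphorylated(totals), 0.0, KineticParameters())
        assert v[0] == 0.0

    def test_hand_evaluated_first_rate(self, totals):
        # fully dephosphorylated, RasGTP = 50 nM, defaults (Fa=1 -> g=1):
        # v1 = 0.2 * 50 * (40/50) / (1 + 40/50) = 8/1.8
        v = reaction_rates(CascadeState.unphosphorylated(totals), 50.0, KineticParameters())
        assert v[0] == pytest.approx(0.2 * 50 * 0.8 / 1.8, rel=1e-12)

    def test_rates_nonnegative(self, totals):
        rng = np.random.default_rng(4)
        p = KineticParameters.for_topology("PF")
        for _ in range(20):
            v = reaction_rates(random_state(rng, totals), rng.uniform(0, 100), p)
            assert np.all(v >= 0)

    def test_matches_independent_oracle(self, totals):
        rng = np.random.default_rng(7)
        for fa in (0.5, 1.0, 5.0):
            p = KineticParameters(Fa=fa)
            for _ in range(34):
                y = random_state(rng, totals)
                ras = rng.uniform(0, 200)
                np.testing.assert_allclose(reaction_rates(y, ras, p),
                                           oracle_rates(y, ras, p), rtol=1e-12)


class TestOdeRhs:
    def test_conservation_is_algebraic(self, totals, nf_params):
        rng = np.random.default_rng(1)
        for _ in range(10):
            d = ode_rhs(random_state(rng, totals), rng.uniform(0, 100), nf_params)
            assert d[0] + d[1] == pytest.approx(0.0, abs=1e-12)
            assert d[2] + d[3] + d[4] == pytest.approx(0.0, abs=1e-10)
            assert d[5] + d[6] + d[7] == pytest.approx(0.0, abs=1e-10)

    def test_rhs_is_sixty_times_rate_balance(self, totals, nf_params):
        rng = np.random.default_rng(2)
        y = random_state(rng, totals)
        v = oracle_rates(y, 30.0, nf_params)
        d = ode_rhs(y, 30.0, nf_params)
        expect = 60.0 * np.array([v[1] - v[0], v[0] - v[1], v[5] - v[2],
                                  v[2] + v[4] - v[3] - v[5], v[3] - v[4],
                                  v[9] - v[6], v[6] + v[8] - v[7] - v[9],
                                  v[7] - v[8]])
        np.testing.assert_allclose(d, expect, rtol=1e-12)

    def test_rhs_vanishes_at_steady_state(self, totals, nf_params):
        ss = steady_state(40.0, totals, nf_params)
        assert np.max(np.abs(ode_rhs(ss.as_array(), 40.0, nf_params))) < 1e-9


class TestTimecourse:
    def test_no_stimulus_no_activation(self, totals, nf_params):
        tr = simulate_timecourse(totals, nf_params, lambda t: 0.0, np.linspace(0, 30, 7))
        assert np.all(tr.ppMAPK < 1e-9)

    def test_conservation_along_trajectory(self, totals, nf_params, schedule):
        from erkpop.ras_input import fit_for_dose

        tr = simulate_timecourse(totals, nf_params, fit_for_dose(schedule, 5),
                                 np.linspace(0, 30, 31))
        assert cas.conservation_error(tr.y, totals) < 1e-6
        assert np.all(tr.y >= 0)
        assert np.all(tr.ppMAPK <= totals.MAPK_total * (1 + 1e-9))

    def test_constant_input_relaxes_to_steady_state(self, totals, nf_params):
        from erkpop.ras_input import RasInputParameters

        const = RasInputParameters(K1=0.0, K2=0.0, tau1=1.0, tau2=1.0, Io=35.0)
        tr = simulate_timecourse(totals, nf_params, const, [0.0, 60.0, 120.0])
        ss = steady_state(35.0, totals, nf_params)
        np.testing.assert_allclose(tr.y[-1], ss.as_array(), rtol=1e-5, atol=1e-6)

    def test_two_integrators_agree(self, totals, nf_params, schedule):
        from scipy.integrate import solve_ivp

        from erkpop.ras_input import evaluate, fit_for_dose

        ras = fit_for_dose(schedule, 4)
        t_grid = np.array([0.0, 2, 5, 10, 30])
        tr = simulate_timecourse(totals, nf_params, ras, t_grid)
        sol = solve_ivp(lambda t, y: ode_rhs(y, evaluate(ras, t), nf_params),
                        (0, 30), CascadeState.unphosphorylated(totals).as_array(),
                        t_eval=t_grid, method="Radau", rtol=1e-10, atol=1e-12)
        assert sol.success
        # agreement to 4 significant figures on the dominant output scale
        np.testing.assert_allclose(tr.ppMAPK, sol.y[7], rtol=2e-4,
                                   atol=1e-4 * totals.MAPK_total)

    def test_bad_grid_rejected(self, totals, nf_params):
        with pytest.raises(ValueError):
            simulate_timecourse(totals, nf_params, lambda t: 0.0, [1.0, 2.0])
        with pytest.raises(ValueError):
            simulate_timecourse(totals, nf_params, lambda t: 0.0, [0.0, 2.0, 2.0])


class TestSteadyState:
    def test_zero_input_stays_unphosphorylated(self, totals, nf_params):
        ss = steady_state(0.0, totals, nf_params)
        np.testing.assert_allclose(ss.as_array(),
                                   CascadeState.unphosphorylated(totals).as_array(),
                                   atol=1e-6)

    def test_pf_has_two_states_at_intermediate_input(self, totals, pf_params):
        lo = steady_state(10.0, totals, pf_params)  # from rest
        # approach the same input from the fully-activated branch
        high = steady_state(100.0, totals, pf_params)
        hi = steady_state(10.0, totals, pf_params, initial=high)
        assert hi.ppMAPK - lo.ppMAPK > 50.0

    def test_nf_state_is_unique(self, totals, nf_params):
        lo = steady_state(30.0, totals, nf_params)
        high = steady_state(100.0, totals, nf_params)
        hi = steady_state(30.0, totals, nf_params, initial=high)
        assert abs(hi.ppMAPK - lo.ppMAPK) < 1e-3

    def test_nf_monotone_and_thresholded(self, totals, nf_params):
        grid = np.arange(0.0, 101.0, 5.0)
        pp = sweep_steady_states(grid, totals, nf_params)[:, 7]
        assert np.all(np.diff(pp) >= -1e-6)
        # activation threshold: ppERK below 1% of the ERK pool at low RasGTP
        assert pp[grid <= 5.0].max() < 0.01 * totals.MAPK_total
        assert pp[-1] > 0.5 * totals.MAPK_total

    def test_us_monotone(self, totals):
        us = KineticParameters.for_topology("US")
        grid = np.arange(0.0, 101.0, 10.0)
        pp = sweep_steady_states(grid, totals, us)[:, 7]
        assert np.all(np.diff(pp) >= -1e-6)

    def test_initial_state_must_conserve(self, totals, nf_params):
        bad = CascadeState(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            steady_state(10.0, totals, nf_params, initial=bad)


class TestParameterContainers:
    def test_defaults_match_published_constants(self):
        p = KineticParameters()
        expected = dict(k1cat=0.2, Km1=50, Vmax2=5, Km2=50, k3cat=1, Km3=130,
                        k4cat=5, Km4=50, Vmax5=250, Km5=100, Vmax6=250, Km6=100,
                        Ki1=80, k7cat=1, Km7=50, k8cat=20, Km8=50, Vmax9=380,
                        Km9=10, Vmax10=50, Km10=18, Ki2=100, Ka=100)
        for name, val in expected.items():
            assert getattr(p, name) == val

    def test_topology_fa_mapping(self):
        assert KineticParameters.for_topology("PF").Fa == 5.0
        assert KineticParameters.for_topology("US").Fa == 1.0
        assert KineticParameters.for_topology("NF").Fa == 0.5
        with pytest.raises(ValueError):
            KineticParameters.for_topology("XX")

    def test_screening_vector_roundtrip_excludes_fa(self):
        p = KineticParameters.for_topology("PF")
        vec = p.screening_vector()
        assert len(vec) == 23
        q = KineticParameters.from_screening_vector(vec, Fa=0.5)
        assert q.screening_vector().tolist() == vec.tolist()
        assert q.Fa == 0.5

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            KineticParameters(k1cat=0.0)
        with pytest.raises(ValueError):
            ProteinTotals(MAPK_total=-5.0)
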