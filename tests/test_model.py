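import numpy as np
import pytest

from _oracles import (
    random_admissible_state,
    stoichiometry_rhs,
    ubiquitination_rate_literal,
)
from pias3net import (
    InputSchedule,
    find_steady_state,
    rhs,
    simulate,
    ubiquitination_rate,
    ubiquitination_terms,
)
from pias3net.model import (
    SIdx,
    STATE_NAMES,
    SolverSettings,
    default_initial_state,
    mitf_pias3_complex,
    total_mitf,
    total_pias3,
    total_stat3,
)


def _zero_turnover(params):
    """No production, degradation or ubiquitination: a closed system."""
    return params.replace(
        p_MITF=0, p_PIAS3=0, p_STAT3=0,
        gamma_MITF=0, gamma_MITFp73=0, gamma_MITFp409=0,
        gamma_PIAS3=0, gamma_STAT3=0, k_u=0)


class TestRhs:
    def test_matches_stoichiometry_oracle_on_random_states(self, params, rng):
        """The packed derivative equals an independent S x v assembly."""
        sched = InputSchedule.resting(params)
        for _ in range(100):
            y = random_admissible_state(rng)
            erkp = rng.uniform(10, 1000)
            jakp = rng.uniform(10, 1000)
            expected = stoichiometry_rhs(y, params, erkp, jakp)
            got = rhs(0.0, y, params, InputSchedule.constant(erkp, jakp))
            scale = np.maximum(np.abs(expected), 1e-12)
            assert np.all(np.abs(got - expected) / scale < 1e-9)
        del sched

    def test_all_zero_state_only_production_survives(self, params):
        """Only the three production terms and the ubiquitination gain
        (which tags at rate ERKp * k_u even when the pools are empty)
        survive at the empty state."""
        y = np.zeros(len(STATE_NAMES))
        d = rhs(0.0, y, params, InputSchedule.resting(params))
        assert d[SIdx.MITF] == pytest.approx(params.p_MITF)
        assert d[SIdx.PIAS3] == pytest.approx(params.p_PIAS3)
        assert d[SIdx.STAT3] == pytest.approx(params.p_STAT3)
        assert d[SIdx.R] == pytest.approx(params.ERKp_baseline * params.k_u)
        others = [j for j in range(len(STATE_NAMES))
                  if j not in (SIdx.MITF, SIdx.PIAS3, SIdx.STAT3, SIdx.R)]
        assert np.all(d[others] == 0.0)

    def test_rsk1_pool_derivative_cancels_exactly(self, params, rng):
        sched = InputSchedule.resting(params)
        for _ in range(20):
            y = random_admissible_state(rng, max_amount=400)
            d = rhs(0.0, y, params, sched)
            assert d[SIdx.RSK1] + d[SIdx.RSK1p] == 0.0


class TestUbiquitination:
    def test_untagged_pool_only_gains(self, params, rng):
        """At R=0 the depletion and dilution terms vanish identically."""
        y = random_admissible_state(rng)
        y[SIdx.R] = 0.0
        t = ubiquitination_terms(y, params, erkp=500.0)
        assert t["term_ii"] == 0.0
        assert t["term_iii"] == 0.0
        assert ubiquitination_rate(y, params, 500.0) == pytest.approx(
            500.0 * params.k_u)

    def test_fully_tagged_pool_gains_nothing(self, params, rng):
        y = random_admissible_state(rng)
        y[SIdx.R] = 1.0
        assert ubiquitination_terms(y, params, 500.0)["term_i"] == 0.0

    def test_singularity_free_form_matches_printed_ratios(self, params, rng):
        """The regularized update equals the literal one-minute ratio forms."""
        for _ in range(200):
            y = random_admissible_state(rng)
            erkp = rng.uniform(10, 1200)
            assert ubiquitination_rate(y, params, erkp) == pytest.approx(
                ubiquitination_rate_literal(y, params, erkp), abs=1e-10)

    def test_dilution_ratio_bounds_and_unit_constant(self, params, rng):
        y = random_admissible_state(rng)
        t = ubiquitination_terms(y, params, erkp=10.0)
        assert t["a"] == 1.0
        assert 0.0 <= t["A"] <= 1.0
        assert t["term_i"] >= 0.0

    def test_negative_influx_clamped_keeps_r_bounded(self, params):
        """A huge S409 pool cannot push the dilution ratio above one."""
        y = np.zeros(len(STATE_NAMES))
        y[SIdx.MITFp73] = 5.0
        y[SIdx.MITFp409] = 5000.0  # gamma_MITFp409 * 5000 >> p_MITF
        y[SIdx.R] = 0.5
        t = ubiquitination_terms(y, params, erkp=10.0)
        assert t["A"] == 1.0
        assert t["term_iii"] == 0.0


class TestConservation:
    def test_rsk1_total_constant_along_trajectory(self, params, resting_state):
        traj = simulate(params, InputSchedule.constant(1000, 10),
                        resting_state, 120.0)
        totals = traj.y[:, SIdx.RSK1] + traj.y[:, SIdx.RSK1p]
        assert np.allclose(totals, totals[0], rtol=1e-9, atol=0)

    def test_closed_system_totals_conserved(self, params, resting_state):
        p = _zero_turnover(params)
        traj = simulate(p, InputSchedule.constant(200, 200),
                        resting_state, 1000.0)
        for total in (total_mitf, total_pias3, total_stat3):
            series = total(traj.y)
            assert np.all(np.abs(series / series[0] - 1) < 1e-6)

    def test_binding_equilibria_reach_mass_action_ratio(self, params):
        """With only binding active, each complex satisfies k_ass/k_diss."""
        p = _zero_turnover(params).replace(
            k_Mp73E_plus=0, k_Mp73a_plus=0, k_Mp73_minus=0,
            k_Mp409_plus=0, k_Mp409_minus=0,
            k_Sp_plus=0, k_Sp_minus=0, k_Rp_plus=0, k_Rp_minus=0)
        y0 = np.zeros(len(STATE_NAMES))
        for name in ("MITF", "MITFp73", "MITFp409", "MITFpp", "STAT3p"):
            y0[STATE_NAMES.index(name)] = 50.0
        y0[SIdx.PIAS3] = 100.0
        traj = simulate(p, InputSchedule.resting(p), y0, 5000.0,
                        t_eval=[5000.0])
        y = traj.final_state
        pairs = [
            ("MITF", "PIAS3_MITF", p.k_Mass / p.k_Mdiss),
            ("MITFp73", "PIAS3_MITFp73", p.k_Mp73ass / p.k_Mp73diss),
            ("MITFp409", "PIAS3_MITFp409", p.k_Mp409ass / p.k_Mp409diss),
            ("MITFpp", "PIAS3_MITFpp", p.k_Mppass / p.k_Mppdiss),
            ("STAT3p", "PIAS3_STAT3p", p.k_Spass / p.k_Spdiss),
        ]
        free_p = y[SIdx.PIAS3]
        for free, cplx, kd_inv in pairs:
            ratio = y[STATE_NAMES.index(cplx)] / (
                y[STATE_NAMES.index(free)] * free_p)
            assert ratio == pytest.approx(kd_inv, rel=1e-3)


class TestSimulate:
    def test_rsk1_resting_fraction_closed_form(self, params, resting_state):
        # at baseline ERKp the isolated RSK1 cycle has the exact solution
        # RSK1p / total = k+ E / (k+ E + k-) = 0.004 / 0.044
        frac = resting_state[SIdx.RSK1p] / params.RSK1_total
        assert frac == pytest.approx(0.004 / 0.044, rel=1e-5)

    def test_deterministic_repeat_is_bitwise_identical(self, params, resting_state):
        kw = dict(duration=200.0, settings=SolverSettings(report_step=5.0))
        sched = InputSchedule.constant(950, 950)
        t1 = simulate(params, sched, resting_state, **kw)
        t2 = simulate(params, sched, resting_state, **kw)
        assert np.array_equal(t1.y, t2.y)
        assert np.array_equal(t1.t, t2.t)

    def test_first_state_equals_initial_and_time_increases(self, params):
        y0 = default_initial_state(params)
        traj = simulate(params, InputSchedule.resting(params), y0, 50.0)
        assert np.array_equal(traj.y[0], y0)
        assert np.all(np.diff(traj.t) > 0)

    def test_schedule_step_honoured(self, params, resting_state):
        sched = InputSchedule.resting(params).with_step(30.0, 1000.0, 10.0)
        traj = simulate(params, sched, resting_state, 60.0)
        # before the step RSK1p stays at rest; after, it rises sharply
        rkp = traj.column("RSK1p")
        pre = rkp[traj.t <= 30.0]
        assert np.all(np.abs(pre - pre[0]) < 1.0)
        assert rkp[-1] > 5 * pre[0]

    def test_invalid_duration_rejected(self, params, resting_state):
        with pytest.raises(ValueError):
            simulate(params, InputSchedule.resting(params), resting_state, 0.0)

    def test_complex_rises_then_falls_on_activation(self, params, resting_state):
        """Transient MITF-PIAS3 complex accumulation under moderate input."""
        traj = simulate(params, InputSchedule.constant(500, 50),
                        resting_state, 30.0)
        c = mitf_pias3_complex(traj.values)
        assert c[10] > c[0] and c[-1] < c[10]


class TestSteadyState:
    def test_residual_below_tolerance(self, params, resting_state):
        d = rhs(0.0, resting_state, params, InputSchedule.resting(params))
        assert np.max(np.abs(d) / (np.abs(resting_state) + 1)) < 1e-6

    def test_no_phosphorylation_source_means_no_phospho_stat3(self, params):
        p = params.replace(k_Sp_plus=0.0)
        ss = find_steady_state(p)
        assert ss[SIdx.STAT3p] == pytest.approx(0.0, abs=1e-6)
        assert ss[SIdx.PIAS3_STAT3p] == pytest.approx(0.0, abs=1e-6)

    def test_resting_totals_roughly_equimolar(self, resting_state):
        totals = [total_mitf(resting_state), total_pias3(resting_state),
                  total_stat3(resting_state)]
        assert all(t > 0 for t in totals)
        assert max(totals) / min(totals) < 10.0


class TestInputSchedule:
    def test_levels_piecewise_constant(self):
        s = InputSchedule(((0.0, 10.0, 10.0), (30.0, 1000.0, 10.0)))
        assert s.levels(0.0) == (10.0, 10.0)
        assert s.levels(29.999) == (10.0, 10.0)
        assert s.levels(30.0) == (1000.0, 10.0)

    def test_decreasing_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            InputSchedule(((10.0, 1.0, 1.0), (5.0, 1.0, 1.0)))

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            InputSchedule(((0.0, -1.0, 10.0),))

    def test_time_before_domain_rejected(self):
        with pytest.raises(ValueError):
            InputSchedule(((5.0, 1.0, 1.0),)).levels(0.0)
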