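"""Markov engine: matrix assembly, treatment effects, trace and accumulation."""

import copy

import numpy as np
import pytest

from eipcea import (
    DistributionSpec,
    HealthState,
    LifeTable,
    accumulate_outcomes,
    apply_treatment_effect,
    build_transition_matrix,
    microsimulate_cohort,
    run_cohort,
    run_strategy,
)
from eipcea.markov import ModelDraw, CohortTrace
from eipcea.params import ALIVE_STATES, N_STATES, ValidationError, discount_factor
from eipcea.psa import sample_parameters


class TestApplyTreatmentEffect:
    def test_identity_at_rr_one(self):
        row = np.array([0.3, 0.4, 0.0, 0.0, 0.0, 0.3])
        out = apply_treatment_effect(row, 1.0, HealthState.REMISSION)
        assert np.allclose(out, row)

    def test_hand_renormalized_example(self):
        # remission 0.4 scaled by 1.25 -> 0.5; the remaining 0.6 shrinks to 0.5
        row = np.zeros(N_STATES)
        row[HealthState.REMISSION] = 0.4
        row[HealthState.ACUTE] = 0.6
        out = apply_treatment_effect(row, 1.25, HealthState.REMISSION)
        assert out[HealthState.REMISSION] == pytest.approx(0.5)
        assert out[HealthState.ACUTE] == pytest.approx(0.5)
        assert out.sum() == pytest.approx(1.0)

    def test_rr_zero_returns_mass_proportionally(self):
        row = np.zeros(N_STATES)
        row[HealthState.RELAPSE] = 0.2
        row[HealthState.REMISSION] = 0.6
        row[HealthState.PNS] = 0.2
        out = apply_treatment_effect(row, 0.0, HealthState.RELAPSE)
        assert out[HealthState.RELAPSE] == 0.0
        assert out[HealthState.REMISSION] == pytest.approx(0.75)
        assert out[HealthState.PNS] == pytest.approx(0.25)

    def test_capping_counts_events(self):
        row = np.zeros(N_STATES)
        row[HealthState.REMISSION] = 0.8
        row[HealthState.ACUTE] = 0.2
        caps = []
        out = apply_treatment_effect(row, 2.0, HealthState.REMISSION, caps)
        assert out[HealthState.REMISSION] == 1.0
        assert out.sum() == pytest.approx(1.0)
        assert len(caps) == 1


class TestBuildTransitionMatrix:
    def test_rows_stochastic_and_mask_respected(self, reference_params, reference_draw):
        from eipcea.params import DEFAULT_ADJACENCY

        for strat in ("eip", "cmht"):
            M = build_transition_matrix(reference_params, reference_draw, strat, 0)
            assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert np.all((M >= 0) & (M <= 1))
            for s in ALIVE_STATES:
                allowed = {int(t) for t in DEFAULT_ADJACENCY[s]} | {int(HealthState.DEAD)}
                for j in range(N_STATES):
                    if j not in allowed:
                        assert M[s, j] == 0.0

    def test_dead_row_is_absorbing(self, reference_params, reference_draw):
        M = build_transition_matrix(reference_params, reference_draw, "cmht", 17)
        expected = np.zeros(N_STATES)
        expected[HealthState.DEAD] = 1.0
        assert np.array_equal(M[HealthState.DEAD], expected)

    def test_zero_mortality_gives_zero_death_column(self, reference_params, reference_draw):
        params = copy.deepcopy(reference_params)
        params.life_table = LifeTable(np.array([0]), np.array([0.0]))
        M = build_transition_matrix(params, reference_draw, "cmht", 0)
        assert np.all(M[: HealthState.DEAD, HealthState.DEAD] == 0.0)

    def test_matrix_matches_independent_hand_assembly(self, reference_params, reference_draw):
        """Cycle-0 matrix equals one assembled from scratch outside the engine."""
        import math

        params, draw = reference_params, reference_draw
        lt = params.life_table
        M = build_transition_matrix(params, draw, "eip", 0)
        rate = lt.rate(params.start_age)
        cl = params.economics.cycle_length_years
        specs = params.strategy_transitions("eip")
        for s in ALIVE_STATES:
            hr = params.mortality_hazard_ratio[s.name].mean()
            p_death = 1.0 - math.exp(-rate * hr * cl)
            shares = {t: spec.mean() for t, spec in specs[s.name].items()}
            if s is HealthState.ACUTE:  # remission effect
                rr = params.treatment_effect.rr_remission.mean()
                newp = min(rr * shares["REMISSION"], 1.0)
                rest = 1.0 - shares["REMISSION"]
                shares = {
                    t: (newp if t == "REMISSION" else v * (1 - newp) / rest)
                    for t, v in shares.items()
                }
            if s is HealthState.REMISSION:  # relapse effect
                rr = params.treatment_effect.rr_relapse.mean()
                newp = min(rr * shares["RELAPSE"], 1.0)
                rest = 1.0 - shares["RELAPSE"]
                shares = {
                    t: (newp if t == "RELAPSE" else v * (1 - newp) / rest)
                    for t, v in shares.items()
                }
            assert M[s, HealthState.DEAD] == pytest.approx(p_death, abs=1e-12)
            for t, v in shares.items():
                assert M[s, HealthState[t]] == pytest.approx(
                    (1 - p_death) * v, abs=1e-12
                ), f"{s.name}->{t}"

    def test_overfull_row_rejected(self, reference_params, reference_draw):
        draw = copy.deepcopy(reference_draw)
        draw.shares["cmht"][HealthState.ACUTE] *= 2.5
        with pytest.raises(ValidationError, match="ACUTE"):
            build_transition_matrix(reference_params, draw, "cmht", 0)


class TestRunCohort:
    def test_dimensions_for_ten_year_quarterly_horizon(self, reference_params, reference_draw):
        trace = run_cohort(reference_params, reference_draw, "eip")
        assert trace.occupancy.shape == (41, 6)  # 40 transitions + start row
        assert trace.times[-1] == pytest.approx(10.0)

    def test_trace_conservation_and_monotone_death(self, reference_params, reference_draw):
        for strat in ("eip", "cmht"):
            trace = run_cohort(reference_params, reference_draw, strat)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(trace.occupancy >= 0)
            dead = trace.occupancy[:, HealthState.DEAD]
            assert np.all(np.diff(dead) >= -1e-15)

    def test_identity_dynamics_is_fixed_point(self, reference_params):
        """With no movement or mortality, the trace stays at the start row."""
        params = copy.deepcopy(reference_params)
        params.life_table = LifeTable(np.array([0]), np.array([0.0]))
        fixed = lambda v: DistributionSpec(kind="fixed", parameters=[v])
        stay = {
            "ACUTE": {"ACUTE": 1.0, "REMISSION": 0.0, "RESISTANT": 0.0, "PNS": 0.0},
            "REMISSION": {"REMISSION": 1.0, "RELAPSE": 0.0, "PNS": 0.0},
            "RELAPSE": {"RELAPSE": 1.0, "REMISSION": 0.0, "RESISTANT": 0.0},
            "RESISTANT": {"RESISTANT": 1.0, "REMISSION": 0.0},
            "PNS": {"PNS": 1.0, "RELAPSE": 0.0},
        }
        params.transitions = {
            "cmht": {f: {t: fixed(v) for t, v in row.items()} for f, row in stay.items()}
        }
        params.transition_dirichlet = {}
        draw = ModelDraw.from_point_estimates(params)
        draw.rr_remission = 1.0
        draw.rr_relapse = 1.0
        trace = run_cohort(params, draw, "eip")
        assert np.allclose(trace.occupancy, trace.occupancy[0], atol=1e-12)

    @staticmethod
    def _microsim_se(params, draw, strat, n_agents):
        """Exact per-cycle SEs of microsimulated occupancy proportions.

        Propagates the multinomial count covariance through the chain:
        V_{t+1} = sum_s E[N_s] (diag(M_s) - M_s M_s^T) + M^T V_t M,
        with V_0 the multinomial covariance of the initial draw.
        """
        from eipcea.markov import build_transition_matrix

        p = params.start_vector()
        V = n_agents * (np.diag(p) - np.outer(p, p))
        ses = [np.sqrt(np.diag(V)) / n_agents]
        for t in range(params.economics.n_cycles):
            M = build_transition_matrix(params, draw, strat, t)
            exp_counts = n_agents * p
            V_cond = sum(
                exp_counts[s] * (np.diag(M[s]) - np.outer(M[s], M[s]))
                for s in range(len(p))
            )
            V = V_cond + M.T @ V @ M
            p = p @ M
            ses.append(np.sqrt(np.maximum(np.diag(V), 0.0)) / n_agents)
        return np.array(ses)

    @pytest.mark.parametrize("draw_seed", [11, 22, 33])
    def test_trace_agrees_with_microsimulation(self, reference_params, draw_seed):
        """Cohort trace vs 10^6-agent microsimulation within 3 binomial SEs.

        The SE of each state-by-cycle occupancy accounts for sampling error
        accumulated over previous cycles (exact multinomial covariance
        recursion), so 3 SEs is a calibrated bound per cell.
        """
        rng = np.random.default_rng(draw_seed)
        draw = sample_parameters(reference_params, 1.25, 0.51, rng)
        n_agents = 1_000_000
        for strat in ("eip", "cmht"):
            trace = run_cohort(reference_params, draw, strat)
            micro = microsimulate_cohort(
                reference_params, draw, strat, n_agents,
                np.random.default_rng(draw_seed + 1000),
            )
            se = self._microsim_se(reference_params, draw, strat, n_agents)
            # tiny floor covers exactly-deterministic cells (e.g. DEAD at t=0)
            z = np.abs(micro.occupancy - trace.occupancy) / (se + 1e-9)
            # 41 cycles x 6 states: allow the expected handful of >3-SE cells
            # (P ~ 0.27% per cell under the null) but nothing extreme
            assert float(np.mean(z > 3.0)) <= 0.005
            assert float(z.max()) <= 4.5


class TestAccumulateOutcomes:
    def test_conservation_full_utility_no_death_no_discount(self, reference_params):
        params = copy.deepcopy(reference_params)
        params.life_table = LifeTable(np.array([0]), np.array([0.0]))
        params.economics.discount_rate_annual = 0.0
        params.hsuv = {
            s.name: DistributionSpec(kind="fixed", parameters=[1.0])
            for s in ALIVE_STATES
        }
        draw = ModelDraw.from_point_estimates(params)
        out = run_strategy(params, draw, "cmht")
        assert out.qaly_discounted == pytest.approx(10.0, abs=1e-12)
        assert out.life_years == pytest.approx(10.0, abs=1e-12)

    def test_zero_costs_accumulate_to_zero(self, reference_params):
        params = copy.deepcopy(reference_params)
        zero = DistributionSpec(kind="fixed", parameters=[0.0])
        params.state_costs = {s.name: zero for s in ALIVE_STATES}
        params.program_cost_per_cycle = {"eip": zero, "cmht": zero}
        draw = ModelDraw.from_point_estimates(params)
        out = run_strategy(params, draw, "eip")
        assert out.cost_discounted == 0.0
        assert out.cost_undiscounted == 0.0

    def test_two_cycle_toy_model_matches_hand_ledger(self):
        """Two cycles, fully hand-computed costs and QALYs at r = 0.03."""
        occ = np.array(
            [
                [1.0, 0.0, 0, 0, 0, 0.0],
                [0.5, 0.4, 0, 0, 0, 0.1],
                [0.3, 0.5, 0, 0, 0, 0.2],
            ]
        )
        trace = CohortTrace(occupancy=occ, times=np.array([0, 0.25, 0.5]), cycle_length=0.25)

        from eipcea import make_reference_parameter_set

        params, _ = make_reference_parameter_set()
        params = copy.deepcopy(params)
        fixed = lambda v: DistributionSpec(kind="fixed", parameters=[v])
        params.hsuv = {s.name: fixed(0.5) for s in ALIVE_STATES}
        params.hsuv["ACUTE"] = fixed(0.6)
        params.hsuv["REMISSION"] = fixed(0.8)
        params.state_costs = {s.name: fixed(0.0) for s in ALIVE_STATES}
        params.state_costs["ACUTE"] = fixed(1000.0)
        params.state_costs["REMISSION"] = fixed(100.0)
        params.program_cost_per_cycle = {"eip": fixed(10.0), "cmht": fixed(0.0)}
        draw = ModelDraw.from_point_estimates(params)
        out = accumulate_outcomes(trace, params, draw, "eip")

        d1 = discount_factor(1, 0.03, 0.25)
        # cycle 0: occupancy (1.0 acute); cycle 1: (0.5 acute, 0.4 remission)
        qaly = (1.0 * 0.6) * 0.25 + (0.5 * 0.6 + 0.4 * 0.8) * 0.25 * d1
        cost = (1.0 * 1000 + 1.0 * 10) + (0.5 * 1000 + 0.4 * 100 + 0.9 * 10) * d1
        assert out.qaly_discounted == pytest.approx(qaly, abs=1e-12)
        assert out.cost_discounted == pytest.approx(cost, abs=1e-12)
        assert out.qaly_undiscounted >= out.qaly_discounted

    def test_discounting_weakly_decreases_totals(self, reference_params):
        params0 = copy.deepcopy(reference_params)
        params0.economics.discount_rate_annual = 0.0
        d0 = ModelDraw.from_point_estimates(params0)
        hi = run_strategy(params0, d0, "eip")
        lo = run_strategy(reference_params, ModelDraw.from_point_estimates(reference_params), "eip")
        assert lo.qaly_discounted <= hi.qaly_discounted
        assert lo.cost_discounted <= hi.cost_discounted

    def test_higher_utility_weakly_increases_qalys(self, reference_params):
        params = copy.deepcopy(reference_params)
        params.hsuv = dict(params.hsuv)
        params.hsuv["REMISSION"] = DistributionSpec(kind="fixed", parameters=[0.95])
        base = run_strategy(
            reference_params, ModelDraw.from_point_estimates(reference_params), "eip"
        )
        bumped = run_strategy(params, ModelDraw.from_point_estimates(params), "eip")
        assert bumped.qaly_discounted >= base.qaly_discounted

    def test_eip_dominates_cmht_on_qalys_with_favourable_effects(
        self, reference_params, reference_draw
    ):
        """RR_remission > 1 and RR_relapse < 1 with shared payoffs."""
        eip = run_strategy(reference_params, reference_draw, "eip")
        cmht = run_strategy(reference_params, reference_draw, "cmht")
        assert eip.qaly_discounted >= cmht.qaly_discounted
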