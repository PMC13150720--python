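"""Monte Carlo PSA, one-way sensitivity and scenario analyses."""

import copy

import numpy as np
import pytest

from eipcea import DistributionSpec, run_psa
from eipcea.params import ALIVE_STATES, ValidationError
from eipcea.psa import (
    ScenarioSpec,
    base_case,
    one_way_sa,
    run_scenarios,
    sample_parameters,
    set_parameter_point,
)
from eipcea.simulate import GDP_PER_CAPITA_CLP


def all_fixed(params):
    """Copy of the parameter set with every distribution collapsed to its mean."""
    p = copy.deepcopy(params)
    p.life_table = params.life_table
    fixed = lambda v: DistributionSpec(kind="fixed", parameters=[v])
    p.hsuv = {k: fixed(v.mean()) for k, v in p.hsuv.items()}
    p.state_costs = {k: fixed(v.mean()) for k, v in p.state_costs.items()}
    p.mortality_hazard_ratio = {
        k: fixed(v.mean()) for k, v in p.mortality_hazard_ratio.items()
    }
    p.program_cost_per_cycle = {
        k: fixed(v.mean()) for k, v in p.program_cost_per_cycle.items()
    }
    p.transition_dirichlet = {}
    return p


class TestSampleParameters:
    def test_fixed_specs_reproduce_point_estimates(self, reference_params, rng):
        p = all_fixed(reference_params)
        draw = sample_parameters(p, 1.25, 0.51, rng)
        for s in ALIVE_STATES:
            assert draw.hsuv[s] == p.hsuv[s.name].mean()
            assert draw.state_cost[s] == p.state_costs[s.name].mean()

    def test_sampled_utilities_stay_in_unit_interval(self, reference_params, rng):
        for _ in range(200):
            draw = sample_parameters(reference_params, 1.25, 0.51, rng)
            assert np.all((draw.hsuv >= 0) & (draw.hsuv <= 1))

    def test_dirichlet_rows_sum_to_one(self, reference_params, rng):
        draw = sample_parameters(reference_params, 1.25, 0.51, rng)
        for strat in ("eip", "cmht"):
            sums = draw.shares[strat].sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-12)

    def test_gamma_cost_mean_matches_closed_form(self, reference_params):
        rng = np.random.default_rng(5)
        spec = reference_params.state_costs["ACUTE"]
        k, theta = spec.parameters
        draws = np.array(
            [
                sample_parameters(reference_params, 1.0, 1.0, rng).state_cost[0]
                for _ in range(10_000)
            ]
        )
        se = np.sqrt(k) * theta / np.sqrt(10_000)
        assert abs(draws.mean() - k * theta) <= 3 * se

    def test_common_random_numbers_share_baseline_rows(self, reference_params, rng):
        """Both strategies see the same baseline transition draw."""
        draw = sample_parameters(reference_params, 1.25, 0.51, rng)
        assert np.array_equal(draw.shares["eip"], draw.shares["cmht"])


class TestRunPSA:
    def test_single_iteration_fixed_specs_equals_base_case(self, reference_params):
        p = all_fixed(reference_params)
        rr_rem = p.treatment_effect.rr_remission.mean()
        rr_rel = p.treatment_effect.rr_relapse.mean()
        psa = run_psa(p, np.array([rr_rem]), np.array([rr_rel]), n=1, master_seed=3)
        bc = base_case(p)
        assert psa.costs[0, 0] - psa.costs[0, 1] == pytest.approx(bc.delta_cost)
        assert psa.qalys[0, 0] - psa.qalys[0, 1] == pytest.approx(bc.delta_qaly)

    def test_reproducible_under_master_seed(self, reference_params):
        rr = np.array([1.2, 1.3]), np.array([0.5, 0.6])
        a = run_psa(reference_params, *rr, n=20, master_seed=42)
        b = run_psa(reference_params, *rr, n=20, master_seed=42)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)
        assert a.records.equals(b.records)

    def test_fixed_specs_give_zero_variance_cloud(self, reference_params):
        p = all_fixed(reference_params)
        psa = run_psa(p, np.array([1.25]), np.array([0.51]), n=10, master_seed=0)
        assert np.ptp(psa.costs, axis=0).max() == 0.0
        assert np.ptp(psa.qalys, axis=0).max() == 0.0

    def test_mean_tracks_deterministic_run_at_small_variance(self, reference_params):
        """Near-linear model: PSA mean ~ deterministic run at the means."""
        psa = run_psa(
            reference_params, np.array([1.25]), np.array([0.51]), n=400, master_seed=9
        )
        p = all_fixed(reference_params)
        p.treatment_effect.rr_remission = DistributionSpec(kind="fixed", parameters=[1.25])
        p.treatment_effect.rr_relapse = DistributionSpec(kind="fixed", parameters=[0.51])
        bc = base_case(p)
        de = psa.delta_qaly()
        dc = psa.delta_cost()
        assert abs(de.mean() - bc.delta_qaly) <= 4 * de.std() / np.sqrt(len(de))
        assert abs(dc.mean() - bc.delta_cost) <= 4 * dc.std() / np.sqrt(len(dc))

    def test_record_columns_cover_every_uncertain_parameter(self, reference_params):
        psa = run_psa(
            reference_params, np.array([1.25]), np.array([0.51]), n=3, master_seed=1
        )
        cols = set(psa.records.columns)
        assert {"rr_remission", "rr_relapse", "hsuv.REMISSION", "cost.RELAPSE",
                "program_cost.eip"} <= cols
        assert not psa.records.isna().any().any()


class TestOneWaySA:
    def test_zero_width_interval_reproduces_base_case(self, reference_params):
        bc = base_case(reference_params)
        hs = reference_params.hsuv["REMISSION"].mean()
        tab = one_way_sa(
            reference_params, [("hsuv.REMISSION", hs, hs)], GDP_PER_CAPITA_CLP
        )
        assert tab.loc[0, "icer_low"] == pytest.approx(bc.icer, rel=1e-9)
        assert tab.loc[0, "icer_high"] == pytest.approx(bc.icer, rel=1e-9)

    def test_remission_utility_direction(self, reference_params):
        """Higher remission HSUV -> larger delta-E -> smaller ICER (EIP gains
        more remission time than CMHT)."""
        tab = one_way_sa(
            reference_params, [("hsuv.REMISSION", 0.7, 0.9)], GDP_PER_CAPITA_CLP
        )
        assert tab.loc[0, "icer_high"] < tab.loc[0, "icer_low"]

    def test_program_cost_shifts_delta_cost_one_for_one(self, reference_params):
        lo, hi = 50_000.0, 150_000.0
        res_lo = base_case(set_parameter_point(reference_params, "program_cost.eip", lo))
        res_hi = base_case(set_parameter_point(reference_params, "program_cost.eip", hi))
        assert res_lo.delta_qaly == pytest.approx(res_hi.delta_qaly, abs=1e-12)
        # discounted alive person-cycles multiplies the per-cycle difference
        per_cycle = (res_hi.delta_cost - res_lo.delta_cost) / (hi - lo)
        assert per_cycle > 0
        ref = base_case(reference_params)
        assert res_hi.delta_cost > ref.delta_cost > res_lo.delta_cost

    def test_unknown_parameter_path_rejected(self, reference_params):
        with pytest.raises(ValidationError, match="no_such"):
            one_way_sa(reference_params, [("no_such.thing", 0, 1)], 1e6)

    def test_out_of_support_bound_rejected(self, reference_params):
        with pytest.raises(ValidationError):
            one_way_sa(reference_params, [("hsuv.REMISSION", 0.5, 1.5)], 1e6)

    def test_table_sorted_by_nb_range(self, reference_params):
        tab = one_way_sa(
            reference_params,
            [
                ("hsuv.REMISSION", 0.75, 0.90),
                ("program_cost.eip", 90_000.0, 100_000.0),
                ("state_costs.RELAPSE", 1_000_000.0, 1_400_000.0),
            ],
            GDP_PER_CAPITA_CLP,
        )
        assert list(tab["nb_range"]) == sorted(tab["nb_range"], reverse=True)


class TestScenarios:
    def test_base_horizon_scenario_is_identity(self, reference_params):
        res = run_scenarios(reference_params, [ScenarioSpec(name="base", horizon=10)])
        bc = base_case(reference_params)
        assert res["base"].delta_cost == pytest.approx(bc.delta_cost)
        assert res["base"].delta_qaly == pytest.approx(bc.delta_qaly)

    def test_longer_horizons_accumulate_more_undiscounted_qalys(self, reference_params):
        out = run_scenarios(
            reference_params,
            [
                ScenarioSpec(name="h10", horizon=10),
                ScenarioSpec(name="h20", horizon=20),
                ScenarioSpec(name="h30", horizon=30),
                ScenarioSpec(name="lifetime", horizon="lifetime"),
            ],
        )
        for strat_attr in ("eip", "cmht"):
            q10 = getattr(out["h10"], strat_attr).qaly_undiscounted
            q20 = getattr(out["h20"], strat_attr).qaly_undiscounted
            q30 = getattr(out["h30"], strat_attr).qaly_undiscounted
            q60 = getattr(out["lifetime"], strat_attr).qaly_undiscounted
            assert q10 <= q20 <= q30 <= q60
        # lifetime horizon runs to cohort age 80 = 60 years from entry
        assert out["lifetime"].eip.horizon_years == pytest.approx(60.0)

    def test_override_scenario_changes_named_parameter_only(self, reference_params):
        res = run_scenarios(
            reference_params,
            [ScenarioSpec(name="cheap", overrides={"program_cost.eip": 0.0})],
        )["cheap"]
        bc = base_case(reference_params)
        assert res.delta_qaly == pytest.approx(bc.delta_qaly, abs=1e-12)
        assert res.delta_cost < bc.delta_cost
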