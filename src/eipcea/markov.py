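"""Markov cohort engine: transition-matrix assembly, cohort trace, and
discounted cost/QALY accumulation.

The engine works on a :class:`ModelDraw` — one concrete realization of every
parameter (the point estimates for deterministic runs, one Monte Carlo draw
per PSA iteration).  Per cycle, death is applied first as a competing risk
(life-table rate x state hazard ratio converted to a cycle probability) and
the surviving mass is allocated across the adjacency-allowed destinations in
proportion to the strategy's conditional destination shares, after the pooled
risk ratios have scaled the remission and relapse transitions.

Accounting convention: a cycle's costs and QALYs are valued at the occupancy
at the *start* of the cycle and discounted with that cycle's index, so a
10-year horizon at utility 1, zero mortality and zero discounting yields
exactly 10 QALYs.  No half-cycle correction is applied by default; a
trapezoidal within-cycle correction is available for sensitivity use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import (
    ALIVE_STATES,
    DEFAULT_ADJACENCY,
    N_STATES,
    HealthState,
    ParameterSet,
    ValidationError,
    annual_rate_to_cycle_prob,
    discount_factor,
)

#: transitions the pooled risk ratios act on: RR_remission scales entry into
#: remission from the acute state, RR_relapse scales relapse from remission
RR_REMISSION_EDGE = (HealthState.ACUTE, HealthState.REMISSION)
RR_RELAPSE_EDGE = (HealthState.REMISSION, HealthState.RELAPSE)


@dataclass
class ModelDraw:
    """One concrete realization of all model parameters.

    ``shares[strategy]`` is a 5x6 array of conditional-on-survival destination
    shares (rows: alive states; columns: all states, DEAD column zero).
    """

    shares: dict[str, np.ndarray]
    hsuv: np.ndarray            # length 5, indexed by alive state
    state_cost: np.ndarray      # length 5, per cycle
    program_cost: dict[str, float]  # per cycle while alive
    hazard_ratio: np.ndarray    # length 5
    rr_remission: float
    rr_relapse: float
    record: dict[str, float] = field(default_factory=dict)
    #: count of RR x p > 1 capping events (surfaced in PSA diagnostics)
    rr_cap_events: int = 0

    @classmethod
    def from_point_estimates(cls, params: ParameterSet) -> "ModelDraw":
        """Deterministic draw at the distribution means (base case)."""
        shares = {}
        for strat in ("eip", "cmht"):
            rows = params.strategy_transitions(strat)
            mat = np.zeros((len(ALIVE_STATES), N_STATES))
            for s in ALIVE_STATES:
                for to_name, spec in rows[s.name].items():
                    mat[s, HealthState[to_name]] = spec.mean()
            shares[strat] = mat
        return cls(
            shares=shares,
            hsuv=np.array([params.hsuv[s.name].mean() for s in ALIVE_STATES]),
            state_cost=np.array(
                [params.state_costs[s.name].mean() for s in ALIVE_STATES]
            ),
            program_cost={
                strat: params.program_cost_per_cycle[strat].mean()
                for strat in ("eip", "cmht")
            },
            hazard_ratio=np.array(
                [params.mortality_hazard_ratio[s.name].mean() for s in ALIVE_STATES]
            ),
            rr_remission=params.treatment_effect.rr_remission.mean(),
            rr_relapse=params.treatment_effect.rr_relapse.mean(),
        )


@dataclass
class CohortTrace:
    """Cycle-by-state occupancy of the closed cohort.

    ``occupancy`` has ``n_cycles + 1`` rows; row 0 is the start distribution
    and row t the distribution after t transitions.  ``times`` are the cycle
    start times in years.
    """

    occupancy: np.ndarray
    times: np.ndarray
    cycle_length: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1


@dataclass
class StrategyOutcome:
    """Total discounted and undiscounted costs/QALYs for one strategy."""

    strategy: str
    cost_discounted: float
    qaly_discounted: float
    cost_undiscounted: float
    qaly_undiscounted: float
    life_years: float
    horizon_years: float


def apply_treatment_effect(
    baseline_row: np.ndarray,
    rr: float,
    target_state: HealthState,
    cap_counter: Optional[list] = None,
) -> np.ndarray:
    """Scale one destination's probability by a risk ratio and renormalize.

    The probability into ``target_state`` is multiplied by ``rr`` (capped at
    1); the complement is redistributed proportionally across the other
    destinations so the row still sums to 1.
    """
    if rr < 0:
        raise ValidationError(f"risk ratio must be >= 0, got {rr}")
    row = np.asarray(baseline_row, dtype=float).copy()
    p = row[target_state]
    if p == 0.0 or rr == 1.0:
        if rr * p > 1.0 and cap_counter is not None:
            cap_counter.append(1)
        return row
    new_p = rr * p
    if new_p > 1.0:
        new_p = 1.0
        if cap_counter is not None:
            cap_counter.append(1)
    others = row.sum() - p
    row[target_state] = 0.0
    if others > 0:
        row *= (1.0 - new_p) / others
    row[target_state] = new_p
    return row


def build_transition_matrix(
    params: ParameterSet,
    draw: ModelDraw,
    strategy: str,
    cycle_index: int,
    rr_remission: Optional[float] = None,
    rr_relapse: Optional[float] = None,
) -> np.ndarray:
    """Assemble the 6x6 row-stochastic transition matrix for one cycle.

    Death is applied first: each alive state's death probability comes from
    the life-table rate at the cohort's age this cycle times the state's
    hazard ratio; the remaining mass follows the (effect-adjusted) conditional
    destination shares.
    """
    econ = params.economics
    lt = params.require_life_table()
    age = params.start_age + cycle_index * econ.cycle_length_years
    rate = lt.rate(age)

    rr_rem = draw.rr_remission if rr_remission is None else rr_remission
    rr_rel = draw.rr_relapse if rr_relapse is None else rr_relapse
    dur = params.treatment_effect.effect_duration_years
    if dur is not None and cycle_index * econ.cycle_length_years >= dur:
        rr_rem, rr_rel = 1.0, 1.0

    M = np.zeros((N_STATES, N_STATES))
    M[HealthState.DEAD, HealthState.DEAD] = 1.0
    caps: list = []
    for s in ALIVE_STATES:
        row = draw.shares[strategy][s].copy()
        total = row.sum()
        if total > 1.0 + 1e-9:
            raise ValidationError(
                f"baseline destination shares for {s.name} sum to {total:.6f} > 1"
            )
        row = row / total  # tolerate tiny sampling round-off
        if strategy == "eip":
            if s is RR_REMISSION_EDGE[0]:
                row = apply_treatment_effect(row, rr_rem, RR_REMISSION_EDGE[1], caps)
            if s is RR_RELAPSE_EDGE[0]:
                row = apply_treatment_effect(row, rr_rel, RR_RELAPSE_EDGE[1], caps)
        p_death = annual_rate_to_cycle_prob(
            rate, draw.hazard_ratio[s], econ.cycle_length_years
        )
        M[s] = (1.0 - p_death) * row
        M[s, HealthState.DEAD] = p_death
    draw.rr_cap_events += len(caps)
    return M


def run_cohort(
    params: ParameterSet,
    draw: ModelDraw,
    strategy: str,
    n_cycles: Optional[int] = None,
) -> CohortTrace:
    """Propagate the cohort over the horizon by vector-matrix products."""
    econ = params.economics
    n = econ.n_cycles if n_cycles is None else n_cycles
    occ = np.zeros((n + 1, N_STATES))
    occ[0] = params.start_vector()
    for t in range(n):
        M = build_transition_matrix(params, draw, strategy, t)
        occ[t + 1] = occ[t] @ M
    times = np.arange(n + 1) * econ.cycle_length_years
    return CohortTrace(occupancy=occ, times=times, cycle_length=econ.cycle_length_years)


def accumulate_outcomes(
    trace: CohortTrace,
    params: ParameterSet,
    draw: ModelDraw,
    strategy: str,
    half_cycle_correction: bool = False,
) -> StrategyOutcome:
    """Discounted QALYs and costs from a cohort trace.

    QALYs: sum over cycles of occupancy x HSUV x cycle length x discount
    factor; costs analogously from per-cycle state costs plus the strategy's
    program cost applied to the alive fraction.  With
    ``half_cycle_correction`` the within-cycle occupancy is the trapezoidal
    average of the cycle's start and end rows.
    """
    econ = params.economics
    cl = trace.cycle_length
    n = trace.n_cycles
    alive_idx = np.array([int(s) for s in ALIVE_STATES])

    occ = trace.occupancy[:, alive_idx]
    if half_cycle_correction:
        per_cycle = 0.5 * (occ[:-1] + occ[1:])
    else:
        per_cycle = occ[:-1]

    disc = np.array(
        [discount_factor(t, econ.discount_rate_annual, cl) for t in range(n)]
    )
    alive_frac = per_cycle.sum(axis=1)

    qaly_cycle = per_cycle @ draw.hsuv * cl
    cost_cycle = per_cycle @ draw.state_cost + alive_frac * draw.program_cost[strategy]

    return StrategyOutcome(
        strategy=strategy,
        cost_discounted=float(cost_cycle @ disc),
        qaly_discounted=float(qaly_cycle @ disc),
        cost_undiscounted=float(cost_cycle.sum()),
        qaly_undiscounted=float(qaly_cycle.sum()),
        life_years=float(alive_frac.sum() * cl),
        horizon_years=n * cl,
    )


def run_strategy(
    params: ParameterSet,
    draw: ModelDraw,
    strategy: str,
    n_cycles: Optional[int] = None,
    half_cycle_correction: bool = False,
) -> StrategyOutcome:
    """Convenience: trace + accumulation in one call."""
    trace = run_cohort(params, draw, strategy, n_cycles=n_cycles)
    return accumulate_outcomes(
        trace, params, draw, strategy, half_cycle_correction=half_cycle_correction
    )


def microsimulate_cohort(
    params: ParameterSet,
    draw: ModelDraw,
    strategy: str,
    n_agents: int,
    rng: np.random.Generator,
    n_cycles: Optional[int] = None,
) -> CohortTrace:
    """Agent-count microsimulation with the same per-cycle matrices.

    Serves as an independent stochastic oracle for :func:`run_cohort`: agents
    in each state transition as a multinomial draw from that state's row, so
    occupancy proportions converge to the deterministic trace with binomial
    Monte Carlo error.
    """
    econ = params.economics
    n = econ.n_cycles if n_cycles is None else n_cycles
    start = params.start_vector()
    counts = rng.multinomial(n_agents, start)
    occ = np.zeros((n + 1, N_STATES))
    occ[0] = counts / n_agents
    for t in range(n):
        M = build_transition_matrix(params, draw, strategy, t)
        new_counts = np.zeros(N_STATES, dtype=np.int64)
        for s in range(N_STATES):
            if counts[s] > 0:
                new_counts += rng.multinomial(counts[s], M[s])
        counts = new_counts
        occ[t + 1] = counts / n_agents
    times = np.arange(n + 1) * econ.cycle_length_years
    return CohortTrace(occupancy=occ, times=times, cycle_length=econ.cycle_length_years)


def trace_to_frame(trace: CohortTrace, start_age: float):
    """Long-format DataFrame (`cycle,age,state,occupancy`) for CSV export."""
    import pandas as pd

    rows = []
    for t in range(trace.occupancy.shape[0]):
        for s in HealthState:
            rows.append(
                {
                    "cycle": t,
                    "age": start_age + t * trace.cycle_length,
                    "state": s.name,
                    "occupancy": trace.occupancy[t, s],
                }
            )
    return pd.DataFrame(rows)
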