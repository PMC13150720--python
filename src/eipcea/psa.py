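"""Probabilistic sensitivity analysis, one-way deterministic sensitivity and
scenario analyses.

The PSA propagates parameter uncertainty by Monte Carlo: each iteration draws
one coherent parameter realization (Dirichlet transition rows, beta utilities,
gamma costs, lognormal hazard ratios, posterior risk-ratio draws) and runs
both strategies on that same draw (common random numbers), accumulating
discounted costs and QALYs.  Per-iteration RNG streams are spawned from the
master seed with `numpy.random.SeedSequence`, so results are reproducible
bit-for-bit and independent of execution order.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .economics import IncrementalResult, incremental_analysis, net_benefit
from .markov import ModelDraw, run_strategy
from .params import (
    ALIVE_STATES,
    N_STATES,
    DistributionSpec,
    HealthState,
    ParameterSet,
    ValidationError,
)

STRAT_ORDER = ("eip", "cmht")


@dataclass
class PSAResult:
    """Per-iteration discounted outcomes and sampled parameter records."""

    costs: np.ndarray   # (n, 2) columns ordered as STRAT_ORDER
    qalys: np.ndarray   # (n, 2)
    records: pd.DataFrame  # one row per iteration, one column per parameter
    master_seed: int
    rr_cap_events: int = 0
    strategies: tuple[str, str] = STRAT_ORDER

    @property
    def n_iterations(self) -> int:
        return self.costs.shape[0]

    def delta_cost(self) -> np.ndarray:
        return self.costs[:, 0] - self.costs[:, 1]

    def delta_qaly(self) -> np.ndarray:
        return self.qalys[:, 0] - self.qalys[:, 1]

    def nb_matrix(self, wtp: float) -> np.ndarray:
        """Iterations x strategies net-benefit matrix at willingness-to-pay λ."""
        return wtp * self.qalys - self.costs

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, strat in enumerate(self.strategies):
            rows.append(
                pd.DataFrame(
                    {
                        "iter": np.arange(self.n_iterations),
                        "strategy": strat,
                        "cost": self.costs[:, j],
                        "qaly": self.qalys[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def mean_outcomes(self) -> dict[str, float]:
        return {
            "cost_eip": float(self.costs[:, 0].mean()),
            "cost_cmht": float(self.costs[:, 1].mean()),
            "qaly_eip": float(self.qalys[:, 0].mean()),
            "qaly_cmht": float(self.qalys[:, 1].mean()),
        }


@dataclass
class ScenarioSpec:
    """A named deviation from the base case.

    ``horizon``: years, or the string 'lifetime' (run until cohort age 80).
    ``overrides``: dotted parameter path -> point value (see
    :func:`set_parameter_point`).
    """

    name: str
    horizon: Optional[object] = None
    wtp_multiplier: float = 1.0
    overrides: dict[str, float] = field(default_factory=dict)


LIFETIME_AGE = 80.0


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sampled_row(
    params: ParameterSet, strategy: str, state, rng: np.random.Generator,
    record: dict, prefix: str,
) -> np.ndarray:
    """Sample one transition row: Dirichlet if configured, else point shares."""
    row_specs = params.strategy_transitions(strategy)[state.name]
    dirich = params.transition_dirichlet.get(strategy, {}).get(state.name)
    dests = list(row_specs)
    out = np.zeros(N_STATES)
    if dirich is not None:
        alphas = np.array([dirich[name] for name in dests])
        draw = rng.dirichlet(alphas)
        for name, p in zip(dests, draw):
            out[HealthState[name]] = p
            record[f"{prefix}.{state.name}.{name}"] = float(p)
    else:
        for name in dests:
            p = row_specs[name].sample(rng)
            out[HealthState[name]] = p
            record[f"{prefix}.{state.name}.{name}"] = float(p)
        out = out / out.sum()
    return out


def sample_parameters(
    params: ParameterSet,
    rr_remission: float,
    rr_relapse: float,
    rng: np.random.Generator,
) -> ModelDraw:
    """One coherent Monte Carlo draw of every uncertain parameter.

    The flat ``record`` retained on the draw maps parameter names to sampled
    values and feeds the EVPPI regressions.
    """
    record: dict[str, float] = {}
    shares = {}
    for strat in ("cmht", "eip"):  # cmht first: eip may share its baseline draw
        mat = np.zeros((len(ALIVE_STATES), N_STATES))
        for s in ALIVE_STATES:
            if strat == "eip" and "eip" not in params.transitions:
                # shared baseline: reuse the cmht row draw (common random numbers)
                mat[s] = shares["cmht"][s]
                continue
            mat[s] = _sampled_row(params, strat, s, rng, record, f"tp.{strat}")
        shares[strat] = mat

    hsuv = np.empty(len(ALIVE_STATES))
    cost = np.empty(len(ALIVE_STATES))
    hr = np.empty(len(ALIVE_STATES))
    for s in ALIVE_STATES:
        hsuv[s] = params.hsuv[s.name].sample(rng)
        cost[s] = params.state_costs[s.name].sample(rng)
        hr[s] = params.mortality_hazard_ratio[s.name].sample(rng)
        record[f"hsuv.{s.name}"] = float(hsuv[s])
        record[f"cost.{s.name}"] = float(cost[s])
        record[f"hr.{s.name}"] = float(hr[s])

    program = {
        strat: params.program_cost_per_cycle[strat].sample(rng)
        for strat in STRAT_ORDER
    }
    record["program_cost.eip"] = float(program["eip"])
    record["program_cost.cmht"] = float(program["cmht"])
    record["rr_remission"] = float(rr_remission)
    record["rr_relapse"] = float(rr_relapse)

    return ModelDraw(
        shares=shares,
        hsuv=hsuv,
        state_cost=cost,
        program_cost=program,
        hazard_ratio=hr,
        rr_remission=float(rr_remission),
        rr_relapse=float(rr_relapse),
        record=record,
    )


def run_psa(
    params: ParameterSet,
    remission_draws: np.ndarray,
    relapse_draws: np.ndarray,
    n: int = 5000,
    master_seed: int = 0,
) -> PSAResult:
    """Monte Carlo PSA: n iterations, both strategies per iteration.

    Risk-ratio draws for remission and relapse are paired by index; they are
    recycled cyclically if shorter than n.  Any iteration failure aborts with
    the iteration index and its sampled record.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    remission_draws = np.asarray(remission_draws, dtype=float)
    relapse_draws = np.asarray(relapse_draws, dtype=float)
    seeds = np.random.SeedSequence(master_seed).spawn(n)

    costs = np.empty((n, 2))
    qalys = np.empty((n, 2))
    records = []
    cap_events = 0
    for i in range(n):
        rng = np.random.default_rng(seeds[i])
        rr_rem = remission_draws[i % remission_draws.size]
        rr_rel = relapse_draws[i % relapse_draws.size]
        try:
            draw = sample_parameters(params, rr_rem, rr_rel, rng)
            for j, strat in enumerate(STRAT_ORDER):
                out = run_strategy(params, draw, strat)
                costs[i, j] = out.cost_discounted
                qalys[i, j] = out.qaly_discounted
        except Exception as exc:
            raise RuntimeError(
                f"PSA iteration {i} failed: {exc}; sampled record: "
                f"{draw.record if 'draw' in locals() else 'unavailable'}"
            ) from exc
        cap_events += draw.rr_cap_events
        records.append(draw.record)

    return PSAResult(
        costs=costs,
        qalys=qalys,
        records=pd.DataFrame.from_records(records),
        master_seed=master_seed,
        rr_cap_events=cap_events,
    )


# ---------------------------------------------------------------------------
# deterministic sensitivity / scenarios
# ---------------------------------------------------------------------------

def set_parameter_point(params: ParameterSet, path: str, value: float) -> ParameterSet:
    """Return a copy of ``params`` with one parameter pinned to a point value.

    Supported dotted paths: ``hsuv.<STATE>``, ``state_costs.<STATE>``,
    ``mortality_hazard_ratio.<STATE>``, ``program_cost.<strategy>``,
    ``rr_remission``, ``rr_relapse``, and
    ``transitions.<strategy>.<FROM>.<TO>`` (the row's other destinations are
    rescaled to keep the shares summing to 1).
    """
    new = copy.deepcopy(params)
    new.life_table = params.life_table
    fixed = lambda v: DistributionSpec(kind="fixed", parameters=[float(v)])
    parts = path.split(".")
    try:
        if parts[0] == "hsuv":
            if not 0 <= value <= 1:
                raise ValidationError(f"{path}: utility {value} outside [0, 1]")
            new.hsuv[parts[1]] = fixed(value)
        elif parts[0] == "state_costs":
            if value < 0:
                raise ValidationError(f"{path}: cost must be >= 0")
            new.state_costs[parts[1]] = fixed(value)
        elif parts[0] == "mortality_hazard_ratio":
            if value <= 0:
                raise ValidationError(f"{path}: hazard ratio must be > 0")
            new.mortality_hazard_ratio[parts[1]] = fixed(value)
        elif parts[0] == "program_cost":
            if value < 0:
                raise ValidationError(f"{path}: cost must be >= 0")
            new.program_cost_per_cycle[parts[1]] = fixed(value)
        elif parts[0] == "rr_remission":
            new.treatment_effect.rr_remission = fixed(value)
        elif parts[0] == "rr_relapse":
            new.treatment_effect.rr_relapse = fixed(value)
        elif parts[0] == "transitions":
            _, strat, from_name, to_name = parts
            if not 0 <= value <= 1:
                raise ValidationError(f"{path}: probability {value} outside [0, 1]")
            if strat == "eip" and "eip" not in new.transitions:
                new.transitions["eip"] = copy.deepcopy(new.transitions["cmht"])
            row = new.transitions[strat][from_name]
            old = row[to_name].mean()
            rest = 1.0 - old
            scale = (1.0 - value) / rest if rest > 0 else 0.0
            for name in row:
                m = row[name].mean() * (scale if name != to_name else 0.0)
                row[name] = fixed(m if name != to_name else value)
            row[to_name] = fixed(value)
        else:
            raise KeyError(path)
    except (KeyError, IndexError) as exc:
        raise ValidationError(f"unknown parameter path {path!r}") from exc
    return new


def base_case(params: ParameterSet, n_cycles: Optional[int] = None) -> IncrementalResult:
    """Deterministic run at the parameter point estimates."""
    draw = ModelDraw.from_point_estimates(params)
    eip = run_strategy(params, draw, "eip", n_cycles=n_cycles)
    cmht = run_strategy(params, draw, "cmht", n_cycles=n_cycles)
    return incremental_analysis(eip, cmht)


def one_way_sa(
    params: ParameterSet,
    sweeps: Sequence[tuple[str, float, float]],
    reference_wtp: float,
) -> pd.DataFrame:
    """Tornado table: ICER and incremental NB at each parameter's bounds.

    ``sweeps`` is a list of (parameter path, low, high); all other parameters
    stay at the base case.  Sorted by the incremental-NB range, widest first.
    """
    rows = []
    for path, lo, hi in sweeps:
        entry = {"parameter": path, "low": lo, "high": hi}
        for side, value in (("low", lo), ("high", hi)):
            res = base_case(set_parameter_point(params, path, value))
            entry[f"icer_{side}"] = res.icer
            entry[f"nb_{side}"] = net_benefit(res.delta_qaly, res.delta_cost, reference_wtp)
        entry["nb_range"] = abs(entry["nb_high"] - entry["nb_low"])
        rows.append(entry)
    df = pd.DataFrame(rows)
    return df.sort_values("nb_range", ascending=False).reset_index(drop=True)


def scenario_cycles(params: ParameterSet, horizon) -> int:
    """Number of cycles for a scenario horizon (years or 'lifetime' to age 80)."""
    cl = params.economics.cycle_length_years
    if horizon == "lifetime":
        years = max(LIFETIME_AGE - params.start_age, cl)
    else:
        years = float(horizon)
    n = years / cl
    if abs(n - round(n)) > 1e-9:
        raise ValidationError("scenario horizon must be a multiple of cycle length")
    return int(round(n))


def run_scenarios(
    params: ParameterSet, scenarios: Sequence[ScenarioSpec]
) -> dict[str, IncrementalResult]:
    """One deterministic incremental result per scenario."""
    out = {}
    for sc in scenarios:
        p = params
        for path, value in sc.overrides.items():
            p = set_parameter_point(p, path, value)
        n_cycles = None if sc.horizon is None else scenario_cycles(p, sc.horizon)
        out[sc.name] = base_case(p, n_cycles=n_cycles)
    return out
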