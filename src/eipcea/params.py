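"""Model inputs: health states, parameter distributions, life tables and
economic settings.

Everything downstream (evidence synthesis aside) consumes a single
:class:`ParameterSet`, loaded from a YAML config plus a life-table CSV.  The
parameter set stores *distributions*; deterministic runs use their point
estimates (means; posterior medians for treatment effects) and the PSA samples
them.

Transition probabilities are stored as destination shares conditional on
surviving the cycle: each row over the adjacency-allowed non-dead destinations
sums to 1, and per-cycle death probabilities are layered on top from the life
table and state-specific mortality hazard ratios (competing-risk style, death
first).
"""

from __future__ import annotations

import enum
import math
from typing import Iterator, Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class HealthState(enum.IntEnum):
    """The six mutually exclusive health states of the cohort model.

    ACUTE is the entry state (first-episode / acute psychosis); DEAD is
    absorbing.  Every occupancy vector and transition matrix is indexed in
    this order.
    """

    ACUTE = 0
    REMISSION = 1
    RELAPSE = 2
    RESISTANT = 3
    PNS = 4
    DEAD = 5


ALIVE_STATES = tuple(s for s in HealthState if s is not HealthState.DEAD)
N_STATES = len(HealthState)

#: Allowed transitions between *alive* states, conditional on surviving the
#: cycle (death is reachable from every state and handled separately).
DEFAULT_ADJACENCY: dict[HealthState, tuple[HealthState, ...]] = {
    HealthState.ACUTE: (
        HealthState.ACUTE,
        HealthState.REMISSION,
        HealthState.RESISTANT,
        HealthState.PNS,
    ),
    HealthState.REMISSION: (
        HealthState.REMISSION,
        HealthState.RELAPSE,
        HealthState.PNS,
    ),
    HealthState.RELAPSE: (
        HealthState.REMISSION,
        HealthState.RELAPSE,
        HealthState.RESISTANT,
    ),
    HealthState.RESISTANT: (
        HealthState.REMISSION,
        HealthState.RESISTANT,
    ),
    HealthState.PNS: (
        HealthState.PNS,
        HealthState.RELAPSE,
    ),
}

STRATEGIES = ("eip", "cmht")


class ValidationError(ValueError):
    """A config value violates the model's invariants."""


# ---------------------------------------------------------------------------
# probability / discounting utilities
# ---------------------------------------------------------------------------

def annual_rate_to_cycle_prob(rate: float, hazard_ratio: float, cycle_length: float) -> float:
    """Convert an annual event rate to a per-cycle probability.

    The hazard ratio multiplies the rate (hazard scale), and the probability
    follows the exponential survival model::

        p = 1 - exp(-rate * hazard_ratio * cycle_length)

    Parameters
    ----------
    rate : annual rate per person-year (>= 0).
    hazard_ratio : dimensionless multiplier on the hazard (> 0).
    cycle_length : cycle length in years (> 0).
    """
    if rate < 0:
        raise ValidationError(f"annual rate must be >= 0, got {rate}")
    if hazard_ratio <= 0:
        raise ValidationError(f"hazard ratio must be > 0, got {hazard_ratio}")
    if cycle_length <= 0:
        raise ValidationError(f"cycle length must be > 0, got {cycle_length}")
    return -math.expm1(-rate * hazard_ratio * cycle_length)


def discount_factor(cycle_index: int, r: float, cycle_length: float) -> float:
    """Discrete per-cycle discount factor ``(1 + r) ** -(t * cycle_length)``.

    The annual rate ``r`` is compounded at cycle resolution, so cycle 0 is
    undiscounted and a full year of cycles discounts by exactly ``1/(1+r)``.
    """
    if cycle_index < 0:
        raise ValidationError("cycle_index must be >= 0")
    return float((1.0 + r) ** (-(cycle_index * cycle_length)))


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

DistKind = Literal["fixed", "beta", "gamma", "lognormal", "normal", "dirichlet"]


class DistributionSpec(BaseModel):
    """A parameter's uncertainty distribution.

    kinds and parameters:

    - ``fixed``:      [value]
    - ``beta``:       [alpha, beta]
    - ``gamma``:      [shape, scale]
    - ``lognormal``:  [mu_log, sigma_log]  (mean of log, sd of log)
    - ``normal``:     [mu, sigma]
    - ``dirichlet``:  [alpha_1, ..., alpha_k]
    """

    model_config = ConfigDict(extra="forbid")

    kind: DistKind
    parameters: list[float]

    @model_validator(mode="after")
    def _check(self) -> "DistributionSpec":
        p = self.parameters
        if self.kind == "fixed":
            if len(p) != 1:
                raise ValueError("fixed spec takes exactly one value")
        elif self.kind == "beta":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValueError("beta requires two positive shape parameters")
        elif self.kind == "gamma":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValueError("gamma requires positive shape and scale")
        elif self.kind == "lognormal":
            if len(p) != 2 or p[1] < 0:
                raise ValueError("lognormal requires [mu_log, sigma_log>=0]")
        elif self.kind == "normal":
            if len(p) != 2 or p[1] < 0:
                raise ValueError("normal requires [mu, sigma>=0]")
        elif self.kind == "dirichlet":
            if len(p) < 2 or any(a <= 0 for a in p):
                raise ValueError("dirichlet requires >=2 positive concentrations")
        return self

    def mean(self) -> float:
        p = self.parameters
        if self.kind == "fixed":
            return p[0]
        if self.kind == "beta":
            return p[0] / (p[0] + p[1])
        if self.kind == "gamma":
            return p[0] * p[1]
        if self.kind == "lognormal":
            return math.exp(p[0] + p[1] ** 2 / 2.0)
        if self.kind == "normal":
            return p[0]
        raise ValidationError("mean() is scalar; dirichlet rows use mean_vector()")

    def mean_vector(self) -> np.ndarray:
        if self.kind != "dirichlet":
            raise ValidationError("mean_vector() only applies to dirichlet specs")
        a = np.asarray(self.parameters, dtype=float)
        return a / a.sum()

    def sample(self, rng: np.random.Generator):
        p = self.parameters
        if self.kind == "fixed":
            return p[0]
        if self.kind == "beta":
            return float(rng.beta(p[0], p[1]))
        if self.kind == "gamma":
            return float(rng.gamma(p[0], p[1]))
        if self.kind == "lognormal":
            return float(rng.lognormal(p[0], p[1]))
        if self.kind == "normal":
            return float(rng.normal(p[0], p[1]))
        if self.kind == "dirichlet":
            return rng.dirichlet(np.asarray(p, dtype=float))
        raise ValidationError(f"no sampler for kind {self.kind!r}")


def beta_from_mean_se(mean: float, se: float) -> DistributionSpec:
    """Method-of-moments beta spec for a probability/utility with given mean and SE."""
    if not 0 < mean < 1:
        raise ValidationError("beta moment matching needs mean in (0,1)")
    v = se ** 2
    vmax = mean * (1 - mean)
    if v >= vmax:
        raise ValidationError("SE too large for a beta distribution at this mean")
    nu = vmax / v - 1.0
    return DistributionSpec(kind="beta", parameters=[mean * nu, (1 - mean) * nu])


def gamma_from_mean_se(mean: float, se: float) -> DistributionSpec:
    """Method-of-moments gamma spec for a non-negative cost with given mean and SE."""
    if mean <= 0 or se <= 0:
        raise ValidationError("gamma moment matching needs positive mean and SE")
    shape = (mean / se) ** 2
    return DistributionSpec(kind="gamma", parameters=[shape, mean / shape])


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------

class LifeTable:
    """Age-indexed annual all-cause mortality rates.

    Lookup is piecewise constant and total: an age beyond the last row returns
    the last rate; ages below the first row return the first rate.
    """

    def __init__(self, ages: np.ndarray, rates: np.ndarray):
        ages = np.asarray(ages, dtype=float)
        rates = np.asarray(rates, dtype=float)
        if ages.ndim != 1 or ages.shape != rates.shape or len(ages) == 0:
            raise ValidationError("life table needs matching 1-d age and rate arrays")
        if np.any(np.diff(ages) <= 0):
            raise ValidationError("life-table ages must be strictly increasing")
        if np.any((rates < 0) | (rates > 1)):
            raise ValidationError("life-table rates must lie in [0, 1]")
        self.ages = ages
        self.rates = rates

    def rate(self, age: float) -> float:
        """Annual mortality rate at ``age`` (piecewise constant)."""
        idx = int(np.searchsorted(self.ages, age, side="right")) - 1
        idx = min(max(idx, 0), len(self.ages) - 1)
        return float(self.rates[idx])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        expected = {"age", "annual_mortality_rate"}
        if set(df.columns) != expected:
            raise ValidationError(
                f"life table CSV must have columns {sorted(expected)}, got {list(df.columns)}"
            )
        return cls(df["age"].to_numpy(), df["annual_mortality_rate"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"age": self.ages.astype(int), "annual_mortality_rate": self.rates}
        ).to_csv(path, index=False)

    def life_expectancy(self, from_age: float, max_years: int = 120) -> float:
        """Remaining life expectancy (years) by discrete annual survival product."""
        surv = 1.0
        total = 0.0
        for k in range(max_years):
            p_die = -math.expm1(-self.rate(from_age + k))
            # person-years this year approximated mid-year for the dying
            total += surv * (1.0 - p_die) + surv * p_die * 0.5
            surv *= 1.0 - p_die
        return total


# ---------------------------------------------------------------------------
# economic settings & parameter set
# ---------------------------------------------------------------------------

class EconomicSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    discount_rate_annual: float = 0.03
    cycle_length_years: float = 0.25
    horizon_years: float = 10.0
    wtp_grid: list[float] = Field(default_factory=list)
    currency_label: str = "CLP"
    ppp_clp_per_usd: float = 403.87

    @model_validator(mode="after")
    def _check(self) -> "EconomicSettings":
        if not 0 <= self.discount_rate_annual < 1:
            raise ValueError("discount_rate_annual must be in [0, 1)")
        if self.cycle_length_years <= 0:
            raise ValueError("cycle_length_years must be > 0")
        n_cycles = self.horizon_years / self.cycle_length_years
        if abs(n_cycles - round(n_cycles)) > 1e-9:
            raise ValueError("horizon_years must be an integer multiple of cycle length")
        if any(w < 0 for w in self.wtp_grid):
            raise ValueError("wtp_grid values must be >= 0")
        if sorted(self.wtp_grid) != self.wtp_grid:
            raise ValueError("wtp_grid must be sorted ascending")
        return self

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / self.cycle_length_years))


class PopulationSettings(BaseModel):
    """Inputs for scaling per-person value of information to the population.

    ``annual_incident_cases`` is incidence per 100,000 person-years times the
    eligible population (in units of 100,000).
    """

    model_config = ConfigDict(extra="forbid")

    incidence_per_100k: float = 18.9
    eligible_population: float = 20_100_000.0
    evpi_horizon_years: int = 10

    @property
    def annual_incident_cases(self) -> float:
        return self.incidence_per_100k * self.eligible_population / 100_000.0


class TreatmentEffectSpec(BaseModel):
    """Pooled risk-ratio specs for the two synthesized outcomes.

    In a full run these are replaced by posterior draws from the evidence
    synthesis; the specs here carry the point estimates (posterior medians)
    and a lognormal approximation for standalone deterministic use.
    """

    model_config = ConfigDict(extra="forbid")

    rr_remission: DistributionSpec
    rr_relapse: DistributionSpec
    #: restrict the treatment effect to the first N years; None = full horizon
    effect_duration_years: Optional[float] = None


class ParameterSet(BaseModel):
    """The full model parameterization; single source of truth for every stage."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    economics: EconomicSettings
    population: PopulationSettings = Field(default_factory=PopulationSettings)
    start_age: float = 20.0
    start_state_distribution: dict[str, float] = Field(
        default_factory=lambda: {"ACUTE": 1.0}
    )
    #: conditional-on-survival destination shares, per strategy;
    #: "eip" may be omitted and defaults to the "cmht" baseline
    transitions: dict[str, dict[str, dict[str, DistributionSpec]]]
    #: Dirichlet concentrations for PSA, keyed strategy -> from-state ->
    #: destination -> alpha (optional; rows without one sample independently)
    transition_dirichlet: dict[str, dict[str, dict[str, float]]] = Field(
        default_factory=dict
    )
    hsuv: dict[str, DistributionSpec]
    state_costs: dict[str, DistributionSpec]
    program_cost_per_cycle: dict[str, DistributionSpec]
    mortality_hazard_ratio: dict[str, DistributionSpec]
    treatment_effect: TreatmentEffectSpec
    life_table: Optional[LifeTable] = Field(default=None, exclude=True, repr=False)

    # -- validation ---------------------------------------------------------

    @model_validator(mode="after")
    def _check(self) -> "ParameterSet":
        alive_names = [s.name for s in ALIVE_STATES]
        for name, spec in self.hsuv.items():
            if name not in alive_names:
                raise ValueError(f"hsuv: unknown state {name!r}")
            m = spec.mean()
            if not 0 <= m <= 1:
                raise ValueError(f"hsuv.{name}: mean {m} outside [0, 1]")
            if spec.kind == "fixed" and not 0 <= spec.parameters[0] <= 1:
                raise ValueError(f"hsuv.{name}: value outside [0, 1]")
        missing = set(alive_names) - set(self.hsuv)
        if missing:
            raise ValueError(f"hsuv missing for states {sorted(missing)}")

        for name, spec in self.state_costs.items():
            if name not in alive_names:
                raise ValueError(f"state_costs: unknown state {name!r}")
            if spec.mean() < 0:
                raise ValueError(f"state_costs.{name}: negative mean cost")
        missing = set(alive_names) - set(self.state_costs)
        if missing:
            raise ValueError(f"state_costs missing for states {sorted(missing)}")

        for name, spec in self.mortality_hazard_ratio.items():
            if name not in alive_names:
                raise ValueError(f"mortality_hazard_ratio: unknown state {name!r}")
            if spec.mean() <= 0:
                raise ValueError(f"mortality_hazard_ratio.{name}: must be > 0")
        missing = set(alive_names) - set(self.mortality_hazard_ratio)
        if missing:
            raise ValueError(f"mortality_hazard_ratio missing for {sorted(missing)}")

        for strat in self.program_cost_per_cycle:
            if strat not in STRATEGIES:
                raise ValueError(f"program_cost_per_cycle: unknown strategy {strat!r}")
        missing = set(STRATEGIES) - set(self.program_cost_per_cycle)
        if missing:
            raise ValueError(f"program_cost_per_cycle missing for {sorted(missing)}")

        if "cmht" not in self.transitions:
            raise ValueError("transitions must define the 'cmht' baseline")
        for strat, rows in self.transitions.items():
            if strat not in STRATEGIES:
                raise ValueError(f"transitions: unknown strategy {strat!r}")
            for from_name in [s.name for s in ALIVE_STATES]:
                if from_name not in rows:
                    raise ValueError(f"transitions.{strat}: missing row {from_name}")
                row = rows[from_name]
                allowed = {t.name for t in DEFAULT_ADJACENCY[HealthState[from_name]]}
                for to_name, spec in row.items():
                    if to_name not in allowed:
                        raise ValueError(
                            f"transitions.{strat}.{from_name}.{to_name}: "
                            f"not in the adjacency mask {sorted(allowed)}"
                        )
                    m = spec.mean()
                    if not 0 <= m <= 1:
                        raise ValueError(
                            f"transitions.{strat}.{from_name}.{to_name}: "
                            f"probability {m} outside [0, 1]"
                        )
                total = sum(spec.mean() for spec in row.values())
                if abs(total - 1.0) > 1e-6:
                    raise ValueError(
                        f"transitions.{strat}.{from_name}: destination shares sum "
                        f"to {total:.6f}, expected 1"
                    )

        for strat, rows in self.transition_dirichlet.items():
            if strat not in self.transitions:
                raise ValueError(f"transition_dirichlet: no transitions for {strat!r}")
            for from_name, alphas in rows.items():
                row = self.transitions[strat].get(from_name)
                if row is None:
                    raise ValueError(f"transition_dirichlet.{strat}: unknown row {from_name}")
                if set(alphas) != set(row):
                    raise ValueError(
                        f"transition_dirichlet.{strat}.{from_name}: destinations "
                        f"{sorted(alphas)} do not match the row's {sorted(row)}"
                    )
                if any(a <= 0 for a in alphas.values()):
                    raise ValueError(
                        f"transition_dirichlet.{strat}.{from_name}: alphas must be > 0"
                    )

        sdist = self.start_state_distribution
        for name, w in sdist.items():
            if name not in HealthState.__members__:
                raise ValueError(f"start_state_distribution: unknown state {name!r}")
            if w < 0:
                raise ValueError("start_state_distribution weights must be >= 0")
        if abs(sum(sdist.values()) - 1.0) > 1e-9:
            raise ValueError("start_state_distribution must sum to 1")
        return self

    # -- accessors ----------------------------------------------------------

    def strategy_transitions(self, strategy: str) -> dict[str, dict[str, DistributionSpec]]:
        if strategy == "eip" and "eip" not in self.transitions:
            return self.transitions["cmht"]
        return self.transitions[strategy]

    def start_vector(self) -> np.ndarray:
        v = np.zeros(N_STATES)
        for name, w in self.start_state_distribution.items():
            v[HealthState[name]] = w
        return v

    def require_life_table(self) -> LifeTable:
        if self.life_table is None:
            raise ValidationError("ParameterSet has no life table attached")
        return self.life_table


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

def load_parameter_set(config_path, life_table_path) -> ParameterSet:
    """Load and validate a model config (YAML) and life table (CSV).

    Unknown keys anywhere in the config are rejected; every invariant of
    :class:`ParameterSet` is checked on load.
    """
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError("config must be a YAML mapping")
    try:
        ps = ParameterSet.model_validate(raw)
    except Exception as exc:  # pydantic error -> domain error with key names
        raise ValidationError(f"invalid model config: {exc}") from exc
    ps.life_table = LifeTable.from_csv(life_table_path)
    return ps


def save_parameter_set(params: ParameterSet, config_path, life_table_path=None) -> None:
    """Write the config back to YAML (and optionally the life table to CSV)."""
    data = params.model_dump(mode="json", exclude_none=True)
    with open(config_path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    if life_table_path is not None:
        params.require_life_table().to_csv(life_table_path)


def iter_cycle_ages(params: ParameterSet, n_cycles: Optional[int] = None) -> Iterator[float]:
    """Cohort age at the start of each cycle."""
    cl = params.economics.cycle_length_years
    n = params.economics.n_cycles if n_cycles is None else n_cycles
    for t in range(n):
        yield params.start_age + t * cl
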