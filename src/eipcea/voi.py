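"""Value-of-information analysis: EVPI, population EVPI and regression-based
partial EVPI (EVPPI).

EVPI is the expected gain, in net-monetary-benefit units, from resolving all
parameter uncertainty before choosing a strategy:

    EVPI = E[max_s NB_s] - max_s E[NB_s]

computed over the PSA iterations at a fixed willingness-to-pay.  Partial EVPI
for a parameter group uses the single-loop regression estimator: each
strategy's net benefit is regressed on the group's sampled values with an
additive B-spline basis, and the conditional-expectation surfaces replace the
raw net benefits in the EVPI formula.  Standard errors come from a
nonparametric bootstrap over iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np
from scipy.interpolate import BSpline

from .params import ValidationError
from .psa import PSAResult


@dataclass
class EVPPIEstimate:
    group: str
    estimate: float
    se: float


@dataclass
class VOIResult:
    wtp: float
    evpi_per_person: float
    annual_incident_cases: float
    population_years: int
    discount_rate: float
    population_evpi: float
    evppi: list[EVPPIEstimate]

    def to_dict(self) -> dict:
        return {
            "lambda": self.wtp,
            "evpi_per_person": self.evpi_per_person,
            "annual_incident_cases": self.annual_incident_cases,
            "population_years": self.population_years,
            "discount_rate": self.discount_rate,
            "population_evpi": self.population_evpi,
            "evppi": [
                {"group": e.group, "estimate": e.estimate, "se": e.se}
                for e in self.evppi
            ],
        }


def evpi(nb: np.ndarray) -> float:
    """Per-person EVPI from an iterations x strategies net-benefit matrix."""
    nb = np.asarray(nb, dtype=float)
    if nb.ndim != 2 or nb.shape[1] < 2:
        raise ValidationError("NB matrix must be iterations x (>=2) strategies")
    if not np.all(np.isfinite(nb)):
        raise ValidationError("NB matrix contains non-finite entries")
    value = float(np.mean(nb.max(axis=1)) - nb.mean(axis=0).max())
    return max(value, 0.0)


def population_evpi(
    evpi_per_person: float,
    annual_incident_cases: float,
    years: int,
    r: float,
) -> float:
    """Scale per-person EVPI to the incident population over a horizon.

    The affected population is the annual incident cohort accruing for
    ``years`` years, discounted from t = 0 (current year undiscounted):

        EVPI_pop = EVPI x sum_{t=0}^{years-1} incidence / (1+r)^t
    """
    if evpi_per_person < 0 or annual_incident_cases < 0 or years < 0 or r < 0:
        raise ValidationError("population EVPI inputs must be non-negative")
    weights = (1.0 + r) ** (-np.arange(years))
    return float(evpi_per_person * annual_incident_cases * weights.sum())


# ---------------------------------------------------------------------------
# EVPPI by additive spline regression
# ---------------------------------------------------------------------------

def _spline_basis(x: np.ndarray, df: int = 5) -> np.ndarray:
    """Cubic B-spline basis with interior knots at quantiles (no intercept).

    Values outside the training range (bootstrap resamples) are clipped to the
    boundary knots.
    """
    k = 3
    n_interior = max(df - k, 1)
    probs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, probs)
    lo, hi = float(x.min()), float(x.max())
    t = np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])
    xc = np.clip(x, lo, hi)
    design = BSpline.design_matrix(xc, t, k).toarray()
    return design[:, 1:]  # drop one column; the model adds its own intercept


def _fitted_nb(nb: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-strategy OLS fits of NB on the design matrix; returns fitted values."""
    n = nb.shape[0]
    Xd = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xd, nb, rcond=None)
    return Xd @ beta


def evppi_from_nb(
    nb: np.ndarray,
    theta: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
    df: int = 5,
) -> tuple[float, float]:
    """Regression EVPPI for parameters ``theta`` (iterations x params).

    Returns (estimate, bootstrap SE).  Zero-variance parameter columns are
    dropped; if none remain the estimate is 0 with a warning.
    """
    nb = np.asarray(nb, dtype=float)
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[0] != nb.shape[0]:
        theta = theta.T
    keep = [j for j in range(theta.shape[1]) if np.std(theta[:, j]) > 0]
    if not keep:
        warnings.warn("EVPPI group has zero variance; estimate is 0")
        return 0.0, 0.0
    X = np.column_stack([_spline_basis(theta[:, j], df=df) for j in keep])

    fitted = _fitted_nb(nb, X)
    est = float(np.mean(fitted.max(axis=1)) - fitted.mean(axis=0).max())
    est = max(est, 0.0)

    rng = np.random.default_rng(seed)
    n = nb.shape[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        fb = _fitted_nb(nb[idx], X[idx])
        boots[b] = max(float(np.mean(fb.max(axis=1)) - fb.mean(axis=0).max()), 0.0)
    return est, float(boots.std(ddof=1))


def evppi(
    psa: PSAResult,
    wtp: float,
    group: Sequence[str],
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """EVPPI of a named parameter group from a PSA result.

    ``group`` lists column names of the PSA's per-iteration parameter record.
    """
    missing = [g for g in group if g not in psa.records.columns]
    if missing:
        raise ValidationError(f"unknown parameter names in group: {missing}")
    theta = psa.records.loc[:, list(group)].to_numpy()
    return evppi_from_nb(psa.nb_matrix(wtp), theta, n_boot=n_boot, seed=seed)


DEFAULT_GROUPS: dict[str, Sequence[str]] = {
    "treatment_effects": ("rr_remission", "rr_relapse"),
    "utilities": (
        "hsuv.ACUTE",
        "hsuv.REMISSION",
        "hsuv.RELAPSE",
        "hsuv.RESISTANT",
        "hsuv.PNS",
    ),
    "state_costs": (
        "cost.ACUTE",
        "cost.REMISSION",
        "cost.RELAPSE",
        "cost.RESISTANT",
        "cost.PNS",
    ),
    "program_costs": ("program_cost.eip", "program_cost.cmht"),
}


def voi_analysis(
    psa: PSAResult,
    wtp: float,
    annual_incident_cases: float,
    years: int = 10,
    r: float = 0.03,
    groups: Optional[dict[str, Sequence[str]]] = None,
    n_boot: int = 200,
    seed: int = 0,
) -> VOIResult:
    """Full VOI read-out: EVPI, population EVPI and per-group EVPPI."""
    nb = psa.nb_matrix(wtp)
    per_person = evpi(nb)
    pop = population_evpi(per_person, annual_incident_cases, years, r)
    groups = DEFAULT_GROUPS if groups is None else groups
    estimates = []
    for name, cols in groups.items():
        cols = [c for c in cols if c in psa.records.columns]
        if not cols:
            continue
        est, se = evppi(psa, wtp, cols, n_boot=n_boot, seed=seed)
        estimates.append(EVPPIEstimate(group=name, estimate=est, se=se))
    return VOIResult(
        wtp=wtp,
        evpi_per_person=per_person,
        annual_incident_cases=annual_incident_cases,
        population_years=years,
        discount_rate=r,
        population_evpi=pop,
        evppi=estimates,
    )
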