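"""Incremental cost-effectiveness analysis: ICER, dominance, net monetary
benefit, acceptability curves and cost-effectiveness-plane summaries.

Conventions: increments are EIP minus CMHT (ΔC = C_EIP − C_CMHT,
ΔE = E_EIP − E_CMHT); net monetary benefit at willingness-to-pay λ is
NB = λ·ΔE − ΔC.  The ICER ΔC/ΔE is only reported in the trade-off quadrants;
dominance is reported instead when one strategy is at least as good on both
axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd

from .markov import StrategyOutcome
from .params import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .psa import PSAResult


@dataclass
class IncrementalResult:
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    dominance: str  # 'dominant' | 'dominated' | 'trade-off NE' | 'trade-off SW' | 'no difference'
    eip: StrategyOutcome
    cmht: StrategyOutcome

    def to_dict(self) -> dict:
        return {
            "cost_eip": self.eip.cost_discounted,
            "cost_cmht": self.cmht.cost_discounted,
            "qaly_eip": self.eip.qaly_discounted,
            "qaly_cmht": self.cmht.qaly_discounted,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "dominance": self.dominance,
        }


def incremental_analysis(eip: StrategyOutcome, cmht: StrategyOutcome) -> IncrementalResult:
    """ΔC, ΔE, ICER and dominance classification for EIP vs CMHT."""
    if abs(eip.horizon_years - cmht.horizon_years) > 1e-9:
        raise ValidationError(
            f"mismatched horizons: {eip.horizon_years} vs {cmht.horizon_years} years"
        )
    dc = eip.cost_discounted - cmht.cost_discounted
    de = eip.qaly_discounted - cmht.qaly_discounted

    if dc == 0 and de == 0:
        return IncrementalResult(dc, de, None, "no difference", eip, cmht)
    if dc <= 0 and de >= 0:
        # cheaper and at least as effective: ICER misleading, not reported
        return IncrementalResult(dc, de, None, "dominant", eip, cmht)
    if dc >= 0 and de <= 0:
        return IncrementalResult(dc, de, None, "dominated", eip, cmht)
    quadrant = "trade-off NE" if de > 0 else "trade-off SW"
    return IncrementalResult(dc, de, dc / de, quadrant, eip, cmht)


def net_benefit(delta_qaly: float, delta_cost: float, wtp: float) -> float:
    """Incremental net monetary benefit NB = λ·ΔE − ΔC."""
    if wtp < 0:
        raise ValidationError("willingness-to-pay must be >= 0")
    return wtp * delta_qaly - delta_cost


def strategy_net_benefit(outcome: StrategyOutcome, wtp: float) -> float:
    """Per-strategy net monetary benefit λ·E − C."""
    return wtp * outcome.qaly_discounted - outcome.cost_discounted


def ceac(psa: "PSAResult", wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay λ, the fraction of PSA iterations in which
    EIP has the strictly highest net benefit; exact ties contribute 0.5.
    Returns a DataFrame with columns ``lambda`` and ``prob_eip``.
    """
    if len(wtp_grid) == 0:
        raise ValidationError("wtp_grid must not be empty")
    de = psa.delta_qaly()
    dc = psa.delta_cost()
    if de.size == 0:
        raise ValidationError("PSA has no iterations")
    rows = []
    for lam in wtp_grid:
        nb = lam * de - dc
        prob = float(np.mean((nb > 0) + 0.5 * (nb == 0)))
        rows.append({"lambda": float(lam), "prob_eip": prob})
    return pd.DataFrame(rows)


def quadrant_shares(psa: "PSAResult") -> dict[str, float]:
    """Cost-effectiveness-plane quadrant proportions of the PSA cloud.

    NE: ΔE>0, ΔC>0 (more effective, more costly); SE: ΔE>0, ΔC<0 (EIP
    dominates); NW: ΔE<0, ΔC>0 (CMHT dominates); SW: ΔE<0, ΔC<0.  Boundary
    points (either increment exactly zero) split their mass evenly between
    the adjacent quadrants so the shares always sum to 1.
    """
    de = psa.delta_qaly()
    dc = psa.delta_cost()
    n = de.size
    # weight of each draw toward the E>0 (resp. C>0) half, ties get 1/2
    we = (de > 0) + 0.5 * (de == 0)
    wc = (dc > 0) + 0.5 * (dc == 0)
    ne = float(np.sum(we * wc)) / n
    se = float(np.sum(we * (1 - wc))) / n
    nw = float(np.sum((1 - we) * wc)) / n
    sw = float(np.sum((1 - we) * (1 - wc))) / n
    return {"NE": ne, "SE": se, "NW": nw, "SW": sw}


def plane_frame(psa: "PSAResult") -> pd.DataFrame:
    """Per-iteration incremental pairs for the cost-effectiveness plane CSV."""
    return pd.DataFrame(
        {
            "iter": np.arange(psa.n_iterations),
            "delta_qaly": psa.delta_qaly(),
            "delta_cost": psa.delta_cost(),
        }
    )
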