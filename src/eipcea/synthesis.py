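"""Power-prior Bayesian random-effects binomial meta-analysis.

Pools aggregate two-arm studies with a single-arm observational cohort whose
likelihood contribution is raised to a weight ``a0`` in [0, 1] (the power
prior): a0 = 0 discards the cohort, a0 = 1 treats it as an ordinary study.

Model (arm-level binomial likelihood, log link):

    events_control_i   ~ Binomial(n_control_i,   exp(phi_i))
    events_treatment_i ~ Binomial(n_treatment_i, exp(phi_i + delta_i))
    delta_i ~ Normal(mu, tau^2)          (exchangeable study effects, log RR)
    mu  ~ Normal(0, 1.5^2)
    tau ~ Half-Normal(0.5)
    phi_i ~ Normal(log 0.3, 1.5^2)       (per-study baseline log risk)

so the pooled risk ratio is RR = exp(mu).  Arm risks exp(phi) and
exp(phi + delta) are constrained below 1 by rejecting draws outside the
support.  The single-arm cohort enters the contrast against a pseudo-control
built from a configurable external control proportion; the whole cohort
study's log-likelihood (both arms) is multiplied by a0.

Posterior sampling uses an affine-invariant ensemble sampler (emcee).  The
walker ensemble is split into four groups to compute split-R-hat and
effective sample size with arviz; non-convergence on mu raises (or flags,
when ``strict=False``).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .params import ValidationError

# weakly informative hyperpriors on the log-RR scale
MU_PRIOR_SD = 1.5
TAU_PRIOR_SCALE = 0.5
PHI_PRIOR_MEAN = float(np.log(0.3))
PHI_PRIOR_SD = 1.5

RHAT_LIMIT = 1.05


class ConvergenceError(RuntimeError):
    """MCMC did not converge (split-R-hat on mu above the limit)."""


@dataclass
class StudyArmData:
    """Aggregate two-arm study counts (treatment = EIP, control = CMHT)."""

    study_id: str
    events_treatment: float
    n_treatment: float
    events_control: float
    n_control: float

    def __post_init__(self):
        for ev, n, arm in (
            (self.events_treatment, self.n_treatment, "treatment"),
            (self.events_control, self.n_control, "control"),
        ):
            if n <= 0:
                raise ValidationError(f"{self.study_id}/{arm}: n must be > 0")
            if not 0 <= ev <= n:
                raise ValidationError(f"{self.study_id}/{arm}: events must be in [0, n]")

    def has_zero_cell(self) -> bool:
        return (
            self.events_treatment == 0
            or self.events_control == 0
            or self.events_treatment == self.n_treatment
            or self.events_control == self.n_control
        )


@dataclass
class CohortEvidence:
    """Single-arm observational cohort counts for one outcome.

    ``control_proportion`` sets the pseudo-control event proportion used to
    form the within-study contrast (the cohort has no randomized comparator).
    """

    events: float
    n: float
    outcome: str  # 'remission' | 'relapse'
    control_proportion: float

    def __post_init__(self):
        if self.n <= 0 or not 0 <= self.events <= self.n:
            raise ValidationError("cohort counts must satisfy 0 <= events <= n, n > 0")
        if not 0 < self.control_proportion < 1:
            raise ValidationError("control_proportion must be in (0, 1)")

    def as_study(self) -> StudyArmData:
        return StudyArmData(
            study_id="cohort",
            events_treatment=self.events,
            n_treatment=self.n,
            events_control=self.control_proportion * self.n,
            n_control=self.n,
        )


@dataclass
class SamplerSettings:
    """Ensemble-sampler configuration.

    The ensemble of ``n_walkers`` is split into ``n_chain_groups`` groups for
    split-R-hat; kept draws = n_walkers x (n_steps - n_burn) / thin.
    """

    n_walkers: int = 32
    n_steps: int = 3000
    n_burn: int = 1500
    thin: int = 5
    n_chain_groups: int = 4
    seed: int = 0
    strict: bool = True

    def __post_init__(self):
        if self.n_walkers % self.n_chain_groups:
            raise ValidationError("n_walkers must be divisible by n_chain_groups")
        if not 0 < self.n_burn < self.n_steps:
            raise ValidationError("need 0 < n_burn < n_steps")


@dataclass
class PosteriorSummary:
    """Pooled risk-ratio posterior: median, 95% CrI, draws and diagnostics."""

    outcome: str
    a0: float
    rr_median: float
    rr_lo95: float
    rr_hi95: float
    rhat_mu: float
    ess_mu: float
    converged: bool
    rr_draws: np.ndarray = field(repr=False)
    mu_draws: np.ndarray = field(repr=False)
    tau_draws: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "a0": self.a0,
            "rr_median": self.rr_median,
            "rr_lo95": self.rr_lo95,
            "rr_hi95": self.rr_hi95,
            "rhat_mu": self.rhat_mu,
            "ess_mu": self.ess_mu,
            "converged": self.converged,
            "n_draws": int(self.rr_draws.size),
        }


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def continuity_correct(studies: Sequence[StudyArmData]) -> list[StudyArmData]:
    """Add 0.5 to both arms' cells of any study with a zero cell."""
    out = []
    for s in studies:
        if s.has_zero_cell():
            out.append(
                StudyArmData(
                    study_id=s.study_id,
                    events_treatment=s.events_treatment + 0.5,
                    n_treatment=s.n_treatment + 1.0,
                    events_control=s.events_control + 0.5,
                    n_control=s.n_control + 1.0,
                )
            )
        else:
            out.append(s)
    return out


def load_study_csv(path, outcome: Optional[str] = None) -> tuple[list[StudyArmData], Optional[tuple[float, float]]]:
    """Read a `study_id,arm,events,n` CSV (arm in {eip, control, cohort}).

    Returns the two-arm studies plus the cohort counts (events, n) if rows
    with arm == 'cohort' are present.  An optional ``outcome`` column is
    filtered when ``outcome`` is given (one file per outcome otherwise).
    """
    df = pd.read_csv(path)
    required = {"study_id", "arm", "events", "n"}
    if not required.issubset(df.columns):
        raise ValidationError(f"study CSV must have columns {sorted(required)}")
    if outcome is not None and "outcome" in df.columns:
        df = df[df["outcome"] == outcome]
    studies = []
    cohort = None
    for sid, grp in df.groupby("study_id", sort=False):
        arms = dict(zip(grp["arm"], zip(grp["events"], grp["n"])))
        if "cohort" in arms:
            ev, n = arms["cohort"]
            cohort = (float(ev), float(n))
            continue
        if not {"eip", "control"} <= set(arms):
            raise ValidationError(f"study {sid}: needs both 'eip' and 'control' arms")
        studies.append(
            StudyArmData(
                study_id=str(sid),
                events_treatment=float(arms["eip"][0]),
                n_treatment=float(arms["eip"][1]),
                events_control=float(arms["control"][0]),
                n_control=float(arms["control"][1]),
            )
        )
    return studies, cohort


# ---------------------------------------------------------------------------
# posterior
# ---------------------------------------------------------------------------

def _binom_loglik(events: np.ndarray, n: np.ndarray, logp: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood (constant included; tolerates non-integer counts)."""
    const = gammaln(n + 1) - gammaln(events + 1) - gammaln(n - events + 1)
    return const + events * logp + (n - events) * np.log1p(-np.exp(logp))


class _PowerPriorPosterior:
    """Vectorized log-posterior over walker positions.

    Non-centered parameterization for the exchangeable study effects:
    parameter vector [mu, tau, phi_1..phi_k, eta_1..eta_k] with
    delta_i = mu + tau * eta_i, eta_i ~ Normal(0, 1).  The cohort (if
    present, weighted by a0) is study k.
    """

    def __init__(self, studies: Sequence[StudyArmData], weights: np.ndarray):
        self.k = len(studies)
        self.ndim = 2 + 2 * self.k
        self.w = np.asarray(weights, dtype=float)
        self.ev_t = np.array([s.events_treatment for s in studies])
        self.n_t = np.array([s.n_treatment for s in studies])
        self.ev_c = np.array([s.events_control for s in studies])
        self.n_c = np.array([s.n_control for s in studies])

    def delta(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        return theta[:, [0]] + theta[:, [1]] * theta[:, 2 + self.k :]

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        mu = theta[:, 0]
        tau = theta[:, 1]
        phi = theta[:, 2 : 2 + self.k]
        eta = theta[:, 2 + self.k :]
        delta = mu[:, None] + tau[:, None] * eta

        logp = np.full(theta.shape[0], -np.inf)
        ok = (tau >= 0) & np.all(phi < 0, axis=1) & np.all(phi + delta < 0, axis=1)
        if not np.any(ok):
            return logp if theta.shape[0] > 1 else logp[0]

        mu_ok, tau_ok = mu[ok], tau[ok]
        phi_ok, eta_ok, delta_ok = phi[ok], eta[ok], delta[ok]

        lp = -0.5 * (mu_ok / MU_PRIOR_SD) ** 2
        lp += -0.5 * (tau_ok / TAU_PRIOR_SCALE) ** 2  # half-normal (tau >= 0)
        lp += np.sum(-0.5 * ((phi_ok - PHI_PRIOR_MEAN) / PHI_PRIOR_SD) ** 2, axis=1)
        lp += np.sum(-0.5 * eta_ok ** 2, axis=1)

        ll_c = _binom_loglik(self.ev_c, self.n_c, phi_ok)
        ll_t = _binom_loglik(self.ev_t, self.n_t, phi_ok + delta_ok)
        lp += np.sum(self.w * (ll_c + ll_t), axis=1)

        logp[ok] = lp
        return logp if theta.shape[0] > 1 else logp[0]


def _initial_positions(
    post: _PowerPriorPosterior, settings: SamplerSettings, rng: np.random.Generator
) -> np.ndarray:
    """Start walkers near the empirical study estimates with small jitter."""
    p_c = np.clip(post.ev_c / post.n_c, 1e-3, 0.99)
    p_t = np.clip(post.ev_t / post.n_t, 1e-3, 0.99)
    phi0 = np.log(p_c)
    delta0 = np.log(p_t) - np.log(p_c)
    mu0 = float(np.mean(delta0))
    tau0 = 0.2
    eta0 = (delta0 - mu0) / tau0
    center = np.concatenate([[mu0, tau0], phi0, eta0])
    # spread scaled to each arm's information so narrow (large-n) posteriors
    # start inside the typical set
    se_c = np.sqrt((1 - p_c) / np.maximum(post.ev_c, 1.0))
    se_t = np.sqrt((1 - p_t) / np.maximum(post.ev_t, 1.0))
    se_d = np.sqrt(se_c**2 + se_t**2)
    scale = np.concatenate(
        [[max(float(np.min(se_d)), 1e-3), 0.05], np.maximum(se_c, 1e-4),
         np.full(post.k, 0.3)]
    )
    pos = center + scale * rng.standard_normal((settings.n_walkers, post.ndim))
    pos[:, 1] = np.abs(pos[:, 1]) + 1e-3
    # keep control log-risks strictly negative at start
    pos[:, 2 : 2 + post.k] = np.minimum(pos[:, 2 : 2 + post.k], -0.02)
    # pull eta toward 0 where the implied treatment risk would exceed 1
    delta = pos[:, [0]] + pos[:, [1]] * pos[:, 2 + post.k :]
    bad = pos[:, 2 : 2 + post.k] + delta >= 0
    pos[:, 2 + post.k :][bad] = 0.0
    return pos


def fit_power_prior_meta(
    studies: Sequence[StudyArmData],
    cohort: Optional[CohortEvidence],
    a0: float,
    settings: Optional[SamplerSettings] = None,
    outcome: str = "remission",
) -> PosteriorSummary:
    """Fit the power-prior random-effects model and summarize exp(mu).

    ``cohort=None`` (or a0 = 0, which zeroes the cohort likelihood) gives the
    aggregate-only analysis; a0 = 1 treats the cohort as one more study.
    """
    if len(studies) < 2:
        raise ValidationError("need at least 2 aggregate studies")
    if not 0 <= a0 <= 1:
        raise ValidationError("power-prior weight a0 must be in [0, 1]")
    settings = settings or SamplerSettings()

    all_studies = list(studies)
    weights = [1.0] * len(studies)
    if cohort is not None and a0 > 0:
        all_studies.append(cohort.as_study())
        weights.append(a0)
    all_studies = continuity_correct(all_studies)

    post = _PowerPriorPosterior(all_studies, np.array(weights))
    # ensemble moves need >= 2x dimensions; round up to a chain-group multiple
    g = settings.n_chain_groups
    n_walkers = max(settings.n_walkers, 2 * post.ndim)
    n_walkers += (-n_walkers) % g
    if n_walkers != settings.n_walkers:
        settings = replace(settings, n_walkers=n_walkers)
    rng = np.random.default_rng(settings.seed)
    pos = _initial_positions(post, settings, rng)

    sampler = emcee.EnsembleSampler(
        settings.n_walkers,
        post.ndim,
        post,
        vectorize=True,
        # differential-evolution moves mix far better than the default
        # stretch move on this correlated, constrained posterior
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    state_rng = np.random.RandomState(settings.seed)
    sampler.random_state = state_rng.get_state()
    sampler.run_mcmc(pos, settings.n_steps, progress=False)

    # chain: (n_steps, n_walkers, ndim) -> kept (n_keep, n_walkers)
    mu_chain = sampler.get_chain()[settings.n_burn :: settings.thin, :, 0]
    tau_chain = sampler.get_chain()[settings.n_burn :: settings.thin, :, 1]

    # split walkers into groups acting as chains for split-R-hat / ESS
    g = settings.n_chain_groups
    per = settings.n_walkers // g
    mu_grouped = np.stack(
        [mu_chain[:, i * per : (i + 1) * per].T.reshape(-1) for i in range(g)]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(mu_grouped)  # (chain, draw)
        rhat = float(np.asarray(az.rhat(ds)["x"]).squeeze())
        ess = float(np.asarray(az.ess(ds)["x"]).squeeze())

    converged = rhat <= RHAT_LIMIT
    if not converged and settings.strict:
        raise ConvergenceError(
            f"split-R-hat on mu = {rhat:.3f} > {RHAT_LIMIT} "
            f"(outcome={outcome}, a0={a0}); increase n_steps"
        )

    mu_draws = mu_chain.reshape(-1)
    tau_draws = tau_chain.reshape(-1)
    rr = np.exp(mu_draws)
    lo, med, hi = np.percentile(rr, [2.5, 50.0, 97.5])
    return PosteriorSummary(
        outcome=outcome,
        a0=a0,
        rr_median=float(med),
        rr_lo95=float(lo),
        rr_hi95=float(hi),
        rhat_mu=rhat,
        ess_mu=ess,
        converged=converged,
        rr_draws=rr,
        mu_draws=mu_draws,
        tau_draws=tau_draws,
    )


def weight_sensitivity_curve(
    studies: Sequence[StudyArmData],
    cohort: CohortEvidence,
    a0_grid: Sequence[float],
    settings: Optional[SamplerSettings] = None,
    outcome: str = "remission",
) -> list[PosteriorSummary]:
    """Refit the synthesis over a grid of power-prior weights.

    The same sampler seed is used at every grid point so differences across
    the curve reflect the weight, not Monte Carlo noise.
    """
    if any(not 0 <= a <= 1 for a in a0_grid):
        raise ValidationError("a0 grid values must be in [0, 1]")
    return [
        fit_power_prior_meta(studies, cohort, a0, settings=settings, outcome=outcome)
        for a0 in a0_grid
    ]


def posterior_rr_draws(
    summary: PosteriorSummary,
    n: int,
    seed: int,
    resample: bool = True,
) -> np.ndarray:
    """n reproducible risk-ratio draws from a fitted posterior.

    With ``resample`` the stored draws are resampled with replacement;
    otherwise n must not exceed the stored draw count (thinning).
    """
    stored = summary.rr_draws
    if n <= 0:
        raise ValidationError("n must be >= 1")
    if not resample and n > stored.size:
        raise ValidationError(
            f"requested {n} draws but only {stored.size} stored; enable resampling"
        )
    rng = np.random.default_rng(seed)
    if resample:
        return stored[rng.integers(0, stored.size, size=n)]
    idx = np.linspace(0, stored.size - 1, n).astype(int)
    return stored[idx]


def curve_frame(summaries: Sequence[PosteriorSummary]) -> pd.DataFrame:
    """Forest-plot-ready table (`a0,median,lo95,hi95`)."""
    return pd.DataFrame(
        [
            {
                "a0": s.a0,
                "median": s.rr_median,
                "lo95": s.rr_lo95,
                "hi95": s.rr_hi95,
            }
            for s in summaries
        ]
    )


def fit_cache_key(
    studies: Sequence[StudyArmData],
    cohort: Optional[CohortEvidence],
    a0: float,
    settings: SamplerSettings,
) -> str:
    """Stable hash of (data, priors, a0, sampler settings) for posterior caching."""
    payload = {
        "studies": [
            [s.study_id, s.events_treatment, s.n_treatment, s.events_control, s.n_control]
            for s in studies
        ],
        "cohort": None
        if cohort is None
        else [cohort.events, cohort.n, cohort.outcome, cohort.control_proportion],
        "a0": a0,
        "priors": [MU_PRIOR_SD, TAU_PRIOR_SCALE, PHI_PRIOR_MEAN, PHI_PRIOR_SD],
        "sampler": [
            settings.n_walkers,
            settings.n_steps,
            settings.n_burn,
            settings.thin,
            settings.seed,
        ],
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()
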