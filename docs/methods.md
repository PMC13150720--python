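# Methods

This note documents the models implemented in `eipcea`, the choices made
where the design was genuinely open, and what the synthetic reference
fixture does and does not establish.

## Markov cohort model

A closed cohort of first-episode psychosis (FEP) patients enters at age 20
in the acute state and moves between six mutually exclusive states — ACUTE,
REMISSION, RELAPSE, RESISTANT (treatment-resistant schizophrenia), PNS
(persistent negative symptoms) and DEAD — in cycles of 0.25 years over a
10-year base horizon (40 transitions). The adjacency of the live states is
configuration data, not code; the default allows
ACUTE→{ACUTE, REMISSION, RESISTANT, PNS},
REMISSION→{REMISSION, RELAPSE, PNS}, RELAPSE→{REMISSION, RELAPSE, RESISTANT},
RESISTANT→{RESISTANT, REMISSION} (clozapine response) and
PNS→{PNS, RELAPSE}, with death reachable from every state.

**Mortality first (competing risks).** Per cycle, each live state's death
probability is `1 − exp(−rate(age) · HR_state · cycle_length)` where
`rate(age)` is the annual all-cause life-table rate (piecewise constant in
age, last rate extended beyond the table) and `HR_state ≥ 1` a state
hazard ratio. The surviving mass `1 − p_death` is then allocated across the
allowed destinations in proportion to the row's conditional-on-survival
destination shares, which sum to 1 by validation.

**Treatment effects.** The pooled risk ratios from the evidence synthesis
enter on the EIP arm only: RR_remission multiplies the ACUTE→REMISSION share
and RR_relapse the REMISSION→RELAPSE share, each capped at 1 (capping events
are counted and surfaced in PSA diagnostics) with the complement
redistributed proportionally over the row's other destinations. Applying the
relapse RR only to the remission→relapse transition (not to relapse
recurrence), and letting the effects persist over the whole horizon, are
deliberate defaults; effect duration is config-limitable to the first N
years.

**Accounting.** A cycle is valued at its *starting* occupancy: QALYs are
Σ_cycles Σ_states occupancy·HSUV·cycle_length·d(t) with
d(t) = (1+r)^(−t·cycle_length) and r = 0.03/year; costs analogously from
per-cycle state costs plus the strategy's programme cost times the alive
fraction. This start-of-cycle convention makes the conservation identity
exact (utility 1, no deaths, r = 0 over 10 years gives exactly 10 QALYs).
No half-cycle correction is applied by default; a trapezoidal within-cycle
average is available as a flag for sensitivity use. The relapse state's cost
folds hospitalization in as a weight (inpatient share × inpatient cost +
outpatient complement) rather than adding a seventh state. The lifetime
scenario runs to cohort age 80.

**Validation oracle.** The deterministic trace is checked against an
agent-level microsimulation (multinomial transitions of 10⁶ agents through
the same matrices). The comparison uses the *exact* standard error of the
microsimulated occupancies, propagated through the chain via
V_{t+1} = Σ_s E[N_s](diag(M_s) − M_sM_sᵀ) + MᵀV_tM, so the 3-SE acceptance
band is calibrated per state and cycle rather than anti-conservative.

## Power-prior evidence synthesis

Aggregate two-arm studies and the single-arm observational cohort are pooled
in a random-effects binomial model on the log risk-ratio scale:

    events_c,i ~ Binomial(n_c,i, exp(φ_i))
    events_t,i ~ Binomial(n_t,i, exp(φ_i + δ_i))
    δ_i ~ Normal(μ, τ²),   RR = exp(μ)

with weakly informative hyperpriors μ ~ N(0, 1.5²), τ ~ Half-Normal(0.5),
φ_i ~ N(log 0.3, 1.5²), and arm risks constrained below 1 by support
rejection. The cohort has no randomized comparator, so it enters the
contrast against a pseudo-control with a configurable external event
proportion; the *whole* cohort study's log-likelihood is multiplied by the
power-prior weight a₀ ∈ [0, 1]. Studies with a zero cell receive a 0.5
continuity correction on both arms of that study only. δ is sampled
non-centered (δ_i = μ + τ·η_i) to avoid the hierarchical funnel.

Sampling uses an emcee ensemble (32 walkers, differential-evolution moves,
3000 steps with 1500 burn-in, thin 5 ≈ 9600 kept draws). The ensemble is
split into 4 walker groups to compute split-R̂ and effective sample size
(arviz); a fit with split-R̂ > 1.05 on μ raises by default (`strict=False`
degrades this to a flagged, non-converged summary). The walker count is
automatically raised to twice the parameter dimension when small settings
are requested. These sampler sizes were chosen for R̂ ≤ 1.02 and stable
posterior medians across seeds on fixture-sized problems (k ≈ 6 studies);
near-degenerate cases (τ → 0 with ultra-precise studies) mix more slowly and
warrant longer chains.

Simulation-based checks: single mega-study recovery of a true RR within 2%;
a₀ = 0 / a₀ = 1 limits statistically indistinguishable from the
aggregate-only and cohort-as-study fits across seeds; and nominal 95%
credible-interval coverage of the true log-RR within 95% ± 5 points over 200
reduced-scale replicates (k = 3 studies, 100–250 per arm — sizes chosen to
keep the replicate study cheap while leaving the posterior data-dominated).

## Economics, PSA and value of information

Increments are EIP − CMHT. The ICER ΔC/ΔE is reported only in the trade-off
quadrants (dominance is reported otherwise) and from unrounded increments.
Net benefit is NB(λ) = λ·ΔE − ΔC; the CEAC reports, per λ, the fraction of
PSA iterations with NB > 0, ties counting one half — measure-zero in
practice but it keeps the curve's λ→0 and λ→∞ limits exact. Quadrant shares
use the same half-weight tie rule and always partition.
Willingness-to-pay benchmarks follow the one-to-three-GDP-per-capita
convention; one GDP per capita (USD 15,923) converts to ≈ 6.43 million CLP
with the purchasing-power-parity factor 403.87 CLP/USD (derivable from the
dual-currency reporting convention; overridable in config).

The PSA draws, per iteration: Dirichlet transition rows (concentrations
keyed by destination name — positional pairing is fragile under config
round-trips), beta utilities, gamma costs, lognormal hazard ratios, and
paired-by-index posterior draws of the two risk ratios. Both strategies run
on the same draw (common random numbers); per-iteration RNG streams are
spawned from the master seed (`SeedSequence`), making results bit-for-bit
reproducible and order-independent. One-way sensitivity pins one parameter
at a bound (transition overrides rescale the rest of the row) and reports
ICER and incremental NB per bound, sorted by NB range.

EVPI is E[maxₛ NBₛ] − maxₛ E[NBₛ] over the PSA at fixed λ, clamped at 0.
Population EVPI multiplies by the discounted incident population
Σ_{t=0}^{Y−1} incidence/(1+r)^t with discounting starting at t = 0 (current
year undiscounted) — a convention that must be fixed for reproducibility;
the default population inputs are an incidence of 18.9 per 100,000
person-years over a 20.1-million population for 10 years. EVPPI uses the
single-loop regression estimator: each strategy's NB is regressed on the
group's sampled values with an additive cubic B-spline basis (5 df per
parameter, knots at quantiles, deterministic fit), and the fitted
conditional expectations replace NB in the EVPI formula; standard errors
come from 200 nonparametric bootstrap resamples. The estimator is validated
against the closed form for linear NB with normal θ, against EVPI for the
full group, and against 0 for an independent dummy parameter.

## Synthetic reference fixture

No real parameter tables or study-level counts are publicly deposited for
this setting, so the fixture is an explicit stand-in, not a reproduction of
any particular service's data. It emulates: k = 6 two-arm studies per outcome (~2000
participants) generated from the random-effects model with true pooled RR
1.33 (remission, τ = 0.15) and 0.70 (relapse, τ = 0.35); an 82-patient
single-arm cohort whose strong relapse signal pulls the pooled relapse RR
toward ~0.5 as a₀ → 1 (mirroring the qualitative weighting pattern the
method is designed to expose); a Gompertz life table rate(age) = 2·10⁻⁵
e^{0.1·age} giving ~60 remaining years at age 20; and a full parameter set
(transition shares, HSUVs 0.50–0.82, per-cycle state costs in 2018 CLP,
mortality hazard ratios 1.5–3.0, EIP programme cost 96,000 CLP/cycle)
calibrated — as a construction-time gate that raises on failure — so the
deterministic base case lands in the north-east quadrant with ΔE ≈ 0.2 QALYs
and an ICER ≈ 5.5 million CLP/QALY over 10 years.

Uncertainty widths (cost CV 20%, HSUV SE 0.04, Dirichlet strength 100,
lognormal σ 0.15 on hazard ratios) are plausible mid-range choices, and
fixture-derived CEAC/EVPI values characterize this parameterization only:
with real, typically tighter, input distributions the decision uncertainty
would shrink. What passing tests establish is that the machinery is
correct (oracle agreement, identities, coverage, reproducibility) — not that
real Chilean data would yield these numbers. Every generated file carries a
SHA-256 in a manifest; loaders can refuse stale fixtures.

## Known limitations

- The cohort's pseudo-control construction (external control proportion) is
  one of several defensible ways to let single-arm evidence inform a
  contrast; it is config-swappable and its proportion is a sensitivity
  parameter in its own right.
- Two strategies only; no efficiency frontier for ≥3 alternatives.
- No EVSI / research-design optimization; VOI stops at EVPI/EVPPI.
- Cohort-level model: patient heterogeneity appears only through the
  microsimulation oracle, not as a modelling feature.
- Problem sizes in the shipped tests (PSA 150–5000 iterations, 200 synthesis
  replicates at k = 3) are the package's default verification scale; all are
  parameters.
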