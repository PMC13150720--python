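# eipcea

Decision-analytic cost-utility modelling of **Early Intervention in Psychosis
(EIP)** services against standard care by **community mental health teams
(CMHT)**, for health economists and mental-health policy analysts evaluating
first-episode psychosis (FEP) care pathways.

The package implements the full evaluation pipeline:

1. **Evidence synthesis** — a Bayesian random-effects binomial meta-analysis
   on the log risk-ratio scale pooling aggregate two-arm studies with a
   single-arm observational cohort whose likelihood is raised to a **power
   prior** weight a₀ ∈ [0, 1] (a₀ = 0 discards the cohort, a₀ = 1 treats it
   as an ordinary study). Yields pooled risk ratios for symptom remission and
   relapse.
2. **Markov cohort model** — six health states (acute episode, remission,
   relapse, treatment-resistant schizophrenia, persistent negative symptoms,
   dead), 3-month cycles, 10-year base horizon. Mortality in every state is
   the age-specific life-table rate times a state hazard ratio; QALYs
   accumulate as occupancy × health-state utility value (HSUV) per cycle,
   costs as occupancy × per-cycle state cost plus a per-strategy programme
   cost, both discounted at 3% per year.
3. **Economics** — incremental analysis
   ICER = (C_EIP − C_CMHT) / (E_EIP − E_CMHT), net monetary benefit
   NB(λ) = λ·ΔE − ΔC, cost-effectiveness acceptability curves and
   cost-effectiveness-plane quadrant shares.
4. **Probabilistic sensitivity analysis** — Monte Carlo over Dirichlet
   transition rows, beta utilities, gamma costs, lognormal hazard ratios and
   the posterior risk-ratio draws, with common random numbers across
   strategies; plus one-way deterministic sensitivity and horizon scenarios.
5. **Value of information** — per-person EVPI = E[maxₛ NBₛ] − maxₛ E[NBₛ],
   population EVPI over the discounted incident FEP population, and
   regression-based partial EVPI (EVPPI) per parameter group with bootstrap
   standard errors.

Because no parameter tables or study-level counts are publicly deposited for
this setting, the package ships a **synthetic-data module** that
generates every input (study CSVs, observational cohort, Gompertz life table
and a fully calibrated reference parameter set) with known ground truth; all
of its values are explicit stand-ins that can be replaced by real data
through the YAML config.

## Worked example

```bash
eipcea simulate-data --out inputs --seed 0
eipcea run-all --config inputs --out results_run --n 2000 --seed 1
```

which prints (synthesis lines from `eipcea synthesize --config inputs --out
synth --seed 1`, then the run-all summary):

```
remission a0=0.0: RR 1.25 (95% CrI 1.12-1.37)
remission a0=0.5: RR 1.24 (95% CrI 1.13-1.36)
remission a0=1.0: RR 1.22 (95% CrI 1.08-1.34)
relapse a0=0.0: RR 0.62 (95% CrI 0.47-0.80)
relapse a0=0.5: RR 0.55 (95% CrI 0.38-0.76)
relapse a0=1.0: RR 0.52 (95% CrI 0.35-0.74)
{
  "base_case": {
    ...
    "delta_cost": 1117289.1039380338,
    "delta_qaly": 0.20326353694248134,
    "icer": 5496751.265595657,
    "dominance": "trade-off NE"
  },
  "quadrants": {"NE": 0.886, "SE": 0.114, "NW": 0.0, "SW": 0.0}
}
```

Reading: fully incorporating the observational cohort moves the pooled
relapse risk ratio from 0.62 to 0.52 (the cohort shows strong relapse
prevention), while remission barely shifts (1.25 → 1.22). At the point
estimates EIP costs an extra 1.12 million Chilean pesos (CLP) per patient
over 10 years and gains 0.20 QALYs, an ICER of about 5.5 million CLP/QALY —
below a willingness-to-pay of one GDP per capita (≈ 6.43 million CLP at the
purchasing-power-parity factor of 403.87 CLP/USD). About 89% of these PSA
iterations land in the north-east quadrant (more effective, more costly) and
the rest in the south-east, where EIP dominates. Per-stage outputs (traces,
CEAC, plane, VOI tables) are written as CSV/JSON under `results_run/`.

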