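"""Run orchestration and report assembly.

Each command writes its outputs (CSV/JSON) under an output directory together
with a ``run_record.json`` capturing the resolved inputs, seeds and package
version, so every emitted number is recomputable from the emitted files
alone.  Fitted posteriors are cached under ``<out>/cache`` keyed by a hash of
(data, priors, a0, sampler settings) so the PSA and VOI stages reuse draws
without refitting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .economics import ceac, plane_frame, quadrant_shares
from .markov import ModelDraw, run_cohort, trace_to_frame
from .params import ParameterSet, load_parameter_set
from .psa import PSAResult, ScenarioSpec, base_case, run_psa, run_scenarios
from .simulate import GDP_PER_CAPITA_CLP, write_fixture
from .synthesis import (
    CohortEvidence,
    PosteriorSummary,
    SamplerSettings,
    curve_frame,
    fit_cache_key,
    fit_power_prior_meta,
    load_study_csv,
    posterior_rr_draws,
    weight_sensitivity_curve,
)
from .voi import voi_analysis

log = logging.getLogger("eipcea")

#: pseudo-control proportions for the single-arm cohort's contrast
DEFAULT_CONTROL_PROPORTIONS = {"remission": 0.45, "relapse": 0.28}


@dataclasses.dataclass
class RunRecord:
    command: str
    config_path: str
    seed: int
    package_version: str
    timestamp: str
    settings: dict
    outputs: list[str] = dataclasses.field(default_factory=list)

    def write(self, outdir: Path) -> None:
        (outdir / "run_record.json").write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        )


def _new_record(command: str, config_path, seed: int, **settings) -> RunRecord:
    return RunRecord(
        command=command,
        config_path=str(config_path),
        seed=seed,
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        settings=settings,
    )


def _load(config_path, life_table_path) -> ParameterSet:
    params = load_parameter_set(config_path, life_table_path)
    log.info(
        "loaded config: horizon %s y, cycle %s y, discount %s",
        params.economics.horizon_years,
        params.economics.cycle_length_years,
        params.economics.discount_rate_annual,
    )
    return params


# ---------------------------------------------------------------------------
# posterior caching
# ---------------------------------------------------------------------------

def _cached_fit(
    studies,
    cohort: Optional[CohortEvidence],
    a0: float,
    settings: SamplerSettings,
    outcome: str,
    cache_dir: Optional[Path],
) -> PosteriorSummary:
    key = fit_cache_key(studies, cohort, a0, settings)
    if cache_dir is not None:
        path = cache_dir / f"posterior_{outcome}_{key[:16]}.npz"
        if path.exists():
            z = np.load(path)
            log.info("posterior cache hit: %s a0=%s", outcome, a0)
            return PosteriorSummary(
                outcome=outcome,
                a0=a0,
                rr_median=float(z["rr_median"]),
                rr_lo95=float(z["rr_lo95"]),
                rr_hi95=float(z["rr_hi95"]),
                rhat_mu=float(z["rhat_mu"]),
                ess_mu=float(z["ess_mu"]),
                converged=bool(z["converged"]),
                rr_draws=z["rr_draws"],
                mu_draws=z["mu_draws"],
                tau_draws=z["tau_draws"],
            )
    summary = fit_power_prior_meta(studies, cohort, a0, settings=settings, outcome=outcome)
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            cache_dir / f"posterior_{outcome}_{key[:16]}.npz",
            rr_median=summary.rr_median,
            rr_lo95=summary.rr_lo95,
            rr_hi95=summary.rr_hi95,
            rhat_mu=summary.rhat_mu,
            ess_mu=summary.ess_mu,
            converged=summary.converged,
            rr_draws=summary.rr_draws,
            mu_draws=summary.mu_draws,
            tau_draws=summary.tau_draws,
        )
    return summary


def synthesize_outcome(
    study_csv,
    outcome: str,
    a0: float,
    seed: int,
    control_proportion: Optional[float] = None,
    settings: Optional[SamplerSettings] = None,
    cache_dir: Optional[Path] = None,
) -> PosteriorSummary:
    """Fit the power-prior synthesis for one outcome from a study CSV."""
    studies, cohort_counts = load_study_csv(study_csv, outcome)
    cohort = None
    if cohort_counts is not None:
        prop = (
            DEFAULT_CONTROL_PROPORTIONS[outcome]
            if control_proportion is None
            else control_proportion
        )
        cohort = CohortEvidence(
            events=cohort_counts[0], n=cohort_counts[1],
            outcome=outcome, control_proportion=prop,
        )
    settings = settings or SamplerSettings(seed=seed)
    return _cached_fit(studies, cohort, a0, settings, outcome, cache_dir)


# ---------------------------------------------------------------------------
# commands
# ---------------------------------------------------------------------------

def cmd_simulate_data(outdir, seed: int = 0) -> RunRecord:
    """Generate the full input fixture under ``outdir``."""
    outdir = Path(outdir)
    manifest = write_fixture(outdir, seed=seed)
    record = _new_record("simulate-data", outdir / "config.yaml", seed)
    record.outputs = sorted(manifest.files) + ["manifest.json"]
    record.write(outdir)
    return record


def cmd_synthesize(
    inputs_dir,
    outdir,
    seed: int = 0,
    a0_grid: Sequence[float] = (0.0, 0.5, 1.0),
    settings: Optional[SamplerSettings] = None,
) -> dict[str, list[PosteriorSummary]]:
    """Power-prior weighting curve for both outcomes; writes JSON + CSVs."""
    inputs_dir, outdir = Path(inputs_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, list[PosteriorSummary]] = {}
    for outcome in ("remission", "relapse"):
        csv_path = inputs_dir / f"studies_{outcome}.csv"
        summaries = [
            synthesize_outcome(
                csv_path, outcome, a0, seed,
                settings=settings or SamplerSettings(seed=seed),
                cache_dir=outdir / "cache",
            )
            for a0 in a0_grid
        ]
        results[outcome] = summaries
        curve_frame(summaries).to_csv(outdir / f"rr_curve_{outcome}.csv", index=False)
        (outdir / f"synthesis_{outcome}.json").write_text(
            json.dumps([s.to_dict() for s in summaries], indent=2)
        )
    record = _new_record(
        "synthesize", inputs_dir / "config.yaml", seed, a0_grid=list(a0_grid)
    )
    record.outputs = sorted(p.name for p in outdir.glob("*.csv"))
    record.write(outdir)
    return results


def cmd_base_case(
    config_path, life_table_path, outdir, seed: int = 0,
    horizon_years: Optional[float] = None,
) -> dict:
    """Deterministic incremental analysis at the point estimates."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = _load(config_path, life_table_path)
    n_cycles = None
    if horizon_years is not None:
        n_cycles = int(round(horizon_years / params.economics.cycle_length_years))
    res = base_case(params, n_cycles=n_cycles)
    summary = res.to_dict()
    (outdir / "base_case.json").write_text(json.dumps(summary, indent=2))

    draw = ModelDraw.from_point_estimates(params)
    for strat in ("eip", "cmht"):
        trace = run_cohort(params, draw, strat, n_cycles=n_cycles)
        trace_to_frame(trace, params.start_age).to_csv(
            outdir / f"trace_{strat}.csv", index=False
        )
    record = _new_record(
        "run-base-case", config_path, seed,
        horizon_years=horizon_years or params.economics.horizon_years,
    )
    record.outputs = ["base_case.json", "trace_eip.csv", "trace_cmht.csv"]
    record.write(outdir)
    return summary


def cmd_run_psa(
    config_path, life_table_path, outdir,
    remission_draws: np.ndarray, relapse_draws: np.ndarray,
    n: int = 5000, seed: int = 0,
) -> PSAResult:
    """PSA + CEAC + plane quadrant shares; writes the full iteration tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = _load(config_path, life_table_path)
    psa = run_psa(params, remission_draws, relapse_draws, n=n, master_seed=seed)

    psa.to_frame().to_csv(outdir / "psa_iterations.csv", index=False)
    psa.records.to_csv(outdir / "psa_parameters.csv", index=False)
    plane_frame(psa).to_csv(outdir / "plane.csv", index=False)
    ceac(psa, params.economics.wtp_grid).to_csv(outdir / "ceac.csv", index=False)
    shares = quadrant_shares(psa)
    (outdir / "quadrants.json").write_text(json.dumps(shares, indent=2))
    if psa.rr_cap_events:
        log.warning("PSA capped RR x p at 1 in %d row applications", psa.rr_cap_events)

    record = _new_record("run-psa", config_path, seed, n=n,
                         rr_cap_events=psa.rr_cap_events)
    record.outputs = ["psa_iterations.csv", "psa_parameters.csv", "plane.csv",
                      "ceac.csv", "quadrants.json"]
    record.write(outdir)
    return psa


def cmd_run_voi(
    params: ParameterSet, psa: PSAResult, outdir,
    wtp: Optional[float] = None, seed: int = 0, n_boot: int = 200,
) -> dict:
    """EVPI / population EVPI / per-group EVPPI from an existing PSA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wtp = GDP_PER_CAPITA_CLP if wtp is None else wtp
    result = voi_analysis(
        psa,
        wtp=wtp,
        annual_incident_cases=params.population.annual_incident_cases,
        years=params.population.evpi_horizon_years,
        r=params.economics.discount_rate_annual,
        n_boot=n_boot,
        seed=seed,
    )
    payload = result.to_dict()
    (outdir / "voi.json").write_text(json.dumps(payload, indent=2))
    return payload


def cmd_full_pipeline(
    inputs_dir, outdir, n_psa: int = 5000, seed: int = 0,
    sampler_settings: Optional[SamplerSettings] = None,
) -> dict:
    """Run every stage on one input directory; one output tree, one seed tree.

    Stages: evidence synthesis (a0 grid for reporting, a0 = 1 feeding the
    model), deterministic base case, PSA, CEAC/quadrants, VOI.
    """
    inputs_dir, outdir = Path(inputs_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(seed).spawn(4)
    sub = lambda i: int(seeds[i].generate_state(1)[0] % (2**31))

    stage = "synthesis"
    try:
        settings = sampler_settings or SamplerSettings(seed=sub(0))
        synth = cmd_synthesize(
            inputs_dir, outdir / "synthesis", seed=settings.seed, settings=settings
        )
        rem = next(s for s in synth["remission"] if s.a0 == 1.0)
        rel = next(s for s in synth["relapse"] if s.a0 == 1.0)

        stage = "base-case"
        bc = cmd_base_case(
            inputs_dir / "config.yaml", inputs_dir / "life_table.csv",
            outdir / "base_case", seed=seed,
        )

        stage = "psa"
        rem_draws = posterior_rr_draws(rem, n_psa, seed=sub(1))
        rel_draws = posterior_rr_draws(rel, n_psa, seed=sub(1) + 1)
        psa = cmd_run_psa(
            inputs_dir / "config.yaml", inputs_dir / "life_table.csv",
            outdir / "psa", rem_draws, rel_draws, n=n_psa, seed=sub(2),
        )

        stage = "voi"
        params = _load(inputs_dir / "config.yaml", inputs_dir / "life_table.csv")
        voi = cmd_run_voi(params, psa, outdir / "voi", seed=sub(3))
    except Exception:
        log.error("pipeline failed at stage %r; partial outputs kept in %s",
                  stage, outdir)
        raise

    record = _new_record("run-all", inputs_dir / "config.yaml", seed, n_psa=n_psa)
    record.outputs = ["synthesis", "base_case", "psa", "voi"]
    record.write(outdir)
    return {
        "synthesis": {
            o: [s.to_dict() for s in lst] for o, lst in synth.items()
        },
        "base_case": bc,
        "quadrants": quadrant_shares(psa),
        "voi": voi,
    }
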