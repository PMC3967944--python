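"""End-to-end orchestration: population -> regression -> B_RD -> contour.

``run_full_analysis`` materializes one run directory:

    params.csv       trial x parameter matrix (raw scale factors / mV shifts)
    outputs.csv      per-trial APDs and exclusion flags
    sensitivity.json B, R^2, sigma_logAPD per rate (+ rescaled fast B)
    brd.csv          per-parameter B_slow, B_fast_scaled, B_RD, class, rank
    contour.json     baseline APDs, rescale factor, RMSD
    metadata.json    config, seed, exclusion counts, beats-to-steady-state

Everything is deterministic given the config seed; all randomness flows
from that single seed through ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .contour import ContourResult, baseline_contour
from .models import get_model
from .population import PopulationResult, apply_exclusions, run_population, sample_population
from .rate_dependence import (
    RateDependenceEntry,
    build_table,
    percent_frd,
    table_frame,
)
from .sensitivity import SensitivityResult, fit_population

log = logging.getLogger("ratedep")


@dataclass
class AnalysisResult:
    config: RunConfig
    population: PopulationResult
    slow: SensitivityResult
    fast: SensitivityResult
    scaled_fast: np.ndarray
    table: list[RateDependenceEntry]
    contour: ContourResult

    @property
    def percent_frd(self) -> float:
        return percent_frd(self.table, self.config.classification_threshold)


def analyze_population(pop: PopulationResult, threshold: float = 0.01):
    """Exclusions + both-rate regression + B_RD table for a run population."""
    registry = list(get_model(pop.model_id).registry)
    apply_exclusions(pop)
    slow, fast, scaled = fit_population(pop, registry)
    table = build_table(slow.parameter_names, slow.coefficients, scaled, threshold)
    return slow, fast, scaled, table


def run_full_analysis(config: RunConfig, write: bool = True) -> AnalysisResult:
    mdef = get_model(config.model_id)
    proto_slow, proto_fast = config.protocols()
    sigma = config.resolved_sigma()

    log.info("sampling %d trials (sigma=%.4f, seed=%d)", config.n_trials, sigma, config.seed)
    samples = sample_population(
        list(mdef.registry), config.n_trials, sigma, config.v_sd_mV, config.seed
    )
    log.info("pacing population at %.1f and %.1f Hz", *config.rates_hz)
    pop = run_population(
        config.model_id, samples, proto_slow, proto_fast,
        sigma_log=sigma, v_sd=config.v_sd_mV, seed=config.seed,
    )
    slow, fast, scaled, table = analyze_population(pop, config.classification_threshold)
    contour = baseline_contour(config.model_id, proto_slow, proto_fast)

    result = AnalysisResult(
        config=config, population=pop, slow=slow, fast=fast,
        scaled_fast=scaled, table=table, contour=contour,
    )
    if write:
        write_run_directory(result)
    return result


def write_run_directory(result: AnalysisResult) -> Path:
    cfg = result.config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pop = result.population

    pop.parameter_frame().to_csv(out / "params.csv")
    pop.apd_frame().to_csv(out / "outputs.csv")
    table_frame(result.table).to_csv(out / "brd.csv")

    sens = {
        "model": cfg.model_id,
        "n_included": result.slow.n_included,
        "slow": _sens_json(result.slow),
        "fast": _sens_json(result.fast),
        "scaled_B_fast": dict(
            zip(result.fast.parameter_names, map(float, result.scaled_fast))
        ),
        "percent_frd": result.percent_frd,
    }
    (out / "sensitivity.json").write_text(json.dumps(sens, indent=2))

    c = result.contour
    (out / "contour.json").write_text(
        json.dumps(
            {
                "model": c.model_id,
                "APD_slow_ms": c.apd_slow,
                "APD_fast_ms": c.apd_fast,
                "rescale_factor": c.rescale_factor,
                "RMSD_mV": c.rmsd,
                "n_samples": c.n_samples,
            },
            indent=2,
        )
    )

    beats = pd.DataFrame(
        {
            "trial": [s.trial_id for s in pop.samples],
            "beats_slow": [o.beats_used for o in pop.slow],
            "beats_fast": [o.beats_used for o in pop.fast],
        }
    ).set_index("trial")
    meta = {
        "config": cfg.model_dump(mode="json"),
        "config_hash": cfg.config_hash(),
        "sigma_log": pop.sigma_log,
        "exclusion_counts": pop.exclusion_counts(),
        "n_included": int(pop.included_mask().sum()),
        "beats_to_steady_state": beats.to_dict(orient="index"),
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))
    return out


def _sens_json(s: SensitivityResult) -> dict:
    return {
        "rate_hz": s.rate_hz,
        "R2": s.r_squared,
        "sigma_logAPD": s.sigma_log_apd,
        "B": dict(zip(s.parameter_names, map(float, s.coefficients))),
        "SE": dict(zip(s.parameter_names, map(float, s.standard_errors))),
    }
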