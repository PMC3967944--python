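"""Shared fixtures: study protocols and cached per-model population runs.

Population sizes are scaled per model so the whole suite runs on one CPU in
minutes: the LR91 population keeps the study's full 300 trials (it anchors
the regression-fidelity comparison); the heavier human/dynamic models use
100-120 trials, which is ample for 28-36 regression coefficients.
"""

from __future__ import annotations

import numpy as np
import pytest

from ratedep.contour import baseline_contour
from ratedep.models import get_model
from ratedep.pacing import PacingProtocol
from ratedep.population import apply_exclusions, run_population, sample_population
from ratedep.rate_dependence import build_table, percent_frd
from ratedep.sensitivity import fit_population

SEED = 2014

# trials per model for the session populations
N_TRIALS = {
    "LR91": 300,
    "TP06-epi": 120,
    "TP06-mid": 100,
    "TP06-endo": 100,
    "LR09": 100,
}

# beat caps for population pacing (trials warm-start from the baseline
# steady state, so re-convergence is fast; the criterion still applies)
SLOW_MAX_BEATS = 60
FAST_MAX_BEATS = 200


@pytest.fixture(scope="session")
def study_protocols():
    """The study's 0.2 Hz / 2 Hz pacing protocols."""
    return (
        PacingProtocol(5000.0, max_beats=SLOW_MAX_BEATS),
        PacingProtocol(500.0, max_beats=FAST_MAX_BEATS),
    )


class _AnalysisCache:
    """Lazily computed, session-cached per-model population analyses."""

    def __init__(self, protocols):
        self.slow_proto, self.fast_proto = protocols
        self._cache = {}

    def __call__(self, model_id: str):
        if model_id not in self._cache:
            mdef = get_model(model_id)
            sigma = mdef.default_sigma_log
            samples = sample_population(
                list(mdef.registry), N_TRIALS[model_id], sigma, seed=SEED
            )
            pop = run_population(
                model_id, samples, self.slow_proto, self.fast_proto,
                sigma_log=sigma, seed=SEED,
            )
            apply_exclusions(pop)
            slow, fast, scaled = fit_population(pop, list(mdef.registry))
            table = build_table(slow.parameter_names, slow.coefficients, scaled)
            contour = baseline_contour(model_id, self.slow_proto, self.fast_proto)
            self._cache[model_id] = {
                "population": pop,
                "slow": slow,
                "fast": fast,
                "scaled_fast": scaled,
                "table": table,
                "percent_frd": percent_frd(table),
                "contour": contour,
            }
        return self._cache[model_id]


@pytest.fixture(scope="session")
def model_analysis(study_protocols):
    return _AnalysisCache(study_protocols)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
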