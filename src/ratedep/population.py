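"""Randomized model populations at two pacing rates, with exclusion filters.

Each trial multiplies every G/K/p parameter by an independent log-normal
scale factor (median 1, log-SD sigma, i.e. ~95% of factors within
exp(+/- 2 sigma) of baseline: 82-122% at sigma 0.1, 70-144% at 0.1823) and
adds an independent normal voltage shift (SD 2 mV) to every V parameter.
The same perturbed parameter set is paced to steady state at both rates.

Exclusion filters: AP alternans, repolarization failure, or an APD more
than 3 SD from the population mean at either rate (single pass, per rate,
over non-failed trials).  A trial excluded at either rate is dropped from
both, keeping the two regressions paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ConfiguredModel, ParameterDescriptor, PerturbationSet, get_model
from .pacing import (
    PacingProtocol,
    SolverError,
    SteadyStateResult,
    baseline_steady_state,
    run_to_steady_state,
)

DEFAULT_N_TRIALS = 300
DEFAULT_V_SD = 2.0  # mV
OUTLIER_SD = 3.0


@dataclass(frozen=True)
class PopulationSample:
    trial_id: int
    perturbation: PerturbationSet
    seed: int  # per-trial sub-seed record


@dataclass
class TrialOutcome:
    apd: float  # ms; nan on failure
    alternans: bool
    repolarization_failure: bool
    converged: bool
    beats_used: int
    outlier: bool = False

    @property
    def failed(self) -> bool:
        return self.alternans or self.repolarization_failure


@dataclass
class PopulationResult:
    model_id: str
    samples: list[PopulationSample]
    slow: list[TrialOutcome]
    fast: list[TrialOutcome]
    protocol_slow: PacingProtocol
    protocol_fast: PacingProtocol
    sigma_log: float
    v_sd: float
    seed: int
    exclusions_applied: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.samples)

    def included_mask(self) -> np.ndarray:
        mask = np.zeros(self.n, dtype=bool)
        for i, (s, f) in enumerate(zip(self.slow, self.fast)):
            mask[i] = not (s.failed or f.failed or s.outlier or f.outlier)
        return mask

    def included_ids(self) -> list[int]:
        return [s.trial_id for s, keep in zip(self.samples, self.included_mask()) if keep]

    def exclusion_counts(self) -> dict[str, int]:
        counts = {"alternans": 0, "repolarization_failure": 0, "outlier": 0}
        for s, f in zip(self.slow, self.fast):
            if s.repolarization_failure or f.repolarization_failure:
                counts["repolarization_failure"] += 1
            elif s.alternans or f.alternans:
                counts["alternans"] += 1
            elif s.outlier or f.outlier:
                counts["outlier"] += 1
        return counts

    def apd_frame(self) -> pd.DataFrame:
        """Per-trial APDs and flags as a tidy frame."""
        rows = []
        for sample, s, f, keep in zip(
            self.samples, self.slow, self.fast, self.included_mask()
        ):
            rows.append(
                {
                    "trial": sample.trial_id,
                    "APD_slow": s.apd,
                    "APD_fast": f.apd,
                    "alternans": s.alternans or f.alternans,
                    "repolarization_failure": s.repolarization_failure
                    or f.repolarization_failure,
                    "outlier": s.outlier or f.outlier,
                    "included": bool(keep),
                }
            )
        return pd.DataFrame(rows).set_index("trial")

    def parameter_frame(self) -> pd.DataFrame:
        """Trial x parameter matrix of raw scale factors / mV shifts."""
        registry = get_model(self.model_id).registry
        data = {
            d.name: [s.perturbation.get(d.name, 0.0 if d.category == "V" else 1.0)
                     for s in self.samples]
            for d in registry
        }
        frame = pd.DataFrame(data, index=[s.trial_id for s in self.samples])
        frame.index.name = "trial"
        return frame


def sample_population(
    registry: list[ParameterDescriptor],
    n: int,
    sigma_log: float,
    v_sd_mV: float = DEFAULT_V_SD,
    seed: int = 0,
) -> list[PopulationSample]:
    """Draw ``n`` independent perturbation sets (reproducible from ``seed``)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not sigma_log > 0:
        raise ValueError("sigma_log must be > 0")
    root = np.random.SeedSequence(seed)
    samples = []
    for trial, child in enumerate(root.spawn(n)):
        rng = np.random.default_rng(child)
        values = {}
        for d in registry:
            if d.category == "V":
                values[d.name] = float(rng.normal(0.0, v_sd_mV))
            else:
                values[d.name] = float(np.exp(rng.normal(0.0, sigma_log)))
        samples.append(
            PopulationSample(
                trial_id=trial,
                perturbation=PerturbationSet(values),
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
        )
    return samples


def _run_one(
    model: ConfiguredModel, protocol: PacingProtocol, warm_state: np.ndarray
) -> TrialOutcome:
    try:
        res: SteadyStateResult = run_to_steady_state(model, protocol, warm_state)
    except SolverError:
        return TrialOutcome(
            apd=float("nan"), alternans=False, repolarization_failure=True,
            converged=False, beats_used=0,
        )
    return TrialOutcome(
        apd=res.apd,
        alternans=res.alternans,
        repolarization_failure=res.repolarization_failure,
        converged=res.converged,
        beats_used=res.beats_used,
    )


def run_population(
    model_id: str,
    samples: list[PopulationSample],
    protocol_slow: PacingProtocol,
    protocol_fast: PacingProtocol,
    sigma_log: float = float("nan"),
    v_sd: float = DEFAULT_V_SD,
    seed: int = 0,
) -> PopulationResult:
    """Pace every trial to steady state at both rates (same perturbation).

    Trials warm-start from the baseline steady state at each rate, so the
    rest phase is integrated once per rate rather than once per trial.
    Results are ordered by trial id and independent of execution order.
    """
    mdef = get_model(model_id)
    base = mdef.baseline()
    warm_slow = baseline_steady_state(base, protocol_slow).state
    warm_fast = baseline_steady_state(base, protocol_fast).state

    slow, fast = [], []
    for sample in samples:
        inst = mdef.configure(sample.perturbation)
        slow.append(_run_one(inst, protocol_slow, warm_slow))
        fast.append(_run_one(inst, protocol_fast, warm_fast))
    return PopulationResult(
        model_id=model_id,
        samples=list(samples),
        slow=slow,
        fast=fast,
        protocol_slow=protocol_slow,
        protocol_fast=protocol_fast,
        sigma_log=sigma_log,
        v_sd=v_sd,
        seed=seed,
    )


def apply_exclusions(result: PopulationResult, min_included: int = 10) -> PopulationResult:
    """Finalize outlier flags (3-SD rule, single pass, joint across rates).

    Idempotent: outliers are always recomputed from the non-failed trials'
    raw APDs, so a second application changes nothing.
    """
    for outcomes in (result.slow, result.fast):
        apds = np.array(
            [o.apd for o in outcomes if not o.failed and np.isfinite(o.apd)]
        )
        if len(apds) == 0:
            continue
        mean, sd = float(np.mean(apds)), float(np.std(apds))
        for o in outcomes:
            o.outlier = (
                not o.failed
                and np.isfinite(o.apd)
                and sd > 0
                and abs(o.apd - mean) > OUTLIER_SD * sd
            )
    result.exclusions_applied = True
    n_inc = int(result.included_mask().sum())
    if n_inc < min_included:
        raise ValueError(
            f"only {n_inc} trials remain after exclusions; regression needs >= {min_included}"
        )
    return result
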