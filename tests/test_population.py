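"""Population sampling, paired-rate runs, and exclusion filters."""

import numpy as np
import pytest

from ratedep.models import PerturbationSet, get_model, get_parameter_registry
from ratedep.pacing import PacingProtocol
from ratedep.population import (
    PopulationResult,
    PopulationSample,
    TrialOutcome,
    apply_exclusions,
    run_population,
    sample_population,
)


def _factors(samples, registry):
    gkp = [d.name for d in registry if d.category != "V"]
    return np.array([[s.perturbation[n] for n in gkp] for s in samples])


def test_lognormal_scale_factor_spread():
    """sigma = 0.1 puts ~95% of factors in 82-122% of baseline; the
    sigma = 0.1823 upper end reaches ~144%."""
    registry = get_parameter_registry("LR91")
    s1 = sample_population(registry, 1500, 0.1, seed=5)
    f1 = _factors(s1, registry).ravel()
    lo, hi = np.percentile(f1, [2.5, 97.5])
    assert lo == pytest.approx(np.exp(-0.2), rel=0.02)
    assert hi == pytest.approx(np.exp(0.2), rel=0.02)
    s2 = sample_population(registry, 1500, 0.1823, seed=5)
    hi2 = np.percentile(_factors(s2, registry).ravel(), 97.5)
    assert hi2 == pytest.approx(1.44, rel=0.03)


def test_sample_median_approaches_one():
    registry = get_parameter_registry("LR91")
    samples = sample_population(registry, 10_000, 0.1, seed=9)
    factors = _factors(samples, registry)
    # 3 standard errors of the median of a log-normal at n = 1e4
    se = 1.2533 * 0.1 / np.sqrt(len(factors))
    assert abs(np.median(np.log(factors[:, 0]))) < 3 * se


def test_voltage_shifts_are_normal_mean_zero():
    registry = get_parameter_registry("TP06-epi")
    samples = sample_population(registry, 4000, 0.1, v_sd_mV=2.0, seed=13)
    vnames = [d.name for d in registry if d.category == "V"]
    shifts = np.array([[s.perturbation[n] for n in vnames] for s in samples]).ravel()
    assert np.mean(shifts) == pytest.approx(0.0, abs=0.1)
    assert np.std(shifts) == pytest.approx(2.0, rel=0.05)


def test_sampling_is_seed_reproducible_and_validated():
    registry = get_parameter_registry("LR91")
    a = sample_population(registry, 20, 0.1, seed=42)
    b = sample_population(registry, 20, 0.1, seed=42)
    assert all(dict(x.perturbation) == dict(y.perturbation) for x, y in zip(a, b))
    c = sample_population(registry, 20, 0.1, seed=43)
    assert dict(a[0].perturbation) != dict(c[0].perturbation)
    with pytest.raises(ValueError):
        sample_population(registry, 0, 0.1)
    with pytest.raises(ValueError):
        sample_population(registry, 5, -0.1)


def _synthetic_population(apds_slow, apds_fast, model_id="LR91"):
    n = len(apds_slow)
    registry = get_parameter_registry(model_id)
    samples = [
        PopulationSample(i, PerturbationSet({registry[0].name: 1.0}), 0) for i in range(n)
    ]
    mk = lambda a: TrialOutcome(
        apd=a, alternans=False, repolarization_failure=not np.isfinite(a),
        converged=True, beats_used=5,
    )
    proto = PacingProtocol(5000.0)
    return PopulationResult(
        model_id=model_id,
        samples=samples,
        slow=[mk(a) for a in apds_slow],
        fast=[mk(a) for a in apds_fast],
        protocol_slow=proto,
        protocol_fast=PacingProtocol(500.0),
        sigma_log=0.1,
        v_sd=2.0,
        seed=0,
    )


def test_exclusions_clean_population_keeps_everything():
    rng = np.random.default_rng(1)
    pop = _synthetic_population(
        rng.normal(360, 5, 40), rng.normal(320, 5, 40)
    )
    apply_exclusions(pop)
    assert pop.included_mask().all()
    assert pop.exclusion_counts() == {
        "alternans": 0, "repolarization_failure": 0, "outlier": 0
    }


def test_exclusions_flag_injected_outlier_jointly():
    rng = np.random.default_rng(2)
    slow = rng.normal(360, 5, 40)
    fast = rng.normal(320, 5, 40)
    slow[7] = 360 + 5 * np.std(slow) * 3  # far beyond 3 SD at the slow rate only
    pop = _synthetic_population(slow, fast)
    apply_exclusions(pop)
    mask = pop.included_mask()
    assert not mask[7]
    assert mask.sum() == 39
    # joint exclusion: the fast-rate entry of trial 7 is dropped too
    assert 7 not in pop.included_ids()


def test_exclusions_are_idempotent():
    rng = np.random.default_rng(3)
    slow = rng.normal(360, 5, 30)
    slow[0] = 500.0
    pop = _synthetic_population(slow, rng.normal(320, 5, 30))
    apply_exclusions(pop)
    first = pop.included_mask().copy()
    apply_exclusions(pop)
    assert np.array_equal(first, pop.included_mask())


def test_exclusions_error_when_too_few_remain():
    pop = _synthetic_population([np.nan] * 12, [np.nan] * 12)
    with pytest.raises(ValueError, match="regression"):
        apply_exclusions(pop)


def test_failed_trials_never_included():
    pop = _synthetic_population([360.0, np.nan, 358.0], [320.0, 321.0, np.nan])
    for o in pop.slow + pop.fast:
        o.outlier = False
    assert list(pop.included_mask()) == [True, False, False]


def test_single_baseline_trial_matches_baseline_apd(study_protocols):
    """An empty perturbation run through the population machinery lands on
    the baseline steady-state APD at both rates."""
    from ratedep.pacing import baseline_steady_state

    slow, fast = study_protocols
    mdef = get_model("LR91")
    samples = [PopulationSample(0, PerturbationSet({}), 0)]
    pop = run_population("LR91", samples, slow, fast)
    base = mdef.baseline()
    apd_s = baseline_steady_state(base, slow).apd
    apd_f = baseline_steady_state(base, fast).apd
    assert pop.slow[0].apd == pytest.approx(apd_s, abs=0.5)
    assert pop.fast[0].apd == pytest.approx(apd_f, abs=0.5)


def test_run_population_order_independent(study_protocols):
    slow, fast = study_protocols
    registry = get_parameter_registry("LR91")
    samples = sample_population(registry, 4, 0.1, seed=77)
    fwd = run_population("LR91", samples, slow, fast)
    rev = run_population("LR91", list(reversed(samples)), slow, fast)
    rev_by_id = {s.trial_id: o for s, o in zip(rev.samples, rev.slow)}
    for s, o in zip(fwd.samples, fwd.slow):
        assert o.apd == pytest.approx(rev_by_id[s.trial_id].apd, abs=1e-9)
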