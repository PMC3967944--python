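"""Charge integrals Q, perturbation deltas, and the Fig-S4-style taxonomy."""

import numpy as np
import pandas as pd
import pytest

from ratedep.charge import (
    ChargeReport,
    delta_q,
    integrate_current,
    perturbation_rate_class,
)
from ratedep.pacing import APTrace
from ratedep.synth import SyntheticWaveformSpec, synth_ap, synth_current_pair


def _flat_trace(value: float, duration: float = 400.0, dt: float = 0.5) -> APTrace:
    t = np.arange(0.0, duration + dt / 2, dt)
    return APTrace(
        time=t,
        voltage=np.full_like(t, -80.0),
        currents={"I_const": np.full_like(t, value), "I_zero": np.zeros_like(t)},
        apd=200.0,
        t_upstroke=0.0,
        v_peak=-80.0,
        v_diastolic=-80.0,
        cycle_length=duration,
    )


def test_constant_current_integrates_to_rectangle():
    trace = _flat_trace(1.0)
    assert integrate_current(trace, "I_const", (0.0, 200.0)) == pytest.approx(200.0)
    assert integrate_current(trace, "I_zero") == 0.0
    # default window = [0, t_upstroke + APD]
    assert integrate_current(trace, "I_const") == pytest.approx(200.0)


def test_integrate_current_guards():
    trace = _flat_trace(1.0)
    with pytest.raises(KeyError, match="I_missing"):
        integrate_current(trace, "I_missing")
    with pytest.raises(ValueError, match="window"):
        integrate_current(trace, "I_const", (0.0, 1e6))


def test_integration_is_linear_in_the_currents():
    trace = synth_ap(SyntheticWaveformSpec(), 1000.0)
    i1 = trace.currents["I_syn"]
    combined = APTrace(
        time=trace.time,
        voltage=trace.voltage,
        currents={"a": i1, "b": np.cos(trace.time / 50.0), "mix": 2.0 * i1 + 3.0 * np.cos(trace.time / 50.0)},
        apd=trace.apd,
        t_upstroke=trace.t_upstroke,
        v_peak=trace.v_peak,
        v_diastolic=trace.v_diastolic,
        cycle_length=trace.cycle_length,
    )
    qa = integrate_current(combined, "a")
    qb = integrate_current(combined, "b")
    qmix = integrate_current(combined, "mix")
    assert qmix == pytest.approx(2.0 * qa + 3.0 * qb, rel=1e-9)


def test_q_on_resampled_grid_agrees_with_native_grid(study_protocols):
    """Q from the 0.1-ms uniform resample stays within 0.5% of Q from the
    integrator's own non-uniform grid (for currents of appreciable size)."""
    from ratedep.models import get_model
    from ratedep.pacing import baseline_steady_state, capture_steady_trace

    _, fast = study_protocols
    inst = get_model("LR91").baseline()
    ss = baseline_steady_state(inst, fast)
    dense = capture_steady_trace(inst, fast, ss.state)
    uniform = dense.resample(0.1)
    for name in ("I_si", "I_K", "I_K1"):
        q_dense = integrate_current(dense, name)
        q_uniform = integrate_current(uniform, name)
        assert q_uniform == pytest.approx(q_dense, rel=5e-3)


def test_delta_q_fixture_arithmetic_and_sign_rule():
    q_c = pd.Series({"I_x": -100.0})
    q_p = pd.Series({"I_x": -160.0})
    report = ChargeReport(
        model_id="fixture",
        perturbation={"G_x": 2.0},
        q_control={"slow": q_c},
        q_perturbed={"slow": q_p},
        apd_control={"slow": 300.0},
        apd_perturbed={"slow": 330.0},
    )
    dq = report.delta_q("slow")
    assert dq["I_x"] == pytest.approx(-60.0)
    # negative dQ = AP-prolonging contribution, stated on the report
    assert "prolongation" in report.sign_interpretation


def test_empty_perturbation_gives_zero_delta_q(study_protocols):
    slow, fast = study_protocols
    report = delta_q("LR91", {}, slow, fast)
    for rate in ("slow", "fast"):
        assert np.allclose(report.delta_q(rate).to_numpy(), 0.0)
        assert report.apd_control[rate] == report.apd_perturbed[rate]


@pytest.mark.parametrize(
    "family,check",
    [
        ("I1", lambda s, f: s < f < 0),   # inward increase greater at slow
        ("I4", lambda s, f: f > s > 0),   # outward increase greater at fast
        ("I5", lambda s, f: s > f > 0),   # inward decrease greater at slow
        ("I8", lambda s, f: f < s < 0),   # outward decrease greater at fast
        ("I9", lambda s, f: s == f),      # rate-neutral
        ("I12", lambda s, f: s == f),
    ],
)
def test_current_pair_families_have_documented_dq_signs(family, check):
    pair = synth_current_pair(family)
    assert check(pair.dq_slow, pair.dq_fast)
    # measured trapezoid dQ agrees with the closed form
    dq_slow = np.trapezoid(pair.perturbed_slow - pair.control_slow, pair.time)
    dq_fast = np.trapezoid(pair.perturbed_fast - pair.control_fast, pair.time)
    assert dq_slow == pytest.approx(pair.dq_slow, rel=1e-3)
    assert dq_fast == pytest.approx(pair.dq_fast, rel=1e-3)


def test_zero_effect_family_gives_zero_dq():
    pair = synth_current_pair("I9", effect=0.0)
    assert pair.dq_slow == 0.0 and pair.dq_fast == 0.0
    with pytest.raises(KeyError):
        synth_current_pair("I99")


def test_perturbation_rate_class_tolerance_band():
    assert perturbation_rate_class(10.0, 5.0) == "RRD"
    assert perturbation_rate_class(5.0, 10.0) == "FRD"
    assert perturbation_rate_class(5.0, 5.2) == "NRD"
    # magnitude comparison: symmetric for AP-shortening perturbations
    assert perturbation_rate_class(-10.0, -5.0) == "RRD"
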