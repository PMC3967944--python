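"""AP-contour rescaling, RMSD oracle fixtures, and capacity regression."""

import numpy as np
import pytest

from ratedep.contour import (
    baseline_contour,
    contour_rmsd,
    frd_capacity_regression,
    ito_block_experiment,
    rescale_ap,
)
from ratedep.pacing import APTrace
from ratedep.synth import SyntheticWaveformSpec, synth_ap


def test_rescale_to_own_apd_is_identity():
    trace = synth_ap(SyntheticWaveformSpec(), 1000.0)
    grid, v = rescale_ap(trace, trace.apd)
    t = trace.time - trace.t_upstroke
    keep = (t >= 0) & (t <= trace.apd)
    v_ref = np.interp(grid, t[keep], trace.voltage[keep])
    assert np.max(np.abs(v - v_ref)) < 0.01


def test_rescale_doubles_segment_durations():
    """An affine time map stretches every waveform segment by the same
    factor: the plateau-to-ramp breakpoint of a trapezoid AP moves from
    plateau_end to 2 x plateau_end."""
    spec = SyntheticWaveformSpec(apd=100.0, repol_span=20.0)
    trace = synth_ap(spec, 1000.0, dt=0.05)
    grid, v = rescale_ap(trace, 200.0)
    breakpoint_orig = spec.plateau_end()  # ms after upstroke
    # just before 2x the breakpoint the voltage is still at the plateau;
    # at 2x (breakpoint + ramp/2) it is halfway down the ramp
    assert v[np.searchsorted(grid, 2 * breakpoint_orig - 2.0)] == pytest.approx(
        spec.v_peak, abs=0.5
    )
    mid_ramp_t = 2.0 * (breakpoint_orig + spec.repol_span / 2.0)
    v_mid = np.interp(mid_ramp_t, grid, v)
    assert v_mid == pytest.approx((spec.v_peak + spec.v_rest) / 2.0, abs=1.0)


def test_rescale_round_trip_error_below_tolerance():
    trace = synth_ap(SyntheticWaveformSpec(notch_depth=15.0), 1000.0, dt=0.02)
    grid, v_stretched = rescale_ap(trace, 2.0 * trace.apd, dt=0.02)
    stretched = APTrace(
        time=grid,
        voltage=v_stretched,
        currents={},
        apd=2.0 * trace.apd,
        t_upstroke=0.0,
        v_peak=trace.v_peak,
        v_diastolic=trace.v_diastolic,
        cycle_length=1000.0,
    )
    grid2, v_back = rescale_ap(stretched, trace.apd, dt=0.02)
    t = trace.time - trace.t_upstroke
    keep = (t >= 0) & (t <= trace.apd)
    v_ref = np.interp(grid2, t[keep], trace.voltage[keep])
    assert np.sqrt(np.mean((v_back - v_ref) ** 2)) < 0.05


def test_rmsd_of_identical_traces_is_zero():
    trace = synth_ap(SyntheticWaveformSpec(), 1000.0)
    assert contour_rmsd(trace, trace).rmsd == 0.0


def test_rmsd_constant_offset_closed_form():
    trace = synth_ap(SyntheticWaveformSpec(), 1000.0)
    shifted = APTrace(
        time=trace.time,
        voltage=trace.voltage + 3.0,
        currents=trace.currents,
        apd=trace.apd,
        t_upstroke=trace.t_upstroke,
        v_peak=trace.v_peak + 3.0,
        v_diastolic=trace.v_diastolic + 3.0,
        cycle_length=trace.cycle_length,
    )
    res = contour_rmsd(trace, shifted)
    assert res.rmsd == pytest.approx(3.0, rel=1e-6)


def test_rmsd_linear_ramp_difference_matches_symbolic_integral():
    """If the two waveforms differ by a ramp rising 0 -> a over the APD
    window, RMSD = a / sqrt(3) (root of the mean of (a t / T)^2)."""
    trace = synth_ap(SyntheticWaveformSpec(), 1000.0)
    a = 6.0
    t_rel = trace.time - trace.t_upstroke
    ramp = np.where(
        (t_rel >= 0) & (t_rel <= trace.apd), a * np.clip(t_rel, 0, None) / trace.apd, 0.0
    )
    bumped = APTrace(
        time=trace.time,
        voltage=trace.voltage + ramp,
        currents=trace.currents,
        apd=trace.apd,
        t_upstroke=trace.t_upstroke,
        v_peak=trace.v_peak,
        v_diastolic=trace.v_diastolic,
        cycle_length=trace.cycle_length,
    )
    res = contour_rmsd(trace, bumped)
    assert res.rmsd == pytest.approx(a / np.sqrt(3.0), rel=0.01)


def test_rmsd_monotone_in_notch_depth():
    base = synth_ap(SyntheticWaveformSpec(notch_depth=0.0), 1000.0)
    rmsds = [
        contour_rmsd(base, synth_ap(SyntheticWaveformSpec(notch_depth=d), 1000.0)).rmsd
        for d in (5.0, 10.0, 20.0, 30.0)
    ]
    assert all(b > a for a, b in zip(rmsds, rmsds[1:]))


def test_rmsd_convention_rescales_fast_onto_slow_window():
    slow = synth_ap(SyntheticWaveformSpec(apd=300.0, repol_span=60.0), 1000.0)
    fast = synth_ap(SyntheticWaveformSpec(apd=150.0, repol_span=30.0), 500.0)
    res = contour_rmsd(slow, fast)
    assert res.rescale_factor == pytest.approx(2.0, abs=1e-9)
    assert res.apd_slow == pytest.approx(300.0)
    # comparison grid spans [0, APD_slow] at 1 ms
    assert res.n_samples == 301


def test_capacity_regression_degenerate_cases():
    collinear = [(1.0, 10.0), (2.0, 20.0), (3.0, 30.0), (4.0, 40.0)]
    slope, intercept, r2, rho = frd_capacity_regression(collinear)
    assert r2 == pytest.approx(1.0)
    assert slope == pytest.approx(10.0)
    assert rho == pytest.approx(1.0)
    anti = [(1.0, 30.0), (2.0, 20.0), (3.0, 10.0)]
    slope, *_ = frd_capacity_regression(anti)
    assert slope < 0
    with pytest.raises(ValueError):
        frd_capacity_regression([(1.0, 1.0), (2.0, 2.0)])


def test_ito_block_requires_a_transient_outward_current(study_protocols):
    slow, fast = study_protocols
    with pytest.raises(ValueError, match="G_to"):
        ito_block_experiment("LR91", 0.75, slow, fast, n=12, seed=1)
    with pytest.raises(ValueError, match="block"):
        ito_block_experiment("TP06-epi", 1.5, slow, fast, n=12, seed=1)


def test_ito_zero_block_reproduces_control_arm(study_protocols):
    slow, fast = study_protocols
    out = ito_block_experiment("TP06-endo", 0.0, slow, fast, n=40, seed=5)
    c_ctrl, frd_ctrl = out["control"]
    c_blk, frd_blk = out["blocked"]
    assert c_ctrl.rmsd == c_blk.rmsd
    assert frd_ctrl == frd_blk


def test_baseline_contour_positive_rmsd(model_analysis):
    res = model_analysis("TP06-epi")["contour"]
    assert res.rmsd > 0
    assert res.rescale_factor > 1.0  # fast AP shorter than slow
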