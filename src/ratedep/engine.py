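"""Numba pacing drivers shared by all myocyte models.

Integration scheme: Rush-Larsen exponential updates for Hodgkin-Huxley gates
(inside each model's ``step`` kernel) and forward Euler for voltage and
concentrations.  The driver switches between a fine step during the AP
(stimulus, upstroke, plateau, repolarization) and a coarse step in diastole,
based on voltage and on the instantaneous dV/dt.  APD is measured on the fly:
the AP starts at the point of maximum dV/dt and ends at the first downward
crossing of ``V_peak - apd_fraction * (V_peak - V_diastolic)``, with linear
interpolation between steps.  V_diastolic is the voltage at stimulus onset.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# dt regime switch: fine step whenever V is above this or dV/dt is fast
V_GATE = -70.0  # mV
DVDT_GATE = 0.10  # mV/ms


@njit(cache=False)
def run_cycle(step, y, p, cl, stim_amp, stim_dur, dt_fine, dt_coarse, apd_frac):
    """Advance ``y`` in place through one pacing cycle of length ``cl`` ms.

    Returns (apd, t_up, v_peak, v_dia, repolarized, dvdt_max).
    ``apd`` is -1.0 when no repolarization crossing occurred before the next
    stimulus (repolarization failure).
    """
    t = 0.0
    v_dia = y[0]
    v_peak = y[0]
    t_up = 0.0
    dvdt_max = -1.0e30
    dvdt = 0.0
    apd = -1.0
    while t < cl - 1.0e-9:
        if t < stim_dur + 5.0 or y[0] > V_GATE or abs(dvdt) > DVDT_GATE:
            dt = dt_fine
        else:
            dt = dt_coarse
        if t < stim_dur and t + dt > stim_dur:
            dt = stim_dur - t
        if t + dt > cl:
            dt = cl - t
        istim = stim_amp if t < stim_dur - 1.0e-12 else 0.0
        v_old = y[0]
        step(y, p, dt, istim)
        v_new = y[0]
        dvdt = (v_new - v_old) / dt
        t += dt
        if dvdt > dvdt_max:
            dvdt_max = dvdt
            t_up = t
        if v_new > v_peak:
            v_peak = v_new
        if apd < 0.0 and t > t_up and v_new < v_old:
            thr = v_peak - apd_frac * (v_peak - v_dia)
            if v_old >= thr > v_new:
                frac = (v_old - thr) / (v_old - v_new)
                t_cross = t - dt + frac * dt
                apd = t_cross - t_up
    return apd, t_up, v_peak, v_dia, apd >= 0.0, dvdt_max


@njit(cache=False)
def run_quiescent(step, y, p, duration, dt_fine, dt_coarse):
    """Integrate ``duration`` ms with no stimulus (the pre-pacing rest phase)."""
    t = 0.0
    dvdt = 0.0
    while t < duration - 1.0e-9:
        if y[0] > V_GATE or abs(dvdt) > DVDT_GATE:
            dt = dt_fine
        else:
            dt = dt_coarse
        if t + dt > duration:
            dt = duration - t
        v_old = y[0]
        step(y, p, dt, 0.0)
        dvdt = (y[0] - v_old) / dt
        t += dt


@njit(cache=False)
def run_cycle_record(
    step, currents, y, p, cl, stim_amp, stim_dur, dt_fine, dt_coarse, t_buf, v_buf, i_buf, s_buf
):
    """Like :func:`run_cycle` but records every accepted step.

    ``t_buf``/``v_buf``: 1-D buffers; ``i_buf``: (n_samples, n_currents);
    ``s_buf``: stimulus current column.  Returns the number of samples
    written.  The sample at index k holds time t_k, V(t_k) and the roster
    currents evaluated at the state at t_k (pre-step), so trace integrals are
    trapezoids over the true internal grid.
    """
    n_cur = i_buf.shape[1]
    t = 0.0
    dvdt = 0.0
    k = 0
    while True:
        istim = stim_amp if t < stim_dur - 1.0e-12 else 0.0
        t_buf[k] = t
        v_buf[k] = y[0]
        currents(y, p, i_buf[k, :n_cur])
        s_buf[k] = istim
        k += 1
        if t >= cl - 1.0e-9:
            break
        if t < stim_dur + 5.0 or y[0] > V_GATE or abs(dvdt) > DVDT_GATE:
            dt = dt_fine
        else:
            dt = dt_coarse
        if t < stim_dur and t + dt > stim_dur:
            dt = stim_dur - t
        if t + dt > cl:
            dt = cl - t
        v_old = y[0]
        step(y, p, dt, istim)
        dvdt = (y[0] - v_old) / dt
        t += dt
    return k


def record_buffer_size(cl: float, dt_fine: float) -> int:
    return int(np.ceil(cl / dt_fine)) + 8
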