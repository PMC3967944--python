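"""Stimulation protocols, steady-state pacing, APD measurement, trace capture.

A simulation starts from the published initial conditions, rests unstimulated
(default 50 s), then paces at a fixed cycle length until the APD has
stabilized: relative beat-to-beat APD change below ``steady_tolerance`` for
``steady_beats`` consecutive beats.  Populations restart from a cached
baseline steady state instead of repeating the rest phase.

APD is APD90 by default: time from the maximum-upstroke-velocity point to the
first downward crossing of ``V_peak - apd_fraction * (V_peak - V_diastolic)``
(linear interpolation between integration steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import engine
from .models.base import ConfiguredModel


class SolverError(RuntimeError):
    """Numerical failure (non-finite state) during integration."""

    def __init__(self, message: str, beat_index: int | None = None):
        super().__init__(message)
        self.beat_index = beat_index


class RepolarizationFailure(RuntimeError):
    """The AP did not repolarize before the next stimulus."""


@dataclass(frozen=True)
class PacingProtocol:
    """One pacing condition (rate, stimulus, steady-state criterion)."""

    cycle_length: float  # ms (5000 for 0.2 Hz, 500 for 2 Hz)
    stim_amplitude: float | None = None  # A/F; None = model default
    stim_duration: float | None = None  # ms; None = model default
    rest_duration: float = 50.0  # s of quiescence before the first stimulus
    max_beats: int = 1000
    steady_tolerance: float = 1.0e-3  # relative APD change
    steady_beats: int = 3  # consecutive beats meeting the tolerance
    apd_fraction: float = 0.90
    alternans_delta: float = 2.0  # ms; |APD_n - APD_{n-1}| above this at the cap
    alternans_period2: float = 1.0  # ms; |APD_n - APD_{n-2}| below this at the cap

    def __post_init__(self):
        if not 0.0 < self.apd_fraction < 1.0:
            raise ValueError("apd_fraction must be in (0, 1)")
        if self.max_beats < 2:
            raise ValueError("max_beats must be >= 2")
        dur = self.stim_duration if self.stim_duration is not None else 0.5
        if self.cycle_length <= dur:
            raise ValueError("cycle_length must exceed the stimulus duration")

    @property
    def rate_hz(self) -> float:
        return 1000.0 / self.cycle_length

    def resolve_stimulus(self, model) -> tuple[float, float]:
        amp = self.stim_amplitude if self.stim_amplitude is not None else model.stim_amplitude
        dur = self.stim_duration if self.stim_duration is not None else model.stim_duration
        return amp, dur


def protocol_pair(
    slow_cl: float = 5000.0, fast_cl: float = 500.0, **kwargs
) -> tuple[PacingProtocol, PacingProtocol]:
    """The study's slow (0.2 Hz) and fast (2 Hz) protocols."""
    return PacingProtocol(slow_cl, **kwargs), PacingProtocol(fast_cl, **kwargs)


@dataclass
class SteadyStateResult:
    state: np.ndarray
    beats_used: int
    apd_history: np.ndarray  # ms, one entry per paced beat
    converged: bool
    alternans: bool
    repolarization_failure: bool
    protocol: PacingProtocol = field(repr=False)

    @property
    def apd(self) -> float:
        """APD of the final beat (nan on repolarization failure)."""
        if self.repolarization_failure or len(self.apd_history) == 0:
            return float("nan")
        return float(self.apd_history[-1])


@dataclass
class APTrace:
    """One captured pacing cycle: voltage and all roster currents.

    ``time`` is 0 at stimulus onset; the grid is the integrator's own
    (non-uniform: fine during the AP, coarse in diastole).  ``currents``
    includes the stimulus under key ``"I_stim"``.
    """

    time: np.ndarray  # ms
    voltage: np.ndarray  # mV
    currents: dict[str, np.ndarray]  # A/F, outward positive
    apd: float
    t_upstroke: float  # ms from stimulus onset to max dV/dt
    v_peak: float
    v_diastolic: float
    cycle_length: float
    beat_index: int = 0

    def resample(self, dt: float = 0.1) -> "APTrace":
        """Linear-interpolated copy on a uniform grid of spacing ``dt`` ms."""
        grid = np.arange(0.0, self.cycle_length + 0.5 * dt, dt)
        grid = grid[grid <= self.time[-1]]
        return APTrace(
            time=grid,
            voltage=np.interp(grid, self.time, self.voltage),
            currents={
                k: np.interp(grid, self.time, v) for k, v in self.currents.items()
            },
            apd=self.apd,
            t_upstroke=self.t_upstroke,
            v_peak=self.v_peak,
            v_diastolic=self.v_diastolic,
            cycle_length=self.cycle_length,
            beat_index=self.beat_index,
        )


def measure_apd(
    time: np.ndarray, voltage: np.ndarray, apd_fraction: float = 0.90
) -> float:
    """APD from a voltage trace: max-dV/dt alignment, fractional threshold.

    The AP starts at the sample of maximum dV/dt and ends at the first
    subsequent downward crossing of
    ``V_peak - apd_fraction * (V_peak - V_diastolic)`` where V_diastolic is
    the voltage at the start of the trace; crossings are located by linear
    interpolation.  Raises :class:`RepolarizationFailure` if the threshold is
    never reached.
    """
    time = np.asarray(time, dtype=float)
    voltage = np.asarray(voltage, dtype=float)
    if time.ndim != 1 or time.shape != voltage.shape or len(time) < 3:
        raise ValueError("time and voltage must be equal-length 1-D arrays (n >= 3)")
    dvdt = np.diff(voltage) / np.diff(time)
    i_up = int(np.argmax(dvdt))
    t_up = time[i_up + 1]
    v_dia = voltage[0]
    after = slice(i_up + 1, None)
    v_peak = float(np.max(voltage[after]))
    thr = v_peak - apd_fraction * (v_peak - v_dia)
    i_peak = i_up + 1 + int(np.argmax(voltage[after]))
    v_seg = voltage[i_peak:]
    t_seg = time[i_peak:]
    below = np.nonzero((v_seg[1:] < thr) & (v_seg[:-1] >= thr))[0]
    if len(below) == 0:
        raise RepolarizationFailure(
            f"voltage never crossed the APD threshold {thr:.1f} mV"
        )
    k = below[0]
    frac = (v_seg[k] - thr) / (v_seg[k] - v_seg[k + 1])
    t_cross = t_seg[k] + frac * (t_seg[k + 1] - t_seg[k])
    return float(t_cross - t_up)


def _check_finite(y: np.ndarray, beat: int) -> None:
    if not np.all(np.isfinite(y)):
        raise SolverError(f"non-finite state at beat {beat}", beat_index=beat)


def run_to_steady_state(
    model: ConfiguredModel,
    protocol: PacingProtocol,
    initial_state: np.ndarray | None = None,
) -> SteadyStateResult:
    """Rest (unless warm-started) then pace to the steady-state criterion.

    ``initial_state`` skips the rest phase (used when restarting from a
    cached baseline steady state).  Deterministic given its inputs.
    """
    mdef = model.definition
    amp, dur = protocol.resolve_stimulus(mdef)
    if initial_state is None:
        y = mdef.initial_state.copy()
        if protocol.rest_duration > 0:
            engine.run_quiescent(
                mdef.step, y, model.params, protocol.rest_duration * 1000.0,
                mdef.dt_fine, mdef.dt_coarse,
            )
            _check_finite(y, -1)
    else:
        y = np.array(initial_state, dtype=np.float64)
        if y.shape != mdef.initial_state.shape:
            raise ValueError("initial_state has wrong dimension")

    apds: list[float] = []
    converged = False
    repol_failure = False
    streak = 0
    for beat in range(protocol.max_beats):
        apd, t_up, v_peak, v_dia, ok, _ = engine.run_cycle(
            mdef.step, y, model.params, protocol.cycle_length, amp, dur,
            mdef.dt_fine, mdef.dt_coarse, protocol.apd_fraction,
        )
        _check_finite(y, beat)
        if not ok:
            repol_failure = True
            break
        apds.append(apd)
        if len(apds) >= 2:
            rel = abs(apds[-1] - apds[-2]) / apds[-2]
            streak = streak + 1 if rel < protocol.steady_tolerance else 0
            if streak >= protocol.steady_beats:
                converged = True
                break

    alternans = False
    if len(apds) >= 3 and not converged and not repol_failure:
        if (
            abs(apds[-1] - apds[-2]) > protocol.alternans_delta
            and abs(apds[-1] - apds[-3]) < protocol.alternans_period2
        ):
            alternans = True

    return SteadyStateResult(
        state=y,
        beats_used=len(apds) + (1 if repol_failure else 0),
        apd_history=np.asarray(apds),
        converged=converged,
        alternans=alternans,
        repolarization_failure=repol_failure,
        protocol=protocol,
    )


def capture_steady_trace(
    model: ConfiguredModel,
    protocol: PacingProtocol,
    steady_state: np.ndarray,
) -> APTrace:
    """Record one full cycle (stimulus to next stimulus) from a steady state."""
    mdef = model.definition
    amp, dur = protocol.resolve_stimulus(mdef)
    y = np.array(steady_state, dtype=np.float64)
    n_cur = len(mdef.current_names)
    n_max = engine.record_buffer_size(protocol.cycle_length, mdef.dt_fine)
    t_buf = np.empty(n_max)
    v_buf = np.empty(n_max)
    i_buf = np.empty((n_max, n_cur))
    s_buf = np.empty(n_max)
    n = engine.run_cycle_record(
        mdef.step, mdef.currents, y, model.params, protocol.cycle_length, amp, dur,
        mdef.dt_fine, mdef.dt_coarse, t_buf, v_buf, i_buf, s_buf,
    )
    _check_finite(y, 0)
    t = t_buf[:n].copy()
    v = v_buf[:n].copy()
    currents = {name: i_buf[:n, k].copy() for k, name in enumerate(mdef.current_names)}
    currents["I_stim"] = s_buf[:n].copy()
    apd = measure_apd(t, v, protocol.apd_fraction)
    dvdt = np.diff(v) / np.diff(t)
    i_up = int(np.argmax(dvdt))
    return APTrace(
        time=t,
        voltage=v,
        currents=currents,
        apd=apd,
        t_upstroke=float(t[i_up + 1]),
        v_peak=float(np.max(v)),
        v_diastolic=float(v[0]),
        cycle_length=protocol.cycle_length,
    )


# ---------------------------------------------------------------------------
# Baseline steady-state cache (per process).  Keyed on the model, the exact
# parameter vector and the protocol fields that affect the trajectory.

_BASELINE_CACHE: dict[tuple, SteadyStateResult] = {}


def _cache_key(model: ConfiguredModel, protocol: PacingProtocol) -> tuple:
    amp, dur = protocol.resolve_stimulus(model.definition)
    return (
        model.model_id,
        model.params.tobytes(),
        protocol.cycle_length,
        amp,
        dur,
        protocol.rest_duration,
        protocol.max_beats,
        protocol.steady_tolerance,
        protocol.steady_beats,
        protocol.apd_fraction,
    )


def baseline_steady_state(
    model: ConfiguredModel, protocol: PacingProtocol
) -> SteadyStateResult:
    """Memoized :func:`run_to_steady_state` from the published initial state."""
    key = _cache_key(model, protocol)
    if key not in _BASELINE_CACHE:
        _BASELINE_CACHE[key] = run_to_steady_state(model, protocol)
    return _BASELINE_CACHE[key]
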