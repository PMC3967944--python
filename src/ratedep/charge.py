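"""Charge-flux analysis: per-current Q, perturbation deltas, double scans.

Q is the trapezoidal integral of a membrane current (A/F) over the AP --
from stimulus onset to that condition's own APD end -- in pC/nF (A/F x ms).
Positive Q is net outward charge.  For a perturbation, dQ = Q_perturbed -
Q_control per current per rate; positive dQ contributes to APD shortening,
negative dQ to prolongation.  Comparing dQ at the two rates identifies the
currents that carry a perturbation's rate dependence.

The module also provides the single- and double-perturbation APD scans used
to validate mechanisms (e.g. enhanced L-type Ca2+ current plus graded I_Ks
block).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import get_model
from .pacing import (
    APTrace,
    PacingProtocol,
    baseline_steady_state,
    capture_steady_trace,
    run_to_steady_state,
)

SIGN_NOTE = (
    "positive dQ (outward gain) contributes to APD shortening; "
    "negative dQ contributes to APD prolongation"
)


def integrate_current(
    trace: APTrace, current: str, window: tuple[float, float] | None = None
) -> float:
    """Q (pC/nF): trapezoidal integral of ``current`` over the AP window.

    The default window runs from the start of the trace (stimulus onset) to
    the trace's APD end; an explicit ``window`` (ms, trace time axis) must
    lie within the trace span.
    """
    if current not in trace.currents:
        raise KeyError(
            f"unknown current {current!r}; trace has {sorted(trace.currents)}"
        )
    if window is None:
        window = (0.0, trace.t_upstroke + trace.apd)
    lo, hi = window
    if lo < trace.time[0] - 1e-9 or hi > trace.time[-1] + 1e-9:
        raise ValueError("window outside trace span")
    t = trace.time
    i = trace.currents[current]
    keep = (t >= lo) & (t <= hi)
    tt, ii = t[keep], i[keep]
    # close the window edges by interpolation
    if tt[0] > lo:
        tt = np.insert(tt, 0, lo)
        ii = np.insert(ii, 0, np.interp(lo, t, i))
    if tt[-1] < hi:
        tt = np.append(tt, hi)
        ii = np.append(ii, np.interp(hi, t, i))
    return float(np.trapezoid(ii, tt))


def charge_summary(trace: APTrace, include_stim: bool = False) -> pd.Series:
    """Q of every roster current over the trace's AP window."""
    names = [k for k in trace.currents if include_stim or k != "I_stim"]
    return pd.Series({k: integrate_current(trace, k) for k in names}, name="Q")


@dataclass
class ChargeReport:
    model_id: str
    perturbation: dict[str, float]
    q_control: dict[str, pd.Series]  # rate label -> per-current Q
    q_perturbed: dict[str, pd.Series]
    apd_control: dict[str, float]
    apd_perturbed: dict[str, float]
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)
    sign_interpretation: str = SIGN_NOTE

    def delta_q(self, rate: str) -> pd.Series:
        return (self.q_perturbed[rate] - self.q_control[rate]).rename("dQ")

    def frame(self) -> pd.DataFrame:
        parts = {}
        for rate in self.q_control:
            parts[(rate, "Q_control")] = self.q_control[rate]
            parts[(rate, "Q_perturbed")] = self.q_perturbed[rate]
            parts[(rate, "dQ")] = self.delta_q(rate)
        return pd.DataFrame(parts)


def _steady_trace(model, protocol) -> APTrace:
    base = baseline_steady_state(model, protocol)
    if base.repolarization_failure:
        raise RuntimeError(
            f"{model.model_id}: repolarization failure at CL {protocol.cycle_length}"
        )
    return capture_steady_trace(model, protocol, base.state)


def delta_q(
    model_id: str,
    perturbation: dict[str, float],
    protocol_slow: PacingProtocol,
    protocol_fast: PacingProtocol,
) -> ChargeReport:
    """Q and dQ per current at both rates for one named perturbation.

    Four steady-state runs (control/perturbed x slow/fast); each condition
    is integrated over its own AP (stimulus onset to its own APD end).
    """
    mdef = get_model(model_id)
    q_c, q_p, apd_c, apd_p, windows = {}, {}, {}, {}, {}
    for label, protocol in (("slow", protocol_slow), ("fast", protocol_fast)):
        try:
            tr_c = _steady_trace(mdef.baseline(), protocol)
            tr_p = _steady_trace(mdef.configure(perturbation), protocol)
        except RuntimeError as err:
            raise RuntimeError(f"steady-state failure ({label} rate): {err}") from err
        q_c[label] = charge_summary(tr_c)
        q_p[label] = charge_summary(tr_p)
        apd_c[label] = tr_c.apd
        apd_p[label] = tr_p.apd
        windows[label] = (0.0, tr_c.t_upstroke + tr_c.apd)
    return ChargeReport(
        model_id=model_id,
        perturbation=dict(perturbation),
        q_control=q_c,
        q_perturbed=q_p,
        apd_control=apd_c,
        apd_perturbed=apd_p,
        windows=windows,
    )


def perturbation_rate_class(
    dapd_slow_pct: float, dapd_fast_pct: float, tol_pct: float = 0.5
) -> str:
    """RRD/FRD/NRD label for a single perturbation's APD change.

    Compares percent APD change at the two rates: a larger change at slow
    pacing is RRD, a larger change at fast pacing is FRD, differences within
    ``tol_pct`` percentage points are NRD.  The comparison uses magnitudes
    so AP-shortening perturbations classify symmetrically.
    """
    diff = abs(dapd_slow_pct) - abs(dapd_fast_pct)
    if diff > tol_pct:
        return "RRD"
    if diff < -tol_pct:
        return "FRD"
    return "NRD"


def single_perturbation_effect(
    model_id: str,
    perturbation: dict[str, float],
    protocol_slow: PacingProtocol,
    protocol_fast: PacingProtocol,
    reference: dict[str, float] | None = None,
) -> pd.DataFrame:
    """APD at both rates, control vs perturbed, with percent changes.

    ``reference`` (default empty = baseline) is the control condition; the
    perturbation is applied on top of it.
    """
    mdef = get_model(model_id)
    ref = dict(reference or {})
    pert = {**ref, **perturbation}
    rows = []
    for label, protocol in (("slow", protocol_slow), ("fast", protocol_fast)):
        base = baseline_steady_state(mdef.configure(ref), protocol)
        test = run_to_steady_state(
            mdef.configure(pert), protocol, initial_state=base.state
        )
        if base.repolarization_failure or test.repolarization_failure:
            raise RuntimeError(f"repolarization failure at {label} rate")
        rows.append(
            {
                "rate": label,
                "APD_control": base.apd,
                "APD_perturbed": test.apd,
                "dAPD_ms": test.apd - base.apd,
                "dAPD_pct": 100.0 * (test.apd - base.apd) / base.apd,
            }
        )
    return pd.DataFrame(rows).set_index("rate")


def double_perturbation_scan(
    model_id: str,
    fixed: dict[str, float],
    scan_parameter: str,
    levels: list[float],
    protocol_slow: PacingProtocol,
    protocol_fast: PacingProtocol,
    tol_pct: float = 0.5,
) -> pd.DataFrame:
    """APD grid for a fixed perturbation combined with a scanned parameter.

    For each scan level the control is the *scan level alone* and the test
    adds the fixed perturbation, isolating the fixed perturbation's effect
    and its rate-dependence class at that level.  Failed cells are marked
    invalid and the scan continues.
    """
    if any(not lv > 0 for lv in levels):
        raise ValueError("scan levels must be positive scale factors")
    rows = []
    for level in levels:
        try:
            eff = single_perturbation_effect(
                model_id,
                fixed,
                protocol_slow,
                protocol_fast,
                reference={scan_parameter: level},
            )
            rows.append(
                {
                    "level": level,
                    "APD_slow": eff.loc["slow", "APD_perturbed"],
                    "APD_fast": eff.loc["fast", "APD_perturbed"],
                    "dAPD_slow_pct": eff.loc["slow", "dAPD_pct"],
                    "dAPD_fast_pct": eff.loc["fast", "dAPD_pct"],
                    "class": perturbation_rate_class(
                        eff.loc["slow", "dAPD_pct"], eff.loc["fast", "dAPD_pct"], tol_pct
                    ),
                    "valid": True,
                }
            )
        except RuntimeError:
            rows.append(
                {
                    "level": level,
                    "APD_slow": np.nan,
                    "APD_fast": np.nan,
                    "dAPD_slow_pct": np.nan,
                    "dAPD_fast_pct": np.nan,
                    "class": "",
                    "valid": False,
                }
            )
    return pd.DataFrame(rows).set_index("level")
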