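"""Rate-dependent AP-contour change: time-rescaled RMSD and FRD capacity.

The baseline steady-state AP at the fast rate is rescaled in time by
APD_slow / APD_fast (aligned at the maximum-upstroke point) so both
waveforms have identical APD, then the root-mean-square voltage deviation
is taken over a uniform 1-ms grid spanning [0, APD_slow].  Voltage is not
normalized: RMSD is in mV.  The convention is fixed: the fast AP is always
the one rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pacing import APTrace

COMPARISON_DT = 1.0  # ms grid for the RMSD comparison


@dataclass(frozen=True)
class ContourResult:
    model_id: str
    apd_slow: float
    apd_fast: float
    rescale_factor: float  # APD_slow / APD_fast
    rmsd: float  # mV
    n_samples: int


def _ap_window(trace: APTrace) -> tuple[np.ndarray, np.ndarray]:
    """(t - t_upstroke, V) restricted to the AP window [0, APD]."""
    if not np.isfinite(trace.apd) or trace.apd <= 0:
        raise ValueError("trace has no defined APD")
    t = trace.time - trace.t_upstroke
    keep = (t >= 0.0) & (t <= trace.apd)
    return t[keep], trace.voltage[keep]


def rescale_ap(trace: APTrace, target_apd: float, dt: float = COMPARISON_DT):
    """Affine time-rescaled AP: (uniform grid over [0, target], voltage).

    Time is multiplied by ``target_apd / APD`` with t=0 at maximum dV/dt;
    voltages are unchanged and linearly interpolated onto the grid.
    """
    t, v = _ap_window(trace)
    factor = target_apd / trace.apd
    grid = np.arange(0.0, target_apd + 0.5 * dt, dt)
    return grid, np.interp(grid, t * factor, v)


def contour_rmsd(slow: APTrace, fast: APTrace, model_id: str = "") -> ContourResult:
    """RMSD (mV) between the slow AP and the time-rescaled fast AP."""
    t_s, v_s = _ap_window(slow)
    grid = np.arange(0.0, slow.apd + 0.5 * COMPARISON_DT, COMPARISON_DT)
    v_slow = np.interp(grid, t_s, v_s)
    _, v_fast = rescale_ap(fast, slow.apd)
    rmsd = float(np.sqrt(np.mean((v_slow - v_fast) ** 2)))
    return ContourResult(
        model_id=model_id,
        apd_slow=slow.apd,
        apd_fast=fast.apd,
        rescale_factor=slow.apd / fast.apd,
        rmsd=rmsd,
        n_samples=len(grid),
    )


def baseline_contour(
    model_id: str,
    protocol_slow,
    protocol_fast,
    perturbation: dict[str, float] | None = None,
) -> ContourResult:
    """Contour RMSD of a model's (optionally perturbed) baseline APs."""
    from .models import get_model
    from .pacing import baseline_steady_state, capture_steady_trace

    inst = get_model(model_id).configure(perturbation)
    traces = {}
    for label, protocol in (("slow", protocol_slow), ("fast", protocol_fast)):
        ss = baseline_steady_state(inst, protocol)
        if ss.repolarization_failure:
            raise RuntimeError(f"{model_id}: repolarization failure at {label} rate")
        traces[label] = capture_steady_trace(inst, protocol, ss.state)
    return contour_rmsd(traces["slow"], traces["fast"], model_id=model_id)


def ito_block_experiment(
    model_id: str,
    block: float,
    protocol_slow,
    protocol_fast,
    n: int = 300,
    seed: int = 0,
    sigma_log: float | None = None,
):
    """Contour RMSD and %FRD before and after partial I_to block.

    ``block`` is the blocked fraction (0.75 = 75% conductance reduction).
    Reruns the baseline contour and the full population analysis with G_to
    scaled by (1 - block).  Returns {"control": (ContourResult, pct_frd),
    "blocked": (...)}.  Errors if the model has no G_to parameter.
    """
    from .models import get_model
    from .population import apply_exclusions, run_population, sample_population
    from .rate_dependence import build_table, percent_frd
    from .sensitivity import fit_population

    mdef = get_model(model_id)
    if "G_to" not in mdef.parameter_names:
        raise ValueError(f"{model_id} has no transient outward current parameter G_to")
    if not 0.0 <= block < 1.0:
        raise ValueError("block fraction must be in [0, 1)")
    sigma = sigma_log if sigma_log is not None else mdef.default_sigma_log

    out = {}
    for label, base_pert in (("control", {}), ("blocked", {"G_to": 1.0 - block})):
        # With block = 0 both arms are identical by construction.
        if block == 0.0 and label == "blocked":
            out[label] = out["control"]
            continue
        contour = baseline_contour(model_id, protocol_slow, protocol_fast, base_pert)
        samples = sample_population(list(mdef.registry), n, sigma, seed=seed)
        if base_pert:
            # compose the block with each trial's random G_to factor
            from .models import PerturbationSet

            composed = []
            for s in samples:
                vals = dict(s.perturbation)
                vals["G_to"] = vals.get("G_to", 1.0) * base_pert["G_to"]
                composed.append(
                    type(s)(trial_id=s.trial_id, perturbation=PerturbationSet(vals), seed=s.seed)
                )
            samples = composed
        pop = run_population(
            model_id, samples, protocol_slow, protocol_fast, sigma_log=sigma, seed=seed
        )
        apply_exclusions(pop)
        slow, fast, scaled = fit_population(pop, list(mdef.registry))
        table = build_table(slow.parameter_names, slow.coefficients, scaled)
        out[label] = (contour, percent_frd(table))
    return out


def frd_capacity_regression(points: list[tuple[float, float]]):
    """Linear fit of %FRD on RMSD across models.

    ``points`` holds (rmsd_mV, percent_frd) per model.  Returns
    (slope, intercept, r_squared, spearman_rho).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 models")
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    fit = stats.linregress(x, y)
    rho = float(stats.spearmanr(x, y).statistic)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2), rho
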