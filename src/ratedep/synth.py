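"""Synthetic fixtures with the statistical/structural properties the
analysis assumes, so every downstream stage is testable without ODE work.

Three generators:

* :func:`synth_ap` -- parametric AP waveforms (piecewise-linear upstroke /
  notch / plateau / repolarization) whose APD and per-"current" charge
  integrals have closed forms;
* :func:`synth_population` -- log-linear populations (log-APD = X beta +
  noise at each rate) with exactly recoverable standardized coefficients;
* :func:`synth_current_pair` -- the twelve-case taxonomy of how a current
  can respond to a perturbation at the two rates (inward/outward x
  increase/decrease x greater-at-slow / greater-at-fast / rate-neutral),
  with closed-form dQ values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import ParameterDescriptor
from .models.base import PerturbationSet
from .pacing import APTrace
from .population import PopulationSample

# ---------------------------------------------------------------------------
# waveforms


@dataclass(frozen=True)
class SyntheticWaveformSpec:
    """Piecewise-linear AP: rest -> upstroke -> (notch) -> plateau -> ramp down.

    The repolarization ramp runs from the plateau voltage to rest over
    ``repol_span`` ms; the plateau duration is solved so that the APD at
    ``apd_fraction`` equals ``apd`` exactly.
    """

    v_rest: float = -85.0  # mV
    v_peak: float = 15.0  # mV (also the plateau level unless notch given)
    notch_depth: float = 0.0  # mV drop after the peak
    notch_duration: float = 20.0  # ms
    apd: float = 245.0  # ms at apd_fraction
    repol_span: float = 50.0  # ms
    upstroke_duration: float = 1.0  # ms
    apd_fraction: float = 0.90
    current_amplitude: float = 1.0  # A/F, synthetic outward test current

    def threshold_voltage(self) -> float:
        return self.v_peak - self.apd_fraction * (self.v_peak - self.v_rest)

    def ramp_time_to_threshold(self) -> float:
        """Time along the repolarization ramp to reach the APD threshold."""
        v_thr = self.threshold_voltage()
        return self.repol_span * (self.v_peak - v_thr) / (self.v_peak - self.v_rest)

    def plateau_end(self) -> float:
        """Time (after max dV/dt) when the final ramp starts."""
        return self.apd - self.ramp_time_to_threshold()

    def synthetic_current_q(self, cycle_length: float) -> float:
        """Closed-form Q of the synthetic half-sine current over the AP.

        The current is ``A * sin(pi * t / APD)`` on [0, APD], zero after:
        integral = 2 * A * APD / pi.
        """
        return 2.0 * self.current_amplitude * self.apd / np.pi


def synth_ap(
    spec: SyntheticWaveformSpec, cycle_length: float, dt: float = 0.1
) -> APTrace:
    """Deterministic piecewise-linear AP trace with one synthetic current."""
    if spec.apd >= cycle_length:
        raise ValueError("APD must be below the cycle length")
    if spec.plateau_end() <= (spec.notch_duration if spec.notch_depth else 0.0):
        raise ValueError("APD too short for the requested notch/repolarization")
    t0 = 1.0  # stimulus-onset offset before the upstroke
    t_up = t0 + spec.upstroke_duration  # max-dV/dt sample (end of upstroke)
    # node points (time after t_up, voltage)
    nodes_t = [0.0]
    nodes_v = [spec.v_peak]
    if spec.notch_depth > 0:
        nodes_t += [0.35 * spec.notch_duration, spec.notch_duration]
        nodes_v += [spec.v_peak - spec.notch_depth, spec.v_peak]
    nodes_t += [spec.plateau_end(), spec.plateau_end() + spec.repol_span]
    nodes_v += [spec.v_peak, spec.v_rest]

    time = np.arange(0.0, cycle_length + 0.5 * dt, dt)
    v = np.full_like(time, spec.v_rest)
    up = (time >= t0) & (time < t_up)
    # quadratic ease-in so the maximum dV/dt falls at the upstroke end,
    # making the measured alignment point coincide with t_up
    s = (time[up] - t0) / spec.upstroke_duration
    v[up] = spec.v_rest + (spec.v_peak - spec.v_rest) * s * s
    after = time >= t_up
    rel = time[after] - t_up
    v[after] = np.interp(
        rel, nodes_t, nodes_v, right=spec.v_rest
    )
    i_syn = np.where(
        (time >= t_up) & (time <= t_up + spec.apd),
        spec.current_amplitude * np.sin(np.pi * (time - t_up) / spec.apd),
        0.0,
    )
    return APTrace(
        time=time,
        voltage=v,
        currents={"I_syn": i_syn, "I_stim": np.zeros_like(time)},
        apd=spec.apd,
        t_upstroke=t_up,
        v_peak=spec.v_peak,
        v_diastolic=spec.v_rest,
        cycle_length=cycle_length,
    )


# ---------------------------------------------------------------------------
# populations


@dataclass(frozen=True)
class SyntheticPopulationSpec:
    """Log-linear population: z-scored inputs map linearly to log-APD."""

    n_parameters: int = 8
    beta_slow: tuple[float, ...] = ()  # length n_parameters; default ramp
    beta_fast: tuple[float, ...] = ()
    noise_sd: float = 0.0  # on log-APD, same at both rates
    sigma_log: float = 0.1
    v_sd: float = 2.0
    n: int = 300
    n_v_parameters: int = 2  # how many of the parameters are V-category
    base_log_apd: float = float(np.log(300.0))
    seed: int = 0

    def resolved_betas(self) -> tuple[np.ndarray, np.ndarray]:
        if self.beta_slow:
            bs = np.asarray(self.beta_slow, dtype=float)
        else:
            bs = np.linspace(-0.05, 0.05, self.n_parameters)
        if self.beta_fast:
            bf = np.asarray(self.beta_fast, dtype=float)
        else:
            bf = bs.copy()
        if len(bs) != self.n_parameters or len(bf) != self.n_parameters:
            raise ValueError("beta length must equal n_parameters")
        return bs, bf


@dataclass
class SyntheticPopulation:
    spec: SyntheticPopulationSpec
    registry: list[ParameterDescriptor]
    samples: list[PopulationSample]
    apd_slow: dict[int, float]
    apd_fast: dict[int, float]
    # standardized coefficients the pipeline regression should recover
    # exactly in the noiseless case: beta / sd(log-APD) per rate
    beta_standardized_slow: np.ndarray = field(default=None)
    beta_standardized_fast: np.ndarray = field(default=None)


def synthetic_registry(
    n_parameters: int, n_v: int = 2
) -> list[ParameterDescriptor]:
    """A registry of made-up parameters (G-category plus ``n_v`` V-shifts)."""
    reg = []
    for i in range(n_parameters - n_v):
        reg.append(
            ParameterDescriptor(f"G_syn{i}", "G", 1.0, "a.u.", "synthetic conductance")
        )
    for i in range(n_v):
        reg.append(
            ParameterDescriptor(f"V_syn{i}", "V", 0.0, "mV", "synthetic voltage shift")
        )
    return reg


def synth_population(spec: SyntheticPopulationSpec) -> SyntheticPopulation:
    """Generate samples + APDs satisfying log-APD = X beta + noise exactly.

    X is the empirically z-scored transform the sensitivity module builds
    (log of scale factors, raw shifts), so with ``noise_sd = 0`` the
    pipeline recovers ``beta_standardized_*`` to machine precision.
    """
    if spec.n <= spec.n_parameters:
        raise ValueError("need n > n_parameters")
    registry = synthetic_registry(spec.n_parameters, spec.n_v_parameters)
    rng = np.random.default_rng(spec.seed)
    raw = np.empty((spec.n, spec.n_parameters))
    for k, d in enumerate(registry):
        if d.category == "V":
            raw[:, k] = rng.normal(0.0, spec.v_sd, spec.n)
        else:
            raw[:, k] = np.exp(rng.normal(0.0, spec.sigma_log, spec.n))
    trans = np.column_stack(
        [
            raw[:, k] if registry[k].category == "V" else np.log(raw[:, k])
            for k in range(spec.n_parameters)
        ]
    )
    X = (trans - trans.mean(axis=0)) / trans.std(axis=0)

    bs, bf = spec.resolved_betas()
    samples = [
        PopulationSample(
            trial_id=i,
            perturbation=PerturbationSet(
                {d.name: float(raw[i, k]) for k, d in enumerate(registry)}
            ),
            seed=spec.seed,
        )
        for i in range(spec.n)
    ]
    out = SyntheticPopulation(
        spec=spec, registry=registry, samples=samples, apd_slow={}, apd_fast={}
    )
    for label, beta in (("slow", bs), ("fast", bf)):
        noise = rng.normal(0.0, spec.noise_sd, spec.n) if spec.noise_sd > 0 else 0.0
        y_log = spec.base_log_apd + X @ beta + noise
        apds = {i: float(np.exp(y_log[i])) for i in range(spec.n)}
        sd = float(y_log.std())
        if label == "slow":
            out.apd_slow = apds
            out.beta_standardized_slow = beta / sd
        else:
            out.apd_fast = apds
            out.beta_standardized_fast = beta / sd
    return out


# ---------------------------------------------------------------------------
# current-pair taxonomy

# family -> (direction, change, rate_bias); direction -1 = inward current,
# change +1 = magnitude increases with the perturbation, rate_bias "slow" =
# the change is larger at slow pacing ("fast"/"none" likewise).
CURRENT_FAMILIES = {
    "I1": (-1, +1, "slow"),  # inward increase, greater at slow  -> RRD
    "I2": (+1, -1, "slow"),  # outward decrease, greater at slow -> RRD
    "I3": (-1, -1, "fast"),  # inward decrease, greater at fast  -> RRD
    "I4": (+1, +1, "fast"),  # outward increase, greater at fast -> RRD
    "I5": (-1, -1, "slow"),  # inward decrease, greater at slow  -> FRD
    "I6": (+1, +1, "slow"),  # outward increase, greater at slow -> FRD
    "I7": (-1, +1, "fast"),  # inward increase, greater at fast  -> FRD
    "I8": (+1, -1, "fast"),  # outward decrease, greater at fast -> FRD
    "I9": (-1, +1, "none"),  # rate-neutral cases
    "I10": (+1, -1, "none"),
    "I11": (-1, -1, "none"),
    "I12": (+1, +1, "none"),
}


@dataclass(frozen=True)
class CurrentPair:
    family: str
    time: np.ndarray  # shared grid, ms
    control_slow: np.ndarray
    perturbed_slow: np.ndarray
    control_fast: np.ndarray
    perturbed_fast: np.ndarray
    dq_slow: float  # closed form, pC/nF
    dq_fast: float


def synth_current_pair(
    family: str,
    duration: float = 200.0,
    amplitude: float = 1.0,
    effect: float = 0.30,
    bias: float = 3.0,
    dt: float = 0.1,
) -> CurrentPair:
    """Half-sine current under control/perturbed x slow/fast conditions.

    ``effect`` is the fractional magnitude change caused by the perturbation
    at the less-affected rate; ``bias`` multiplies it at the favored rate.
    dQ values follow the closed form Q = sign * 2 A T / pi.
    """
    if family not in CURRENT_FAMILIES:
        raise KeyError(f"unknown family {family!r}; use one of {sorted(CURRENT_FAMILIES)}")
    sign, change, rate_bias = CURRENT_FAMILIES[family]
    time = np.arange(0.0, duration + 0.5 * dt, dt)
    base = sign * amplitude * np.sin(np.pi * time / duration)

    def scaled(rate: str) -> tuple[np.ndarray, float]:
        eff = effect * (bias if rate_bias == rate else 1.0)
        if rate_bias == "none":
            eff = effect
        factor = 1.0 + change * eff
        q0 = sign * 2.0 * amplitude * duration / np.pi
        return base * factor, q0 * (factor - 1.0)

    pert_slow, dq_slow = scaled("slow")
    pert_fast, dq_fast = scaled("fast")
    return CurrentPair(
        family=family,
        time=time,
        control_slow=base.copy(),
        perturbed_slow=pert_slow,
        control_fast=base.copy(),
        perturbed_fast=pert_fast,
        dq_slow=dq_slow,
        dq_fast=dq_fast,
    )
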