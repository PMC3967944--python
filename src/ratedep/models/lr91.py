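"""Luo-Rudy 1991 guinea-pig ventricular model (LR91).

Phase-1 model: six membrane currents, fixed Na+/K+ concentrations, a single
intracellular Ca2+ pool driven by the slow inward current.  Gates are
integrated by Rush-Larsen using the steady-state/time-constant form derived
from the published alpha/beta rate expressions.  V-category shifts move the
steady-state curve only (x_inf evaluated at V - shift); p-category factors
scale the gate rate (tau_eff = tau / p).

State vector: [V, m, h, j, d, f, x, Cai]  (mV, gates dimensionless, mM)
Currents (A/F == uA/uF, outward positive): I_Na, I_si, I_K, I_K1, I_Kp, I_b
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .base import ModelDefinition, ParameterDescriptor

# Fixed concentrations (mM) and Nernst potentials (mV) of the published model
ENA = 54.4
EK = -77.0
EK1 = -87.2
GNA = 23.0
GSI = 0.09
GK = 0.282  # * sqrt(Ko/5.4) = 1 at Ko = 5.4
GK1 = 0.6047
GKP = 0.0183
GB = 0.03921

# registry indices
IG_NA, IG_SI, IG_K, IG_K1, IG_KP, IG_B = 0, 1, 2, 3, 4, 5
IP_M, IP_H, IP_J, IP_D, IP_F, IP_X = 6, 7, 8, 9, 10, 11
IV_M, IV_H, IV_J, IV_D, IV_F, IV_X = 12, 13, 14, 15, 16, 17


@njit(cache=False, inline="always")
def _ab_m(v):
    dv = v + 47.13
    if abs(dv) < 1.0e-6:
        a = 3.2
    else:
        a = 0.32 * dv / (1.0 - math.exp(-0.1 * dv))
    b = 0.08 * math.exp(-v / 11.0)
    return a, b


@njit(cache=False, inline="always")
def _ab_h(v):
    if v < -40.0:
        a = 0.135 * math.exp(-(80.0 + v) / 6.8)
        b = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
    else:
        a = 0.0
        b = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    return a, b


@njit(cache=False, inline="always")
def _ab_j(v):
    if v < -40.0:
        a = (
            (-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + math.exp(0.311 * (v + 79.23)))
        )
        b = 0.1212 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    else:
        a = 0.0
        b = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    return a, b


@njit(cache=False, inline="always")
def _ab_d(v):
    a = 0.095 * math.exp(-0.01 * (v - 5.0)) / (1.0 + math.exp(-0.072 * (v - 5.0)))
    b = 0.07 * math.exp(-0.017 * (v + 44.0)) / (1.0 + math.exp(0.05 * (v + 44.0)))
    return a, b


@njit(cache=False, inline="always")
def _ab_f(v):
    a = 0.012 * math.exp(-0.008 * (v + 28.0)) / (1.0 + math.exp(0.15 * (v + 28.0)))
    b = 0.0065 * math.exp(-0.02 * (v + 30.0)) / (1.0 + math.exp(-0.2 * (v + 30.0)))
    return a, b


@njit(cache=False, inline="always")
def _ab_x(v):
    a = 0.0005 * math.exp(0.083 * (v + 50.0)) / (1.0 + math.exp(0.057 * (v + 50.0)))
    b = 0.0013 * math.exp(-0.06 * (v + 20.0)) / (1.0 + math.exp(-0.04 * (v + 20.0)))
    return a, b


@njit(cache=False, inline="always")
def _xi(v):
    if v > -100.0:
        dv = v + 77.0
        if abs(dv) < 1.0e-4:
            return 2.837 * 0.04 / math.exp(0.04 * (v + 35.0))
        return 2.837 * (math.exp(0.04 * dv) - 1.0) / (dv * math.exp(0.04 * (v + 35.0)))
    return 1.0


@njit(cache=False, inline="always")
def _gate(x, v, p_scale, v_shift, ab, dt):
    """Rush-Larsen update: x_inf at shifted V, rate alpha+beta scaled by p."""
    a_s, b_s = ab(v - v_shift)
    xinf = a_s / (a_s + b_s)
    a, b = ab(v)
    rate = (a + b) * p_scale
    return xinf + (x - xinf) * math.exp(-dt * rate)


@njit(cache=False)
def _currents(y, p, out):
    v = y[0]
    m, h, j, d, f, x = y[1], y[2], y[3], y[4], y[5], y[6]
    cai = y[7]
    out[0] = p[IG_NA] * m * m * m * h * j * (v - ENA)
    esi = 7.7 - 13.0287 * math.log(cai)
    out[1] = p[IG_SI] * d * f * (v - esi)
    out[2] = p[IG_K] * x * _xi(v) * (v - EK)
    ak1 = 1.02 / (1.0 + math.exp(0.2385 * (v - EK1 - 59.215)))
    bk1 = (
        0.49124 * math.exp(0.08032 * (v - EK1 + 5.476))
        + math.exp(0.06175 * (v - EK1 - 594.31))
    ) / (1.0 + math.exp(-0.5143 * (v - EK1 + 4.753)))
    out[3] = p[IG_K1] * ak1 / (ak1 + bk1) * (v - EK1)
    kp = 1.0 / (1.0 + math.exp((7.488 - v) / 5.98))
    out[4] = p[IG_KP] * kp * (v - EK1)
    out[5] = p[IG_B] * (v + 59.87)


@njit(cache=False)
def _step(y, p, dt, istim):
    v = y[0]
    cur = np.empty(6)
    _currents(y, p, cur)
    i_ion = cur[0] + cur[1] + cur[2] + cur[3] + cur[4] + cur[5]
    y[1] = _gate(y[1], v, p[IP_M], p[IV_M], _ab_m, dt)
    y[2] = _gate(y[2], v, p[IP_H], p[IV_H], _ab_h, dt)
    y[3] = _gate(y[3], v, p[IP_J], p[IV_J], _ab_j, dt)
    y[4] = _gate(y[4], v, p[IP_D], p[IV_D], _ab_d, dt)
    y[5] = _gate(y[5], v, p[IP_F], p[IV_F], _ab_f, dt)
    y[6] = _gate(y[6], v, p[IP_X], p[IV_X], _ab_x, dt)
    isi = cur[1]
    y[7] = y[7] + dt * (-1.0e-4 * isi + 0.07 * (1.0e-4 - y[7]))
    y[0] = v - dt * (i_ion + istim)


def _registry() -> tuple[ParameterDescriptor, ...]:
    g = [
        ("G_Na", GNA, "mS/uF", "fast Na+ conductance (I_Na)"),
        ("G_si", GSI, "mS/uF", "slow inward Ca2+ conductance (I_si)"),
        ("G_K", GK, "mS/uF", "time-dependent K+ conductance (I_K)"),
        ("G_K1", GK1, "mS/uF", "inward-rectifier K+ conductance (I_K1)"),
        ("G_Kp", GKP, "mS/uF", "plateau K+ conductance (I_Kp)"),
        ("G_b", GB, "mS/uF", "background conductance (I_b)"),
    ]
    p = [
        ("p_m", "I_Na activation gate m rate"),
        ("p_h", "I_Na fast inactivation gate h rate"),
        ("p_j", "I_Na slow inactivation gate j rate"),
        ("p_d", "I_si activation gate d rate"),
        ("p_f", "I_si inactivation gate f rate"),
        ("p_x", "I_K activation gate x rate"),
    ]
    v = [
        ("V_m", "I_Na activation V1/2 (gate m)"),
        ("V_h", "I_Na fast inactivation V1/2 (gate h)"),
        ("V_j", "I_Na slow inactivation V1/2 (gate j)"),
        ("V_d", "I_si activation V1/2 (gate d)"),
        ("V_f", "I_si inactivation V1/2 (gate f)"),
        ("V_x", "I_K activation V1/2 (gate x)"),
    ]
    reg = [ParameterDescriptor(n, "G", b, u, t) for n, b, u, t in g]
    reg += [ParameterDescriptor(n, "p", 1.0, "dimensionless", t) for n, t in p]
    reg += [ParameterDescriptor(n, "V", 0.0, "mV", t) for n, t in v]
    return tuple(reg)


DEFINITION = ModelDefinition(
    model_id="LR91",
    species="guinea pig",
    layer=None,
    citation="Luo & Rudy, Circ Res 68:1501-1526 (1991)",
    state_names=("V", "m", "h", "j", "d", "f", "x", "Cai"),
    initial_state=np.array(
        [-84.548, 0.0017, 0.9832, 0.9895, 0.003, 0.9999, 0.0057, 1.78e-4]
    ),
    registry=_registry(),
    current_names=("I_Na", "I_si", "I_K", "I_K1", "I_Kp", "I_b"),
    stim_amplitude=-80.0,
    stim_duration=0.5,
    default_sigma_log=0.1,
    dt_fine=0.02,
    dt_coarse=0.25,
    step=_step,
    currents=_currents,
)
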