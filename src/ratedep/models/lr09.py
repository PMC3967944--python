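"""Guinea-pig dynamic ventricular model of the Luo-Rudy lineage (LR09).

Dynamic descendant of LR91: GHK-flux L-type Ca2+ current with Ca-dependent
inactivation, separated rapid (I_Kr) and slow (I_Ks, two activation gates)
delayed rectifiers, Na+/K+ pump, Na+/Ca2+ exchanger, sarcolemmal Ca2+ pump,
and a two-compartment sarcoplasmic reticulum (NSR/JSR) with SERCA uptake,
NSR leak, NSR->JSR translocation, and Ca2+-induced Ca2+ release.  The
release flux uses a phenomenological activation variable driven by the
L-type trigger current (first-order, tau 4.75 ms); the remainder follows
the published dynamic Luo-Rudy formulations.  Intracellular Na+, K+ and
Ca2+ are dynamic; cytosolic (troponin/calmodulin) and JSR (calsequestrin)
buffering uses the steady-state rapid-buffer approximation.

State vector (15):
  [V, Nai, Ki, Cai, CaNSR, CaJSR, m, h, j, d, f, xr, xs1, xs2, u]
  V mV, concentrations mM, gates dimensionless, u = CICR activation.

Current roster (A/F, outward positive):
  I_Na, I_CaL, I_Kr, I_Ks, I_K1, I_Kp, I_NaCa, I_NaK, I_pCa, I_bCa, I_bNa
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .base import ModelDefinition, ParameterDescriptor

R_GAS = 8314.0
TEMP = 310.0
FARADAY = 96485.0
RTF = R_GAS * TEMP / FARADAY

KO = 4.5
NAO = 140.0
CAO = 1.8

ACAP = 1.534e-4  # cm^2, capacitive membrane area
VMYO = 25.84e-6  # uL
VNSR = 2.098e-6
VJSR = 0.182e-6

G_NA = 16.0
P_CA = 5.4e-4  # cm/s, L-type Ca2+ permeability
G_KR = 0.02614 * math.sqrt(KO / 5.4)
G_KS = 0.433  # multiplied by a Ca-dependent factor in the kernel
G_K1 = 0.75 * math.sqrt(KO / 5.4)
G_KP = 5.52e-3
K_NAK = 2.25
K_NCX = 2.5e-4
K_PCA = 1.15
G_BCA = 3.016e-3
G_BNA = 1.0e-3
V_SERCA = 8.75e-3  # mM/ms
K_M_UP = 9.2e-4  # mM
CA_NSR_MAX = 15.0  # mM
TAU_TR = 120.0  # ms
G_REL = 8.0  # 1/ms, maximal CICR release rate
TAU_U = 4.75  # ms, CICR activation time constant
K_TRIG = 0.5  # A/F, half-activation of the CICR trigger

TRPN_MAX = 0.07
KM_TRPN = 0.5e-3
CMDN_MAX = 0.05
KM_CMDN = 2.38e-3
CSQN_MAX = 10.0
KM_CSQN = 0.8

PR_NAK = 0.01833

IG_NA, IG_CAL, IG_KR, IG_KS, IG_K1, IG_KP, IG_BCA, IG_BNA = range(8)
IK_NAK, IK_NCX, IK_PCA, IK_SERCA, IK_REL = range(8, 13)
IP_M, IP_H, IP_J, IP_D, IP_F, IP_XR, IP_XS1, IP_XS2 = range(13, 21)
IV_M, IV_H, IV_J, IV_D, IV_F, IV_XR, IV_XS = range(21, 28)
N_REG = 28


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
def _gate_ab(x, v, p_scale, v_shift, ab, dt):
    a_s, b_s = ab(v - v_shift)
    xinf = a_s / (a_s + b_s)
    a, b = ab(v)
    return xinf + (x - xinf) * math.exp(-dt * (a + b) * p_scale)


@njit(cache=False, inline="always")
def _ibarca(pca, v, cai):
    """GHK flux of Ca2+ through the L-type channel (A/F per open channel)."""
    if abs(v) < 1.0e-4:
        return pca * 2.0 * FARADAY * (cai - 0.341 * CAO)
    z = 2.0 * v / RTF
    ez = math.exp(z)
    return pca * 4.0 * v * FARADAY / RTF * (cai * ez - 0.341 * CAO) / (ez - 1.0)


@njit(cache=False)
def _currents(y, p, out):
    v = y[0]
    nai, ki, cai = y[1], y[2], y[3]
    m, h, j = y[6], y[7], y[8]
    d, f = y[9], y[10]
    xr, xs1, xs2 = y[11], y[12], y[13]

    ena = RTF * math.log(NAO / nai)
    ek = RTF * math.log(KO / ki)
    eks = RTF * math.log((KO + PR_NAK * NAO) / (ki + PR_NAK * nai))
    eca = 0.5 * RTF * math.log(CAO / cai)

    out[0] = p[IG_NA] * m * m * m * h * j * (v - ena)

    fca = 1.0 / (1.0 + (cai / 6.0e-4) ** 2)
    out[1] = d * f * fca * _ibarca(p[IG_CAL], v, cai)

    r_kr = 1.0 / (1.0 + math.exp((v + 9.0) / 22.4))
    out[2] = p[IG_KR] * xr * r_kr * (v - ek)

    gks_ca = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    out[3] = p[IG_KS] * gks_ca * xs1 * xs2 * (v - eks)

    ak1 = 1.02 / (1.0 + math.exp(0.2385 * (v - ek - 59.215)))
    bk1 = (
        0.49124 * math.exp(0.08032 * (v - ek + 5.476))
        + math.exp(0.06175 * (v - ek - 594.31))
    ) / (1.0 + math.exp(-0.5143 * (v - ek + 4.753)))
    out[4] = p[IG_K1] * ak1 / (ak1 + bk1) * (v - ek)

    out[5] = p[IG_KP] * (v - ek) / (1.0 + math.exp((7.488 - v) / 5.98))

    ef = math.exp(0.15 * v / RTF)
    er = math.exp(-0.85 * v / RTF)
    num = ef * nai**3 * CAO - er * NAO**3 * cai
    den = 1.0 + 1.0e-4 * (ef * nai**3 * CAO + er * NAO**3 * cai)
    out[6] = p[IK_NCX] * num / den

    sigma = (math.exp(NAO / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (
        1.0 + 0.1245 * math.exp(-0.1 * v / RTF) + 0.0365 * sigma * math.exp(-v / RTF)
    )
    out[7] = p[IK_NAK] * fnak / (1.0 + (10.0 / nai) ** 2) * KO / (KO + 1.5)

    out[8] = p[IK_PCA] * cai / (cai + 5.0e-4)
    out[9] = p[IG_BCA] * (v - eca)
    out[10] = p[IG_BNA] * (v - ena)


@njit(cache=False)
def _step(y, p, dt, istim):
    v = y[0]
    cur = np.empty(11)
    _currents(y, p, cur)
    i_cal = cur[1]
    i_ion = (
        cur[0] + cur[1] + cur[2] + cur[3] + cur[4] + cur[5]
        + cur[6] + cur[7] + cur[8] + cur[9] + cur[10]
    )

    y[6] = _gate_ab(y[6], v, p[IP_M], p[IV_M], _ab_m, dt)
    y[7] = _gate_ab(y[7], v, p[IP_H], p[IV_H], _ab_h, dt)
    y[8] = _gate_ab(y[8], v, p[IP_J], p[IV_J], _ab_j, dt)

    # I_CaL activation d: tau from the published closed form at unshifted V
    dinf_s = 1.0 / (1.0 + math.exp(-((v - p[IV_D]) + 10.0) / 6.24))
    dinf_v = 1.0 / (1.0 + math.exp(-(v + 10.0) / 6.24))
    if abs(v + 10.0) < 1.0e-4:
        taud = dinf_v / (6.24 * 0.035)
    else:
        taud = dinf_v * (1.0 - math.exp(-(v + 10.0) / 6.24)) / (0.035 * (v + 10.0))
    y[9] = dinf_s + (y[9] - dinf_s) * math.exp(-dt * p[IP_D] / taud)

    vf = v - p[IV_F]
    finf = 1.0 / (1.0 + math.exp((vf + 32.0) / 8.0)) + 0.6 / (
        1.0 + math.exp((50.0 - vf) / 20.0)
    )
    tauf = 1.0 / (0.0197 * math.exp(-((0.0337 * (v + 10.0)) ** 2)) + 0.02)
    y[10] = finf + (y[10] - finf) * math.exp(-dt * p[IP_F] / tauf)

    vxr = v - p[IV_XR]
    xrinf = 1.0 / (1.0 + math.exp(-(vxr + 21.5) / 7.5))
    if abs(v + 14.2) < 1.0e-4:
        axr = 0.0013 / 0.123
    else:
        axr = 0.0013 * (v + 14.2) / (1.0 - math.exp(-0.123 * (v + 14.2)))
    if abs(v + 38.9) < 1.0e-4:
        bxr = 0.000061 / 0.145
    else:
        bxr = 0.000061 * (v + 38.9) / (math.exp(0.145 * (v + 38.9)) - 1.0)
    y[11] = xrinf + (y[11] - xrinf) * math.exp(-dt * p[IP_XR] * (axr + bxr))

    vxs = v - p[IV_XS]
    xsinf = 1.0 / (1.0 + math.exp(-(vxs - 1.5) / 16.7))
    if abs(v + 30.0) < 1.0e-4:
        axs = 7.19e-5 / 0.148
        bxs = 1.31e-4 / 0.0687
    else:
        axs = 7.19e-5 * (v + 30.0) / (1.0 - math.exp(-0.148 * (v + 30.0)))
        bxs = 1.31e-4 * (v + 30.0) / (math.exp(0.0687 * (v + 30.0)) - 1.0)
    y[12] = xsinf + (y[12] - xsinf) * math.exp(-dt * (axs + bxs) * p[IP_XS1])
    y[13] = xsinf + (y[13] - xsinf) * math.exp(-dt * (axs + bxs) / 4.0 * p[IP_XS2])

    # --- calcium handling ---
    nai, ki, cai, cansr, cajsr = y[1], y[2], y[3], y[4], y[5]

    trig = -i_cal if i_cal < 0.0 else 0.0
    uinf = trig * trig / (trig * trig + K_TRIG * K_TRIG)
    y[14] = uinf + (y[14] - uinf) * math.exp(-dt / TAU_U)

    j_rel = p[IK_REL] * y[14] * (cajsr - cai)
    j_up = p[IK_SERCA] * cai / (cai + K_M_UP)
    j_leak = p[IK_SERCA] * cansr / CA_NSR_MAX
    j_tr = (cansr - cajsr) / TAU_TR

    bmyo = 1.0 / (
        1.0
        + TRPN_MAX * KM_TRPN / (cai + KM_TRPN) ** 2
        + CMDN_MAX * KM_CMDN / (cai + KM_CMDN) ** 2
    )
    bjsr = 1.0 / (1.0 + CSQN_MAX * KM_CSQN / (cajsr + KM_CSQN) ** 2)

    i_ca_tot = cur[1] + cur[8] + cur[9] - 2.0 * cur[6]
    dcai = bmyo * (
        -i_ca_tot * ACAP / (2.0 * VMYO * FARADAY)
        + (j_leak - j_up) * VNSR / VMYO
        + j_rel * VJSR / VMYO
    )
    y[3] = cai + dt * dcai
    y[4] = cansr + dt * (j_up - j_leak - j_tr * VJSR / VNSR)
    y[5] = cajsr + dt * bjsr * (j_tr - j_rel)

    i_na_tot = cur[0] + cur[10] + 3.0 * cur[7] + 3.0 * cur[6]
    i_k_tot = cur[2] + cur[3] + cur[4] + cur[5] - 2.0 * cur[7] + istim
    y[1] = nai - dt * i_na_tot * ACAP / (VMYO * FARADAY)
    y[2] = ki - dt * i_k_tot * ACAP / (VMYO * FARADAY)

    y[0] = v - dt * (i_ion + istim)


def _registry() -> tuple[ParameterDescriptor, ...]:
    g = [
        ("G_Na", G_NA, "mS/uF", "fast Na+ conductance (I_Na)"),
        ("G_CaL", P_CA, "cm/s", "L-type Ca2+ permeability (I_CaL)"),
        ("G_Kr", G_KR, "mS/uF", "rapid delayed rectifier conductance (I_Kr)"),
        ("G_Ks", G_KS, "mS/uF", "slow delayed rectifier conductance (I_Ks)"),
        ("G_K1", G_K1, "mS/uF", "inward rectifier conductance (I_K1)"),
        ("G_Kp", G_KP, "mS/uF", "plateau K+ conductance (I_Kp)"),
        ("G_bCa", G_BCA, "mS/uF", "background Ca2+ conductance (I_bCa)"),
        ("G_bNa", G_BNA, "mS/uF", "background Na+ conductance (I_bNa)"),
    ]
    k = [
        ("K_NaK", K_NAK, "A/F", "Na+/K+ pump maximum rate (I_NaK)"),
        ("K_NCX", K_NCX, "A/F", "Na+/Ca2+ exchanger scale (I_NaCa)"),
        ("K_pCa", K_PCA, "A/F", "sarcolemmal Ca2+ pump maximum (I_pCa)"),
        ("K_SERCA", V_SERCA, "mM/ms", "SERCA SR uptake maximum rate"),
        ("K_rel", G_REL, "1/ms", "SR release rate scale (CICR)"),
    ]
    p = [
        ("p_m", "I_Na activation gate m rate"),
        ("p_h", "I_Na fast inactivation gate h rate"),
        ("p_j", "I_Na slow inactivation gate j rate"),
        ("p_d", "I_CaL activation gate d rate"),
        ("p_f", "I_CaL inactivation gate f rate"),
        ("p_xr", "I_Kr activation gate xr rate"),
        ("p_xs1", "I_Ks fast activation gate xs1 rate"),
        ("p_xs2", "I_Ks slow activation gate xs2 rate"),
    ]
    v = [
        ("V_m", "I_Na activation V1/2 (gate m)"),
        ("V_h", "I_Na fast inactivation V1/2 (gate h)"),
        ("V_j", "I_Na slow inactivation V1/2 (gate j)"),
        ("V_d", "I_CaL activation V1/2 (gate d)"),
        ("V_f", "I_CaL inactivation V1/2 (gate f)"),
        ("V_xr", "I_Kr activation V1/2 (gate xr)"),
        ("V_xs", "I_Ks activation V1/2 (gates xs1/xs2)"),
    ]
    reg = [ParameterDescriptor(n, "G", b, u, t) for n, b, u, t in g]
    reg += [ParameterDescriptor(n, "K", b, u, t) for n, b, u, t in k]
    reg += [ParameterDescriptor(n, "p", 1.0, "dimensionless", t) for n, t in p]
    reg += [ParameterDescriptor(n, "V", 0.0, "mV", t) for n, t in v]
    return tuple(reg)


_STATE_NAMES = (
    "V", "Nai", "Ki", "Cai", "CaNSR", "CaJSR",
    "m", "h", "j", "d", "f", "xr", "xs1", "xs2", "u",
)

DEFINITION = ModelDefinition(
    model_id="LR09",
    species="guinea pig",
    layer=None,
    citation="Luo-Rudy dynamic lineage (Luo & Rudy 1994; Livshitz & Rudy 2009); "
    "CICR trigger simplified, see module docstring",
    state_names=_STATE_NAMES,
    initial_state=np.array(
        [
            -88.0, 12.0, 140.0, 1.0e-4, 1.8, 1.8,
            0.0012, 0.98, 0.99, 1.0e-5, 0.99, 1.0e-4, 0.01, 0.05, 0.0,
        ]
    ),
    registry=_registry(),
    current_names=(
        "I_Na", "I_CaL", "I_Kr", "I_Ks", "I_K1", "I_Kp",
        "I_NaCa", "I_NaK", "I_pCa", "I_bCa", "I_bNa",
    ),
    stim_amplitude=-80.0,
    stim_duration=0.5,
    default_sigma_log=0.1823,
    dt_fine=0.02,
    dt_coarse=0.25,
    step=_step,
    currents=_currents,
)
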