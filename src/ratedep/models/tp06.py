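"""ten Tusscher & Panfilov 2006 human ventricular model (TP06).

Three transmural layers (epicardial, mid-myocardial, endocardial) sharing one
compiled kernel; layer-specific maximal conductances enter through the
registry baselines and the endocardial s-gate variant through a structural
flag appended to the parameter vector.

State vector (19):
  [V, Nai, Ki, Cai, CaSR, CaSS, m, h, j, d, f, f2, fCass, r, s, xr1, xr2, xs, Rq]
  V mV; concentrations mM; gates dimensionless; Rq = fraction of closed,
  non-refractory ryanodine receptors.

Current roster (A/F, outward positive):
  I_Na, I_CaL, I_to, I_Kr, I_Ks, I_K1, I_NaCa, I_NaK, I_pCa, I_pK, I_bNa, I_bCa
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .base import ModelDefinition, ParameterDescriptor

# Physical constants and cell geometry
R_GAS = 8314.472  # mJ/(mol K)
TEMP = 310.0  # K
FARADAY = 96485.3415  # C/mol
RTF = R_GAS * TEMP / FARADAY
CM = 0.185  # uF (cell capacitance used by the published concentration fluxes)
VC = 0.016404  # uL, cytoplasm
VSR = 0.001094  # uL, sarcoplasmic reticulum
VSS = 0.00005468  # uL, subsarcolemmal space

KO = 5.4
NAO = 140.0
CAO = 2.0
PKNA = 0.03

# Baselines shared by layers
G_NA = 14.838
G_CAL = 3.98e-5
G_KR = 0.153
G_K1 = 5.405
G_PK = 0.0146
G_PCA = 0.1238
G_BNA = 2.9e-4
G_BCA = 5.92e-4
P_NAK = 2.724
K_NACA = 1000.0
VMAX_UP = 6.375e-3
V_REL = 0.102
V_LEAK = 3.6e-4
V_XFER = 3.8e-3

KM_NAI = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
ALPHA_NCX = 2.5
KM_K = 1.0
KM_NA = 40.0
K_PCA = 5.0e-4
K_UP = 2.5e-4
K1P = 0.15
K2P = 0.045
K3 = 0.060
K4 = 0.005
MAX_SR = 2.5
MIN_SR = 1.0
EC_SR = 1.5
BUF_C = 0.2
K_BUF_C = 0.001
BUF_SR = 10.0
K_BUF_SR = 0.3
BUF_SS = 0.4
K_BUF_SS = 2.5e-4

# registry indices (effective values: baseline * scale; V entries are shifts)
IG_NA, IG_CAL, IG_TO, IG_KR, IG_KS, IG_K1, IG_PK, IG_PCA, IG_BNA, IG_BCA = range(10)
IK_NAK, IK_NCX, IK_SERCA, IK_REL, IK_LEAK, IK_XFER = range(10, 16)
IP_M, IP_H, IP_J, IP_D, IP_F, IP_F2, IP_XR1, IP_XR2, IP_XS, IP_R, IP_S = range(16, 27)
IV_M, IV_H, IV_D, IV_F, IV_XR1, IV_XR2, IV_XS, IV_ATO, IV_ITO = range(27, 36)
N_REG = 36
I_ENDO_FLAG = 36  # const slot: 1.0 for the endocardial s-gate variant


@njit(cache=False)
def _currents(y, p, out):
    v = y[0]
    nai, ki, cai, cass = y[1], y[2], y[3], y[5]
    m, h, j = y[6], y[7], y[8]
    d, f, f2, fcass = y[9], y[10], y[11], y[12]
    r, s = y[13], y[14]
    xr1, xr2, xs = y[15], y[16], y[17]

    ena = RTF * math.log(NAO / nai)
    ek = RTF * math.log(KO / ki)
    eks = RTF * math.log((KO + PKNA * NAO) / (ki + PKNA * nai))
    eca = 0.5 * RTF * math.log(CAO / cai)

    out[0] = p[IG_NA] * m * m * m * h * j * (v - ena)

    dv15 = v - 15.0
    z = 2.0 * dv15 / RTF
    if abs(dv15) < 1.0e-4:
        ghk = 2.0 * FARADAY * (0.25 * cass - CAO)
    else:
        ghk = 4.0 * dv15 * FARADAY / RTF * (0.25 * cass * math.exp(z) - CAO) / (
            math.exp(z) - 1.0
        )
    out[1] = p[IG_CAL] * d * f * f2 * fcass * ghk

    out[2] = p[IG_TO] * r * s * (v - ek)
    out[3] = p[IG_KR] * math.sqrt(KO / 5.4) * xr1 * xr2 * (v - ek)
    out[4] = p[IG_KS] * xs * xs * (v - eks)

    a1 = 0.1 / (1.0 + math.exp(0.06 * (v - ek - 200.0)))
    b1 = (
        3.0 * math.exp(0.0002 * (v - ek + 100.0)) + math.exp(0.1 * (v - ek - 10.0))
    ) / (1.0 + math.exp(-0.5 * (v - ek)))
    out[5] = p[IG_K1] * math.sqrt(KO / 5.4) * a1 / (a1 + b1) * (v - ek)

    ef = math.exp(GAMMA * v / RTF)
    er = math.exp((GAMMA - 1.0) * v / RTF)
    out[6] = (
        p[IK_NCX]
        * (ef * nai**3 * CAO - er * NAO**3 * cai * ALPHA_NCX)
        / ((KM_NAI**3 + NAO**3) * (KM_CA + CAO) * (1.0 + K_SAT * er))
    )

    out[7] = (
        p[IK_NAK]
        * KO
        * nai
        / (
            (KO + KM_K)
            * (nai + KM_NA)
            * (1.0 + 0.1245 * math.exp(-0.1 * v / RTF) + 0.0353 * math.exp(-v / RTF))
        )
    )

    out[8] = p[IG_PCA] * cai / (cai + K_PCA)
    out[9] = p[IG_PK] * (v - ek) / (1.0 + math.exp((25.0 - v) / 5.98))
    out[10] = p[IG_BNA] * (v - ena)
    out[11] = p[IG_BCA] * (v - eca)


@njit(cache=False)
def _step(y, p, dt, istim):
    v = y[0]
    cur = np.empty(12)
    _currents(y, p, cur)
    i_na, i_cal, i_to, i_kr, i_ks, i_k1 = cur[0], cur[1], cur[2], cur[3], cur[4], cur[5]
    i_naca, i_nak, i_pca, i_pk, i_bna, i_bca = (
        cur[6],
        cur[7],
        cur[8],
        cur[9],
        cur[10],
        cur[11],
    )
    i_ion = (
        i_na + i_cal + i_to + i_kr + i_ks + i_k1 + i_naca + i_nak + i_pca + i_pk + i_bna + i_bca
    )

    # --- gates (Rush-Larsen; x_inf at shifted V, tau at unshifted V) ---
    vm = v - p[IV_M]
    minf = 1.0 / (1.0 + math.exp((-56.86 - vm) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + math.exp((v - 50.0) / 200.0))
    y[6] = minf + (y[6] - minf) * math.exp(-dt * p[IP_M] / (am * bm))

    vh = v - p[IV_H]
    hinf = 1.0 / (1.0 + math.exp((vh + 71.55) / 7.43)) ** 2
    if v < -40.0:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
        tauh = 1.0 / (ah + bh)
    else:
        tauh = 0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)) / 0.77
    y[7] = hinf + (y[7] - hinf) * math.exp(-dt * p[IP_H] / tauh)

    jinf = hinf
    if v < -40.0:
        aj = (
            (-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + math.exp(0.311 * (v + 79.23)))
        )
        bj = 0.02424 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    else:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    tauj = 1.0 / (aj + bj)
    y[8] = jinf + (y[8] - jinf) * math.exp(-dt * p[IP_J] / tauj)

    vd = v - p[IV_D]
    dinf = 1.0 / (1.0 + math.exp((-8.0 - vd) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    y[9] = dinf + (y[9] - dinf) * math.exp(-dt * p[IP_D] / (ad * bd + gd))

    vf = v - p[IV_F]
    finf = 1.0 / (1.0 + math.exp((vf + 20.0) / 7.0))
    tauf = (
        1102.5 * math.exp(-((v + 27.0) ** 2) / 225.0)
        + 200.0 / (1.0 + math.exp((13.0 - v) / 10.0))
        + 180.0 / (1.0 + math.exp((v + 30.0) / 10.0))
        + 20.0
    )
    y[10] = finf + (y[10] - finf) * math.exp(-dt * p[IP_F] / tauf)

    f2inf = 0.67 / (1.0 + math.exp((vf + 35.0) / 7.0)) + 0.33
    tauf2 = (
        562.0 * math.exp(-((v + 27.0) ** 2) / 240.0)
        + 31.0 / (1.0 + math.exp((25.0 - v) / 10.0))
        + 80.0 / (1.0 + math.exp((v + 30.0) / 10.0))
    )
    y[11] = f2inf + (y[11] - f2inf) * math.exp(-dt * p[IP_F2] / tauf2)

    cass = y[5]
    fcinf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    taufc = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0
    y[12] = fcinf + (y[12] - fcinf) * math.exp(-dt / taufc)

    va = v - p[IV_ATO]
    rinf = 1.0 / (1.0 + math.exp((20.0 - va) / 6.0))
    taur = 9.5 * math.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
    y[13] = rinf + (y[13] - rinf) * math.exp(-dt * p[IP_R] / taur)

    vs = v - p[IV_ITO]
    if p[I_ENDO_FLAG] > 0.5:
        sinf = 1.0 / (1.0 + math.exp((vs + 28.0) / 5.0))
        taus = 1000.0 * math.exp(-((v + 67.0) ** 2) / 1000.0) + 8.0
    else:
        sinf = 1.0 / (1.0 + math.exp((vs + 20.0) / 5.0))
        taus = (
            85.0 * math.exp(-((v + 45.0) ** 2) / 320.0)
            + 5.0 / (1.0 + math.exp((v - 20.0) / 5.0))
            + 3.0
        )
    y[14] = sinf + (y[14] - sinf) * math.exp(-dt * p[IP_S] / taus)

    vx1 = v - p[IV_XR1]
    xr1inf = 1.0 / (1.0 + math.exp((-26.0 - vx1) / 7.0))
    ax1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    bx1 = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
    y[15] = xr1inf + (y[15] - xr1inf) * math.exp(-dt * p[IP_XR1] / (ax1 * bx1))

    vx2 = v - p[IV_XR2]
    xr2inf = 1.0 / (1.0 + math.exp((vx2 + 88.0) / 24.0))
    ax2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    bx2 = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
    y[16] = xr2inf + (y[16] - xr2inf) * math.exp(-dt * p[IP_XR2] / (ax2 * bx2))

    vxs = v - p[IV_XS]
    xsinf = 1.0 / (1.0 + math.exp((-5.0 - vxs) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((v - 35.0) / 15.0))
    y[17] = xsinf + (y[17] - xsinf) * math.exp(-dt * p[IP_XS] / (axs * bxs + 80.0))

    # --- calcium subsystem ---
    nai, ki, cai, casr = y[1], y[2], y[3], y[4]
    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / casr) ** 2)
    k1 = K1P / kcasr
    k2 = K2P * kcasr
    rq = y[18]
    drq = K4 * (1.0 - rq) - k2 * cass * rq
    y[18] = rq + dt * drq
    o_rel = k1 * cass * cass * rq / (K3 + k1 * cass * cass)
    i_rel = p[IK_REL] * o_rel * (casr - cass)
    i_leak = p[IK_LEAK] * (casr - cai)
    i_up = p[IK_SERCA] / (1.0 + (K_UP / cai) ** 2)
    i_xfer = p[IK_XFER] * (cass - cai)

    bc = 1.0 / (1.0 + BUF_C * K_BUF_C / (cai + K_BUF_C) ** 2)
    bsr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / (casr + K_BUF_SR) ** 2)
    bss = 1.0 / (1.0 + BUF_SS * K_BUF_SS / (cass + K_BUF_SS) ** 2)

    dcai = bc * (
        (i_leak - i_up) * VSR / VC
        + i_xfer
        - (i_bca + i_pca - 2.0 * i_naca) * CM / (2.0 * VC * FARADAY)
    )
    dcasr = bsr * (i_up - i_rel - i_leak)
    dcass = bss * (
        -i_cal * CM / (2.0 * VSS * FARADAY) + i_rel * VSR / VSS - i_xfer * VC / VSS
    )
    y[3] = cai + dt * dcai
    y[4] = casr + dt * dcasr
    y[5] = cass + dt * dcass

    y[1] = nai - dt * (i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca) * CM / (VC * FARADAY)
    y[2] = ki - dt * (
        i_k1 + i_to + i_kr + i_ks - 2.0 * i_nak + i_pk + istim
    ) * CM / (VC * FARADAY)

    y[0] = v - dt * (i_ion + istim)


def _registry(gto: float, gks: float) -> tuple[ParameterDescriptor, ...]:
    g = [
        ("G_Na", G_NA, "nS/pF", "fast Na+ conductance (I_Na)"),
        ("G_CaL", G_CAL, "cm^3/(uF s)", "L-type Ca2+ permeability (I_CaL)"),
        ("G_to", gto, "nS/pF", "transient outward K+ conductance (I_to)"),
        ("G_Kr", G_KR, "nS/pF", "rapid delayed rectifier conductance (I_Kr)"),
        ("G_Ks", gks, "nS/pF", "slow delayed rectifier conductance (I_Ks)"),
        ("G_K1", G_K1, "nS/pF", "inward rectifier conductance (I_K1)"),
        ("G_pK", G_PK, "nS/pF", "plateau K+ conductance (I_pK)"),
        ("G_pCa", G_PCA, "A/F", "sarcolemmal Ca2+ pump maximum (I_pCa)"),
        ("G_bNa", G_BNA, "nS/pF", "background Na+ conductance (I_bNa)"),
        ("G_bCa", G_BCA, "nS/pF", "background Ca2+ conductance (I_bCa)"),
    ]
    k = [
        ("K_NaK", P_NAK, "A/F", "Na+/K+ pump maximum rate (I_NaK)"),
        ("K_NCX", K_NACA, "A/F", "Na+/Ca2+ exchanger maximum rate (I_NaCa)"),
        ("K_SERCA", VMAX_UP, "mM/ms", "SERCA SR uptake maximum rate"),
        ("K_rel", V_REL, "1/ms", "ryanodine-receptor SR release rate"),
        ("K_leak", V_LEAK, "1/ms", "SR leak rate"),
        ("K_xfer", V_XFER, "1/ms", "subspace-to-cytosol Ca2+ transfer rate"),
    ]
    p = [
        ("p_m", "I_Na activation gate m rate"),
        ("p_h", "I_Na fast inactivation gate h rate"),
        ("p_j", "I_Na slow inactivation gate j rate"),
        ("p_d", "I_CaL activation gate d rate"),
        ("p_f", "I_CaL slow inactivation gate f rate"),
        ("p_f2", "I_CaL fast inactivation gate f2 rate"),
        ("p_xr1", "I_Kr activation gate xr1 rate"),
        ("p_xr2", "I_Kr inactivation gate xr2 rate"),
        ("p_xs", "I_Ks activation gate xs rate"),
        ("p_r", "I_to activation gate r rate"),
        ("p_s", "I_to inactivation gate s rate"),
    ]
    v = [
        ("V_m", "I_Na activation V1/2 (gate m)"),
        ("V_h", "I_Na inactivation V1/2 (gates h and j)"),
        ("V_d", "I_CaL activation V1/2 (gate d)"),
        ("V_f", "I_CaL inactivation V1/2 (gates f and f2)"),
        ("V_xr1", "I_Kr activation V1/2 (gate xr1)"),
        ("V_xr2", "I_Kr inactivation V1/2 (gate xr2)"),
        ("V_xs", "I_Ks activation V1/2 (gate xs)"),
        ("V_a_to", "I_to activation V1/2 (gate r)"),
        ("V_i_to", "I_to inactivation V1/2 (gate s)"),
    ]
    reg = [ParameterDescriptor(n, "G", b, u, t) for n, b, u, t in g]
    reg += [ParameterDescriptor(n, "K", b, u, t) for n, b, u, t in k]
    reg += [ParameterDescriptor(n, "p", 1.0, "dimensionless", t) for n, t in p]
    reg += [ParameterDescriptor(n, "V", 0.0, "mV", t) for n, t in v]
    return tuple(reg)


_STATE_NAMES = (
    "V", "Nai", "Ki", "Cai", "CaSR", "CaSS",
    "m", "h", "j", "d", "f", "f2", "fCass", "r", "s", "xr1", "xr2", "xs", "Rq",
)

_Y0 = np.array(
    [
        -86.2, 7.67, 138.3, 7.0e-5, 1.3, 7.0e-5,
        0.00165, 0.749, 0.6788, 3.288e-5, 0.7026, 0.9526, 0.9942,
        2.347e-8, 0.999998, 0.0165, 0.473, 0.0174, 0.8978,
    ]
)

_CURRENTS = (
    "I_Na", "I_CaL", "I_to", "I_Kr", "I_Ks", "I_K1",
    "I_NaCa", "I_NaK", "I_pCa", "I_pK", "I_bNa", "I_bCa",
)


def _definition(layer: str, gto: float, gks: float, endo_flag: float) -> ModelDefinition:
    return ModelDefinition(
        model_id=f"TP06-{layer}",
        species="human",
        layer=layer,
        citation="ten Tusscher & Panfilov, Am J Physiol 291:H1088-H1100 (2006)",
        state_names=_STATE_NAMES,
        initial_state=_Y0.copy(),
        registry=_registry(gto, gks),
        current_names=_CURRENTS,
        stim_amplitude=-52.0,
        stim_duration=1.0,
        default_sigma_log=0.1,
        dt_fine=0.02,
        dt_coarse=0.25,
        step=_step,
        currents=_currents,
        const_params=(endo_flag,),
    )


EPI = _definition("epi", 0.294, 0.392, 0.0)
MID = _definition("mid", 0.294, 0.098, 0.0)
ENDO = _definition("endo", 0.073, 0.392, 1.0)
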