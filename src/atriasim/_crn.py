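"""Courtemanche–Ramirez–Nattel (CRN, 1998) human atrial action potential model.

Numerics backbone of :mod:`atriasim.cell_dynamics` and
:mod:`atriasim.monodomain_solver`.  The model is implemented once, as a
scalar per-cell update compiled with numba and shared between the
single-cell and tissue paths.  State layout (21 variables per cell)::

    0  V      membrane potential          mV
    1  m      INa activation
    2  h      INa fast inactivation
    3  j      INa slow inactivation
    4  oa     Ito activation
    5  oi     Ito inactivation
    6  ua     IKur activation
    7  ui     IKur inactivation
    8  xr     IKr activation
    9  xs     IKs activation
    10 d      ICaL activation
    11 f      ICaL voltage inactivation
    12 fca    ICaL calcium inactivation
    13 u      RyR release activation
    14 v      RyR release inactivation
    15 w      RyR release voltage gate
    16 Nai    intracellular Na+           mM
    17 Ki     intracellular K+            mM
    18 Cai    intracellular Ca2+          mM
    19 Caup   SR uptake-compartment Ca2+  mM
    20 Carel  SR release-compartment Ca2+ mM

Scaled currents (per-cell multiplier array of length 9, order fixed)::

    0 INa, 1 ICaL, 2 IK1, 3 IKr, 4 IKs, 5 Ito, 6 IKur, 7 INaK, 8 INCX

All membrane currents are expressed in pA/pF (uA/uF); stimulus sign is
depolarising-positive.  Gates advance with Rush–Larsen exponential updates,
voltage and concentrations with forward Euler.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

N_STATE = 21
N_CURRENTS = 9

CURRENT_NAMES = ("INa", "ICaL", "IK1", "IKr", "IKs", "Ito", "IKur", "INaK", "INCX")
CURRENT_INDEX = {name: i for i, name in enumerate(CURRENT_NAMES)}

STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "v", "w", "Nai", "Ki", "Cai", "Caup", "Carel",
)

# Physical constants
R_GAS = 8.3143      # J / (mol K)
TEMP = 310.0        # K
FARADAY = 96.4867   # C / mmol
RTF = R_GAS * TEMP / FARADAY
CM_PF = 100.0       # membrane capacitance, pF

# Extracellular concentrations (mM)
NA_O = 140.0
K_O = 5.4
CA_O = 1.8

# Maximal conductances (nS/pF) / fluxes
G_NA = 7.8
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_CA = 0.001131
G_B_NA = 0.0006744375
I_NAK_MAX = 0.59933874
KM_NAI = 10.0
KM_KO = 1.5
I_NCX_MAX = 1600.0
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
I_PCA_MAX = 0.275

# Calcium handling
K_REL = 30.0
I_UP_MAX = 0.005
K_UP = 0.00092
CA_UP_MAX = 15.0
TAU_TR = 180.0
TAU_FCA = 2.0
TAU_U = 8.0
V_I = 13668.0       # um^3
V_UP = 1109.52
V_REL = 96.48
CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8
KQ10 = 3.0

#: Quasi-steady-state initial conditions at rest (original formulation).
_Y0 = np.array([
    -81.18,      # V
    2.908e-3,    # m
    9.649e-1,    # h
    9.775e-1,    # j
    3.043e-2,    # oa
    9.992e-1,    # oi
    4.966e-3,    # ua
    9.986e-1,    # ui
    3.296e-5,    # xr
    1.869e-2,    # xs
    1.367e-4,    # d
    9.996e-1,    # f
    7.755e-1,    # fca
    0.0,         # u
    1.0,         # v
    9.992e-1,    # w
    1.117e1,     # Nai
    1.39e2,      # Ki
    1.013e-4,    # Cai
    1.488,       # Caup
    1.488,       # Carel
])


def baseline_state() -> np.ndarray:
    """Return a fresh copy of the published resting state vector."""
    return _Y0.copy()


def baseline_states(n: int) -> np.ndarray:
    """(n, N_STATE) array of resting cells; each cell's state is contiguous."""
    return np.repeat(_Y0[None, :], n, axis=0)


@njit(cache=True, fastmath=True)
def _cell_update(y, sc, istim, dt):
    """Advance one cell by dt in place.  y: (21,) view, sc: (9,) view.

    Returns the total ionic current (pA/pF) before the step, for
    diagnostics.  Rush–Larsen for all 15 gates, Euler elsewhere.
    """
    V = y[0]
    m = y[1]; h = y[2]; jj = y[3]
    oa = y[4]; oi = y[5]; ua = y[6]; ui = y[7]
    xr = y[8]; xs = y[9]
    d = y[10]; f = y[11]; fca = y[12]
    u = y[13]; vv = y[14]; w = y[15]
    nai = y[16]; ki = y[17]; cai = y[18]; caup = y[19]; carel = y[20]

    ena = RTF * math.log(NA_O / nai)
    ek = RTF * math.log(K_O / ki)
    eca = 0.5 * RTF * math.log(CA_O / cai)

    # --- membrane currents (pA/pF) ---
    i_na = sc[0] * G_NA * m * m * m * h * jj * (V - ena)
    i_k1 = sc[2] * G_K1 * (V - ek) / (1.0 + math.exp(0.07 * (V + 80.0)))
    i_to = sc[5] * G_TO * oa * oa * oa * oi * (V - ek)
    g_kur = 0.005 + 0.05 / (1.0 + math.exp(-(V - 15.0) / 13.0))
    i_kur = sc[6] * g_kur * ua * ua * ua * ui * (V - ek)
    i_kr = sc[3] * G_KR * xr * (V - ek) / (1.0 + math.exp((V + 15.0) / 22.4))
    i_ks = sc[4] * G_KS * xs * xs * (V - ek)
    i_cal = sc[1] * G_CAL * d * f * fca * (V - 65.0)

    sig = (math.exp(NA_O / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * V / RTF)
                   + 0.0365 * sig * math.exp(-V / RTF))
    i_nak = sc[7] * I_NAK_MAX * f_nak * K_O / (K_O + KM_KO) \
        / (1.0 + (KM_NAI / nai) ** 1.5)

    ev = math.exp(GAMMA * V / RTF)
    ev1 = math.exp((GAMMA - 1.0) * V / RTF)
    i_ncx = sc[8] * I_NCX_MAX * (ev * nai ** 3 * CA_O - ev1 * NA_O ** 3 * cai) \
        / ((KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O) * (1.0 + K_SAT * ev1))

    i_bna = G_B_NA * (V - ena)
    i_bca = G_B_CA * (V - eca)
    i_pca = I_PCA_MAX * cai / (0.0005 + cai)

    i_ion = (i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal
             + i_nak + i_ncx + i_bna + i_bca + i_pca)

    # --- SR calcium fluxes (mM/ms) ---
    i_rel = K_REL * u * u * vv * w * (carel - cai)
    i_up = I_UP_MAX / (1.0 + K_UP / cai)
    i_up_leak = I_UP_MAX * caup / CA_UP_MAX
    i_tr = (caup - carel) / TAU_TR

    # --- gate rates ---
    dv = V + 47.13
    if abs(dv) < 1e-6:
        a_m = 3.2
    else:
        a_m = 0.32 * dv / (1.0 - math.exp(-0.1 * dv))
    b_m = 0.08 * math.exp(-V / 11.0)
    m_inf = a_m / (a_m + b_m)
    tau_m = 1.0 / (a_m + b_m)

    if V >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        a_j = 0.0
        b_j = 0.3 * math.exp(-2.535e-7 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        a_h = 0.135 * math.exp(-(V + 80.0) / 6.8)
        b_h = 3.56 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.35 * V)
        a_j = (-1.2714e5 * math.exp(0.2444 * V) - 3.474e-5 * math.exp(-0.04391 * V)) \
            * (V + 37.78) / (1.0 + math.exp(0.311 * (V + 79.23)))
        b_j = 0.1212 * math.exp(-0.01052 * V) / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    h_inf = a_h / (a_h + b_h)
    tau_h = 1.0 / (a_h + b_h)
    j_inf = a_j / (a_j + b_j)
    tau_j = 1.0 / (a_j + b_j)

    a_oa = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    tau_oa = 1.0 / ((a_oa + b_oa) * KQ10)
    oa_inf = 1.0 / (1.0 + math.exp(-(V + 20.47) / 17.54))

    a_oi = 1.0 / (18.53 + math.exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + math.exp(-(V + 1.26) / 7.44))
    tau_oi = 1.0 / ((a_oi + b_oi) * KQ10)
    oi_inf = 1.0 / (1.0 + math.exp((V + 43.1) / 5.3))

    a_ua = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    tau_ua = 1.0 / ((a_ua + b_ua) * KQ10)
    ua_inf = 1.0 / (1.0 + math.exp(-(V + 30.3) / 9.6))

    a_ui = 1.0 / (21.0 + math.exp(-(V - 185.0) / 28.0))
    b_ui = math.exp((V - 158.0) / 16.0)
    tau_ui = 1.0 / ((a_ui + b_ui) * KQ10)
    ui_inf = 1.0 / (1.0 + math.exp((V - 99.45) / 27.48))

    dv = V + 14.1
    if abs(dv) < 1e-6:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * dv / (1.0 - math.exp(-dv / 5.0))
    dv = V - 3.3328
    if abs(dv) < 1e-6:
        b_xr = 3.7836118e-4
    else:
        b_xr = 7.3898e-5 * dv / (math.exp(dv / 5.1237) - 1.0)
    tau_xr = 1.0 / (a_xr + b_xr)
    xr_inf = 1.0 / (1.0 + math.exp(-(V + 14.1) / 6.5))

    dv = V - 19.9
    if abs(dv) < 1e-6:
        a_xs = 6.8e-4
        b_xs = 3.15e-4
    else:
        a_xs = 4e-5 * dv / (1.0 - math.exp(-dv / 17.0))
        b_xs = 3.5e-5 * dv / (math.exp(dv / 9.0) - 1.0)
    tau_xs = 0.5 / (a_xs + b_xs)
    xs_inf = 1.0 / math.sqrt(1.0 + math.exp(-(V - 19.9) / 12.7))

    dv = V + 10.0
    e1 = math.exp(-dv / 6.24)
    if abs(dv) < 1e-6:
        tau_d = 1.0 / (0.035 * 6.24 * 2.0)
    else:
        tau_d = (1.0 - e1) / (0.035 * dv * (1.0 + e1))
    d_inf = 1.0 / (1.0 + math.exp(-dv / 8.0))

    tau_f = 9.0 / (0.0197 * math.exp(-(0.0337 * dv) ** 2) + 0.02)
    f_inf = 1.0 / (1.0 + math.exp((V + 28.0) / 6.9))

    fca_inf = 1.0 / (1.0 + cai / 0.00035)

    fn = 1e3 * (1e-15 * V_REL * i_rel
                - 1e-15 / (2.0 * FARADAY) * (0.5 * i_cal - 0.2 * i_ncx) * CM_PF)
    u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))

    dv = V - 7.9
    e1 = math.exp(-dv / 5.0)
    if abs(dv) < 1e-6:
        tau_w = 6.0 / (5.0 * 1.3)
    else:
        tau_w = 6.0 * (1.0 - e1) / ((1.0 + 0.3 * e1) * dv)
    w_inf = 1.0 - 1.0 / (1.0 + math.exp(-(V - 40.0) / 17.0))

    # --- Rush–Larsen gate updates ---
    y[1] = m_inf + (m - m_inf) * math.exp(-dt / tau_m)
    y[2] = h_inf + (h - h_inf) * math.exp(-dt / tau_h)
    y[3] = j_inf + (jj - j_inf) * math.exp(-dt / tau_j)
    y[4] = oa_inf + (oa - oa_inf) * math.exp(-dt / tau_oa)
    y[5] = oi_inf + (oi - oi_inf) * math.exp(-dt / tau_oi)
    y[6] = ua_inf + (ua - ua_inf) * math.exp(-dt / tau_ua)
    y[7] = ui_inf + (ui - ui_inf) * math.exp(-dt / tau_ui)
    y[8] = xr_inf + (xr - xr_inf) * math.exp(-dt / tau_xr)
    y[9] = xs_inf + (xs - xs_inf) * math.exp(-dt / tau_xs)
    y[10] = d_inf + (d - d_inf) * math.exp(-dt / tau_d)
    y[11] = f_inf + (f - f_inf) * math.exp(-dt / tau_f)
    y[12] = fca_inf + (fca - fca_inf) * math.exp(-dt / TAU_FCA)
    y[13] = u_inf + (u - u_inf) * math.exp(-dt / TAU_U)
    y[14] = v_inf + (vv - v_inf) * math.exp(-dt / tau_v)
    y[15] = w_inf + (w - w_inf) * math.exp(-dt / tau_w)

    # --- concentrations (Euler) ---
    conc = CM_PF / (FARADAY * V_I)
    y[16] = nai + dt * (conc * (-3.0 * i_nak - 3.0 * i_ncx - i_bna - i_na))
    y[17] = ki + dt * (conc * (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks))
    b1 = 0.5 * conc * (2.0 * i_ncx - i_pca - i_cal - i_bca) \
        + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I
    b2 = 1.0 + TRPN_MAX * KM_TRPN / (cai + KM_TRPN) ** 2 \
        + CMDN_MAX * KM_CMDN / (cai + KM_CMDN) ** 2
    y[18] = cai + dt * b1 / b2
    y[19] = caup + dt * (i_up - i_up_leak - i_tr * V_REL / V_UP)
    y[20] = carel + dt * (i_tr - i_rel) \
        / (1.0 + CSQN_MAX * KM_CSQN / (carel + KM_CSQN) ** 2)

    # --- membrane potential (Euler) ---
    y[0] = V + dt * (-(i_ion) + istim)
    return i_ion


@njit(cache=True, fastmath=True)
def step_states(Y, scales, istim, dt, n_sub):
    """Advance all cells n_sub reaction substeps of dt, in place.

    Y: (N, 21); scales: (N, 9); istim: (N,) in pA/pF.
    """
    n = Y.shape[0]
    for _ in range(n_sub):
        for c in range(n):
            _cell_update(Y[c], scales[c], istim[c], dt)


@njit(cache=True, fastmath=True)
def step_states_clamped(Y, scales, v_clamp, dt, n_sub):
    """Advance gates/concentrations with V held at v_clamp (voltage clamp)."""
    n = Y.shape[0]
    for _ in range(n_sub):
        for c in range(n):
            Y[c, 0] = v_clamp
            _cell_update(Y[c], scales[c], 0.0, dt)
            Y[c, 0] = v_clamp


def compute_currents(y: np.ndarray, scales: np.ndarray) -> dict:
    """Named instantaneous membrane currents (pA/pF) for one cell.

    Kept as plain numpy so it can be inspected/differentiated; used by the
    voltage-clamp protocols and tests.
    """
    V, m, h, jj = y[0], y[1], y[2], y[3]
    oa, oi, ua, ui = y[4], y[5], y[6], y[7]
    xr, xs = y[8], y[9]
    d, f, fca = y[10], y[11], y[12]
    nai, ki, cai = y[16], y[17], y[18]

    ena = RTF * np.log(NA_O / nai)
    ek = RTF * np.log(K_O / ki)
    eca = 0.5 * RTF * np.log(CA_O / cai)
    g_kur = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
    sig = (np.exp(NA_O / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V / RTF)
                   + 0.0365 * sig * np.exp(-V / RTF))
    ev = np.exp(GAMMA * V / RTF)
    ev1 = np.exp((GAMMA - 1.0) * V / RTF)
    return {
        "INa": scales[0] * G_NA * m ** 3 * h * jj * (V - ena),
        "ICaL": scales[1] * G_CAL * d * f * fca * (V - 65.0),
        "IK1": scales[2] * G_K1 * (V - ek) / (1.0 + np.exp(0.07 * (V + 80.0))),
        "IKr": scales[3] * G_KR * xr * (V - ek) / (1.0 + np.exp((V + 15.0) / 22.4)),
        "IKs": scales[4] * G_KS * xs ** 2 * (V - ek),
        "Ito": scales[5] * G_TO * oa ** 3 * oi * (V - ek),
        "IKur": scales[6] * g_kur * ua ** 3 * ui * (V - ek),
        "INaK": scales[7] * I_NAK_MAX * f_nak * K_O / (K_O + KM_KO)
                / (1.0 + (KM_NAI / nai) ** 1.5),
        "INCX": scales[8] * I_NCX_MAX
                * (ev * nai ** 3 * CA_O - ev1 * NA_O ** 3 * cai)
                / ((KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O)
                   * (1.0 + K_SAT * ev1)),
        "IbNa": G_B_NA * (V - ena),
        "IbCa": G_B_CA * (V - eca),
        "IpCa": I_PCA_MAX * cai / (0.0005 + cai),
    }


def rhs(t: float, y: np.ndarray, scales: np.ndarray, istim: float = 0.0) -> np.ndarray:
    """Full ODE right-hand side for one cell (for generic ODE integrators).

    Derivative form of the same model: gates as (x_inf - x)/tau.  Used as an
    independent integration route (e.g. scipy.solve_ivp) to cross-check the
    fixed-step Rush–Larsen path.
    """
    work = y.copy()
    dt = 1e-7  # tiny step; recover derivatives by finite update of the RL map
    _cell_update(work, np.asarray(scales, dtype=np.float64), istim, dt)
    return (work - y) / dt
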