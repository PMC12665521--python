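"""Courtemanche-Ramirez-Nattel (1998) human atrial ionic model.

The model has 21 state variables: membrane voltage, 15 Hodgkin-Huxley-type
gates, the three intracellular ion concentrations and the two SR calcium
compartments.  Two remodeled variants are provided:

* ``AF_REMODELED`` -- chronic-AF electrical remodeling: G_Kur and G_to halved,
  G_CaL reduced by 70%.
* ``FIBROTIC`` -- a further adapted variant standing in for fibrotic tissue:
  G_Kur and G_to halved, G_CaL halved, G_Na reduced by 30%.

Integration uses Rush-Larsen updates for the voltage-dependent gates and
forward Euler for voltage and concentrations.  All voltage-dependent rate
functions are pre-tabulated on a fine Vm grid and linearly interpolated,
which keeps tissue-scale runs tractable on one core.

Units: ms, mV, pA/pF, mM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

# Physical constants
R_GAS = 8.3143        # J / (K mol)
TEMP = 310.0          # K
FARADAY = 96.4867     # C / mmol
RTF = R_GAS * TEMP / FARADAY

CM = 100.0            # pF
V_I = 13668.0         # um^3, intracellular volume
V_UP = 1109.52        # um^3, SR uptake compartment
V_REL = 96.48         # um^3, SR release compartment

NA_O = 140.0          # mM
K_O = 5.4
CA_O = 1.8

G_NA = 7.8            # nS/pF
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_CA = 0.001131
G_B_NA = 0.0006744375

I_NAK_MAX = 0.59933874
I_NACA_MAX = 1600.0
I_PCA_MAX = 0.275
I_UP_MAX = 0.005

K_Q10 = 3.0
GAMMA = 0.35
KM_NAI = 10.0
KM_KO = 1.5
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
K_REL = 30.0
K_UP = 0.00092
CA_UP_MAX = 15.0
TAU_TR = 180.0
TAU_U = 8.0
TAU_F_CA = 2.0

CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

N_STATES = 21
# state vector layout
IV, IM, IH, IJ, IOA, IOI, IUA, IUI, IXR, IXS, ID, IF, IFCA, IU, IVG, IW, \
    INAI, IKI, ICAI, ICAUP, ICAREL = range(N_STATES)


@dataclass(frozen=True)
class RemodelingParams:
    """Dimensionless multipliers on baseline channel conductances."""

    g_kur: float = 1.0
    g_to: float = 1.0
    g_cal: float = 1.0
    g_na: float = 1.0


AF_REMODELED = RemodelingParams(g_kur=0.5, g_to=0.5, g_cal=0.3, g_na=1.0)
FIBROTIC = RemodelingParams(g_kur=0.5, g_to=0.5, g_cal=0.5, g_na=0.7)
VARIANTS = {"baseline": RemodelingParams(), "af": AF_REMODELED,
            "fibrotic": FIBROTIC}


def initial_state() -> np.ndarray:
    """Resting state of the baseline model (quiescent fixed point vicinity)."""
    y = np.empty(N_STATES)
    y[IV] = -81.18
    y[IM] = 2.908e-3
    y[IH] = 9.649e-1
    y[IJ] = 9.775e-1
    y[IOA] = 3.043e-2
    y[IOI] = 9.992e-1
    y[IUA] = 4.966e-3
    y[IUI] = 9.986e-1
    y[IXR] = 3.296e-5
    y[IXS] = 1.869e-2
    y[ID] = 1.367e-4
    y[IF] = 9.996e-1
    y[IFCA] = 7.755e-1
    y[IU] = 0.0
    y[IVG] = 1.0
    y[IW] = 9.992e-1
    y[INAI] = 11.17
    y[IKI] = 139.0
    y[ICAI] = 1.013e-4
    y[ICAUP] = 1.488
    y[ICAREL] = 1.488
    return y


def _safe_ratio(num, den, limit):
    """num/den with the removable-singularity limit patched in."""
    out = np.where(np.abs(den) < 1e-9, limit, num / np.where(den == 0.0, 1.0, den))
    return out


# table column layout: 12 gates x (inf, rl-factor) then current helpers
COL_GKUR = 24
COL_K1R = 25
COL_KRR = 26
COL_FNAK = 27
COL_E1 = 28
COL_E2 = 29
N_COLS = 30

V_MIN = -120.0
V_MAX = 80.0
DV_TAB = 0.05


def build_tables(dt: float) -> np.ndarray:
    """Tabulate gate steady states, Rush-Larsen factors exp(-dt/tau) and the
    voltage-dependent current factors on a uniform Vm grid."""
    v = np.arange(V_MIN, V_MAX + DV_TAB, DV_TAB)
    tab = np.empty((v.size, N_COLS))

    def put(slot, inf, tau):
        tab[:, 2 * slot] = inf
        tab[:, 2 * slot + 1] = np.exp(-dt / tau)

    # m
    a = _safe_ratio(0.32 * (v + 47.13), 1.0 - np.exp(-0.1 * (v + 47.13)), 3.2)
    b = 0.08 * np.exp(-v / 11.0)
    put(0, a / (a + b), 1.0 / (a + b))
    # h
    lo = v < -40.0
    a = np.where(lo, 0.135 * np.exp(-(v + 80.0) / 6.8), 0.0)
    b = np.where(lo, 3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v),
                 1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))))
    put(1, a / (a + b), 1.0 / (a + b))
    # j
    a = np.where(
        lo,
        (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
        * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))),
        0.0,
    )
    b = np.where(
        lo,
        0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))),
        0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))),
    )
    put(2, a / (a + b), 1.0 / (a + b))
    # oa / oi (transient outward)
    a = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    put(3, 1.0 / (1.0 + np.exp(-(v + 20.47) / 17.54)), 1.0 / ((a + b) * K_Q10))
    a = 1.0 / (18.53 + np.exp((v + 113.7) / 10.95))
    b = 1.0 / (35.56 + np.exp(-(v + 1.26) / 7.44))
    put(4, 1.0 / (1.0 + np.exp((v + 43.1) / 5.3)), 1.0 / ((a + b) * K_Q10))
    # ua / ui (ultra-rapid)
    a = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    put(5, 1.0 / (1.0 + np.exp(-(v + 30.3) / 9.6)), 1.0 / ((a + b) * K_Q10))
    a = 1.0 / (21.0 + np.exp(-(v - 185.0) / 28.0))
    b = np.exp((v - 158.0) / 16.0)
    put(6, 1.0 / (1.0 + np.exp((v - 99.45) / 27.48)), 1.0 / ((a + b) * K_Q10))
    # xr
    a = _safe_ratio(0.0003 * (v + 14.1), 1.0 - np.exp(-(v + 14.1) / 5.0), 0.0015)
    b = _safe_ratio(7.3898e-5 * (v - 3.3328),
                    np.exp((v - 3.3328) / 5.1237) - 1.0, 7.3898e-5 * 5.1237)
    put(7, 1.0 / (1.0 + np.exp(-(v + 14.1) / 6.5)), 1.0 / (a + b))
    # xs
    a = _safe_ratio(4e-5 * (v - 19.9), 1.0 - np.exp(-(v - 19.9) / 17.0), 6.8e-4)
    b = _safe_ratio(3.5e-5 * (v - 19.9), np.exp((v - 19.9) / 9.0) - 1.0, 3.15e-4)
    put(8, 1.0 / np.sqrt(1.0 + np.exp(-(v - 19.9) / 12.7)), 0.5 / (a + b))
    # d
    ex = np.exp(-(v + 10.0) / 6.24)
    tau_d = _safe_ratio(1.0 - ex, 0.035 * (v + 10.0) * (1.0 + ex),
                        1.0 / (0.035 * 6.24 * 2.0))
    put(9, 1.0 / (1.0 + np.exp(-(v + 10.0) / 8.0)), tau_d)
    # f
    tau_f = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (v + 10.0) ** 2) + 0.02)
    put(10, 1.0 / (1.0 + np.exp((v + 28.0) / 6.9)), tau_f)
    # w
    ew = np.exp(-(v - 7.9) / 5.0)
    tau_w = _safe_ratio(6.0 * (1.0 - ew), (1.0 + 0.3 * ew) * (v - 7.9),
                        6.0 / (5.0 * 1.3))
    put(11, 1.0 - 1.0 / (1.0 + np.exp(-(v - 40.0) / 17.0)), tau_w)

    tab[:, COL_GKUR] = 0.005 + 0.05 / (1.0 + np.exp(-(v - 15.0) / 13.0))
    tab[:, COL_K1R] = 1.0 / (1.0 + np.exp(0.07 * (v + 80.0)))
    tab[:, COL_KRR] = 1.0 / (1.0 + np.exp((v + 15.0) / 22.4))
    sigma = (np.exp(NA_O / 67.3) - 1.0) / 7.0
    fvrt = v / RTF
    tab[:, COL_FNAK] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * fvrt)
                              + 0.0365 * sigma * np.exp(-fvrt))
    tab[:, COL_E1] = np.exp(GAMMA * fvrt)
    tab[:, COL_E2] = np.exp((GAMMA - 1.0) * fvrt)
    if not np.all(np.isfinite(tab)):
        raise FloatingPointError("non-finite entry in rate tables")
    return tab


@njit(cache=True, fastmath=True)
def advance(S, nb, coupling, gna, gto, gkur, gcal, istim, dt, nsteps, tab,
            exp_fca, exp_u):  # pragma: no cover - jitted
    """Advance all nodes by ``nsteps`` explicit steps of size ``dt``.

    S        : (21, n) state array, updated in place
    nb       : (4, n) int32 neighbor indices (self index = missing neighbor)
    coupling : (4, n) D/dx^2 per link (ms^-1); 0 for decoupled links
    gna..gcal: (n,) conductance scale factors
    istim    : (n,) stimulus current (pA/pF), constant over the call
    """
    n = S.shape[1]
    inv_dv = 1.0 / DV_TAB
    inaca_den0 = (KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O)
    for _ in range(nsteps):
        v0 = S[IV].copy()
        for p in range(n):
            v = v0[p]
            # table lookup with linear interpolation
            x = (v - V_MIN) * inv_dv
            if x < 0.0:
                x = 0.0
            elif x > tab.shape[0] - 2:
                x = float(tab.shape[0] - 2)
            i0 = int(x)
            w1 = x - i0
            w0 = 1.0 - w1

            nai = S[INAI, p]
            ki = S[IKI, p]
            cai = S[ICAI, p]

            e_na = RTF * np.log(NA_O / nai)
            e_k = RTF * np.log(K_O / ki)
            e_ca = 0.5 * RTF * np.log(CA_O / cai)

            def lk(c):
                return w0 * tab[i0, c] + w1 * tab[i0 + 1, c]

            i_na = gna[p] * G_NA * S[IM, p] ** 3 * S[IH, p] * S[IJ, p] * (v - e_na)
            i_k1 = G_K1 * (v - e_k) * lk(COL_K1R)
            i_to = gto[p] * G_TO * S[IOA, p] ** 3 * S[IOI, p] * (v - e_k)
            i_kur = gkur[p] * lk(COL_GKUR) * S[IUA, p] ** 3 * S[IUI, p] * (v - e_k)
            i_kr = G_KR * S[IXR, p] * (v - e_k) * lk(COL_KRR)
            i_ks = G_KS * S[IXS, p] ** 2 * (v - e_k)
            i_cal = gcal[p] * G_CAL * S[ID, p] * S[IF, p] * S[IFCA, p] * (v - 65.0)
            i_nak = I_NAK_MAX * lk(COL_FNAK) * (K_O / (K_O + KM_KO)) \
                / (1.0 + (KM_NAI / nai) ** 1.5)
            e2 = lk(COL_E2)
            i_naca = I_NACA_MAX * (lk(COL_E1) * nai ** 3 * CA_O
                                   - e2 * NA_O ** 3 * cai) \
                / (inaca_den0 * (1.0 + K_SAT * e2))
            i_bna = G_B_NA * (v - e_na)
            i_bca = G_B_CA * (v - e_ca)
            i_pca = I_PCA_MAX * cai / (0.0005 + cai)

            # SR calcium fluxes
            i_rel = K_REL * S[IU, p] ** 2 * S[IVG, p] * S[IW, p] * (S[ICAREL, p] - cai)
            i_tr = (S[ICAUP, p] - S[ICAREL, p]) / TAU_TR
            i_up = I_UP_MAX / (1.0 + K_UP / cai)
            i_upleak = I_UP_MAX * S[ICAUP, p] / CA_UP_MAX

            fn = 1e3 * (1e-15 * V_REL * i_rel
                        - 1e-15 / (2.0 * FARADAY) * (0.5 * i_cal - 0.2 * i_naca) * CM)
            u_inf = 1.0 / (1.0 + np.exp(-(fn - 3.4175e-13) / 13.67e-16))
            tau_v = 1.91 + 2.09 * u_inf
            v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(fn - 6.835e-14) / 13.67e-16))

            # Rush-Larsen gate updates (slots match build_tables order)
            S[IM, p] = lk(0) + (S[IM, p] - lk(0)) * lk(1)
            S[IH, p] = lk(2) + (S[IH, p] - lk(2)) * lk(3)
            S[IJ, p] = lk(4) + (S[IJ, p] - lk(4)) * lk(5)
            S[IOA, p] = lk(6) + (S[IOA, p] - lk(6)) * lk(7)
            S[IOI, p] = lk(8) + (S[IOI, p] - lk(8)) * lk(9)
            S[IUA, p] = lk(10) + (S[IUA, p] - lk(10)) * lk(11)
            S[IUI, p] = lk(12) + (S[IUI, p] - lk(12)) * lk(13)
            S[IXR, p] = lk(14) + (S[IXR, p] - lk(14)) * lk(15)
            S[IXS, p] = lk(16) + (S[IXS, p] - lk(16)) * lk(17)
            S[ID, p] = lk(18) + (S[ID, p] - lk(18)) * lk(19)
            S[IF, p] = lk(20) + (S[IF, p] - lk(20)) * lk(21)
            S[IW, p] = lk(22) + (S[IW, p] - lk(22)) * lk(23)

            fca_inf = 1.0 / (1.0 + cai / 0.00035)
            S[IFCA, p] = fca_inf + (S[IFCA, p] - fca_inf) * exp_fca
            S[IU, p] = u_inf + (S[IU, p] - u_inf) * exp_u
            S[IVG, p] = v_inf + (S[IVG, p] - v_inf) * np.exp(-dt / tau_v)

            # concentrations (forward Euler)
            S[INAI, p] += dt * (-3.0 * i_nak - 3.0 * i_naca - i_bna - i_na) \
                * CM / (FARADAY * V_I)
            S[IKI, p] += dt * (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks) \
                * CM / (FARADAY * V_I)
            b1 = (2.0 * i_naca - i_pca - i_cal - i_bca) * CM / (2.0 * FARADAY * V_I) \
                + (V_UP * (i_upleak - i_up) + i_rel * V_REL) / V_I
            b2 = 1.0 + TRPN_MAX * KM_TRPN / (cai + KM_TRPN) ** 2 \
                + CMDN_MAX * KM_CMDN / (cai + KM_CMDN) ** 2
            S[ICAI, p] = cai + dt * b1 / b2
            S[ICAUP, p] += dt * (i_up - i_upleak - i_tr * V_REL / V_UP)
            S[ICAREL, p] += dt * (i_tr - i_rel) \
                / (1.0 + CSQN_MAX * KM_CSQN / (S[ICAREL, p] + KM_CSQN) ** 2)

            i_ion = i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal + i_pca \
                + i_nak + i_naca + i_bna + i_bca
            diff = coupling[0, p] * (v0[nb[0, p]] - v) \
                + coupling[1, p] * (v0[nb[1, p]] - v) \
                + coupling[2, p] * (v0[nb[2, p]] - v) \
                + coupling[3, p] * (v0[nb[3, p]] - v)
            S[IV, p] = v + dt * (diff - i_ion - istim[p])
    return S


class CellSolver:
    """Single-cell / multi-node integrator wrapper around the jitted kernel."""

    def __init__(self, n: int = 1, dt: float = 0.02):
        self.n = n
        self.dt = dt
        self.tab = build_tables(dt)
        self.exp_fca = float(np.exp(-dt / TAU_F_CA))
        self.exp_u = float(np.exp(-dt / TAU_U))

    def scales(self, params: RemodelingParams):
        n = self.n
        return (np.full(n, params.g_na), np.full(n, params.g_to),
                np.full(n, params.g_kur * 1.0), np.full(n, params.g_cal))

    def run(self, S, nb, coupling, params: RemodelingParams, istim, nsteps):
        gna, gto, gkur, gcal = self.scales(params)
        return advance(S, nb, coupling, gna, gto, gkur, gcal, istim,
                       self.dt, nsteps, self.tab, self.exp_fca, self.exp_u)


def _lone_node_topology(n: int):
    nb = np.tile(np.arange(n, dtype=np.int64), (4, 1))
    coupling = np.zeros((4, n))
    return nb, coupling


def pace_cell(params: RemodelingParams, bcl: float = 500.0, beats: int = 20,
              dt: float = 0.02, stim_amp: float = -20.0, stim_dur: float = 2.0,
              record_last: int = 2, record_step: float = 0.1):
    """Pace a single cell to quasi-steady state and return the trace of the
    final beats.

    Returns (times ms, vm mV) sampled every ``record_step`` ms over the last
    ``record_last`` beats, with t=0 at the first recorded stimulus onset.
    """
    solver = CellSolver(1, dt)
    S = initial_state()[:, None].copy()
    nb, coupling = _lone_node_topology(1)
    stim = np.array([stim_amp])
    none = np.zeros(1)
    n_stim = int(round(stim_dur / dt))
    n_rest = int(round(bcl / dt)) - n_stim

    for _ in range(beats - record_last):
        solver.run(S, nb, coupling, params, stim, n_stim)
        solver.run(S, nb, coupling, params, none, n_rest)

    rec_every = int(round(record_step / dt))
    steps_per_beat = n_stim + n_rest
    n_total = record_last * steps_per_beat
    vm = np.empty(n_total // rec_every)
    times = np.arange(vm.size) * record_step
    for k in range(vm.size):
        vm[k] = S[IV, 0]
        pos = (k * rec_every) % steps_per_beat
        cur = stim if pos < n_stim else none
        solver.run(S, nb, coupling, params, cur, rec_every)
    return times, vm


def apd90(times: np.ndarray, vm: np.ndarray, bcl: float) -> float:
    """APD90 of the final beat of a paced trace.

    Measured from the maximum-upstroke-velocity time of the last action
    potential to 90% repolarization toward the pre-stimulus diastolic Vm.
    """
    dt = times[1] - times[0]
    last_onset = times[-1] - bcl
    i0 = int(np.searchsorted(times, last_onset))
    v_dia = vm[max(i0 - 1, 0)]
    seg = vm[i0:]
    dvdt = np.diff(seg) / dt
    i_act = int(np.argmax(dvdt))
    v_peak = float(np.max(seg))
    v90 = v_dia + 0.1 * (v_peak - v_dia)
    below = np.nonzero(seg[i_act:] < v90)[0]
    # skip any sub-threshold samples right at the upstroke foot
    below = below[below > 5]
    if below.size == 0:
        raise RuntimeError("no 90% repolarization found within the last beat")
    i_rep = i_act + below[0]
    # linear interpolation of the crossing
    v_a, v_b = seg[i_rep - 1], seg[i_rep]
    frac = (v_a - v90) / (v_a - v_b) if v_a != v_b else 0.0
    return (i_rep - 1 + frac - i_act) * dt


def measure_apd90(params: RemodelingParams, bcl: float = 500.0,
                  beats: int = 20, dt: float = 0.02) -> float:
    """Convenience: pace to quasi-steady state and return the final-beat APD90."""
    times, vm = pace_cell(params, bcl=bcl, beats=beats, dt=dt)
    return apd90(times, vm, bcl)
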