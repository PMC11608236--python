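"""JIT-compiled right-hand side of the 61-state swine myocyte model.

Membrane-current formulations follow the ORd human ventricular model
(Hodgkin-Huxley INa/INaL/IKr/IKs/IK1, Kang-Hilgemann NCX, Smith-Crampin
Na/K pump, GHK background fluxes) with swine-refit parameters; the
transient outward current is the Ca2+-activated chloride current Ito2
(Hund-Rudy lineage) since swine lack I_to1; the L-type channel is the
two-loop Markov scheme in :mod:`swinecell.ltcc`.  Ca2+ cycling uses a
single junctional release compartment with CaMKII-regulated release and
SERCA uptake.

All expressions operate on plain float64 scalars so numba can compile the
function once per session.  Removable singularities of the GHK terms are
guarded by clamping |V| away from zero (the error is far below solver
tolerance).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import constants as c
from .ltcc import _block_derivs, _ltcc_rates_arr

_R = c.RGAS
_F = c.FARADAY
_T = c.TEMP


@njit(cache=True)
def rhs_full(t, y, p, wave_dt, wave_v, wave_dv):
    """Return (dy, currents) at time t (ms)."""
    dy = np.zeros(c.N_STATES)
    cur = np.zeros(c.N_CURRENTS)

    mode = p[c.P_MODE]

    v = y[c.S_V]
    nai = y[c.S_NAI]
    nass = y[c.S_NASS]
    ki = y[c.S_KI]
    kss = y[c.S_KSS]
    cai = y[c.S_CAI]
    cass = y[c.S_CASS]
    cansr = y[c.S_CANSR]
    cajsr = y[c.S_CAJSR]
    cli = y[c.S_CLI]

    nao = p[c.P_NAO]
    cao = p[c.P_CAO]
    ko = p[c.P_KO]
    clo = p[c.P_CLO]

    # geometry
    L = p[c.P_CELL_LEN]
    rad = p[c.P_CELL_RAD]
    vcell = 1000.0 * math.pi * rad * rad * L
    ageo = 2.0 * math.pi * rad * rad + 2.0 * math.pi * rad * L
    acap = 2.0 * ageo
    vmyo = 0.68 * vcell
    vnsr = 0.0552 * vcell
    vjsr = 0.0048 * vcell
    vss = 0.02 * vcell

    # AP clamp: V follows the imposed periodic waveform exactly
    if mode == 2.0:
        nwave = wave_v.shape[0]
        period_w = wave_dt * (nwave - 1)
        tt = t % period_w
        k = int(tt / wave_dt)
        if k >= nwave - 1:
            k = nwave - 2
        frac = (tt - k * wave_dt) / wave_dt
        v = wave_v[k] * (1.0 - frac) + wave_v[k + 1] * frac

    vfrt = v * _F / (_R * _T)
    if abs(vfrt) < 1e-7:
        vfrt = 1e-7 if vfrt >= 0 else -1e-7
    vg = vfrt * _R * _T / _F          # singularity-guarded voltage
    vffrt = vg * _F * _F / (_R * _T)

    ena = (_R * _T / _F) * math.log(nao / nai)
    ek = (_R * _T / _F) * math.log(ko / ki)
    eks = (_R * _T / _F) * math.log((ko + 0.01833 * nao)
                                    / (ki + 0.01833 * nai))
    ecl = -(_R * _T / _F) * math.log(clo / cli)

    # ---------------- CaMKII ----------------
    km_cam = p[c.P_KM_CAM] * p[c.P_CAMK_KM_MULT]
    camkb = p[c.P_CAMK_O] * (1.0 - y[c.S_CAMKT]) / (1.0 + km_cam / cass)
    camka = camkb + y[c.S_CAMKT]
    dy[c.S_CAMKT] = (p[c.P_A_CAMK] * camkb * (camkb + y[c.S_CAMKT])
                     - p[c.P_B_CAMK] * y[c.S_CAMKT])
    km_camk = p[c.P_KM_CAMK]
    fp = camka / (camka + km_camk)     # CaMKII-phosphorylated fraction
    # coupling of chronic CaMKII activity (trapped fraction, a slow
    # integral of activation) to the Na+ conductances; using the slow
    # variable avoids spurious beat-to-beat feedback
    ckm = p[c.P_CAMK_COUP_KM]
    ctrap = y[c.S_CAMKT]
    hcoup = ctrap ** 2 / (ctrap ** 2 + ckm ** 2)

    # ---------------- fast Na+ current ----------------
    tsa = p[c.P_TSHIFT_ACT]
    tsi = p[c.P_TSHIFT_INACT]
    q10 = p[c.P_Q10_TAU_SCALE]
    mss = 1.0 / (1.0 + math.exp(-(v + 39.57 - tsa) / 9.871))
    tm = q10 / (6.765 * math.exp((v + 11.64) / 34.77)
                + 8.552 * math.exp(-(v + 77.42) / 5.955))
    dy[c.S_M] = (mss - y[c.S_M]) / tm
    hss = 1.0 / (1.0 + math.exp((v + 82.90 - tsi) / 6.086))
    thf = q10 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285)
                 + 6.149 * math.exp((v + 0.5096) / 20.27))
    ths = q10 / (0.009794 * math.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * math.exp((v + 5.730) / 56.66))
    dy[c.S_HF] = (hss - y[c.S_HF]) / thf
    dy[c.S_HS] = (hss - y[c.S_HS]) / ths
    h = 0.99 * y[c.S_HF] + 0.01 * y[c.S_HS]
    jss = hss
    tj = 2.038 * q10 + q10 / (0.02136 * math.exp(-(v + 100.6) / 8.281)
                              + 0.3052 * math.exp((v + 0.9941) / 38.45))
    dy[c.S_J] = (jss - y[c.S_J]) / tj
    hssp = 1.0 / (1.0 + math.exp((v + 89.1 - tsi) / 6.086))
    dy[c.S_HSP] = (hssp - y[c.S_HSP]) / (3.0 * ths)
    hp = 0.99 * y[c.S_HF] + 0.01 * y[c.S_HSP]
    dy[c.S_JP] = (jss - y[c.S_JP]) / (1.46 * tj)
    gna = p[c.P_GNA] * (1.0 - p[c.P_CAMK_GNA_COUP] * hcoup)
    finap = fp
    ina = (gna * (v - ena) * y[c.S_M] ** 3
           * ((1.0 - finap) * h * y[c.S_J] + finap * hp * y[c.S_JP]))

    # ---------------- late Na+ current ----------------
    mlss = 1.0 / (1.0 + math.exp(-(v + 42.85 - tsa) / 5.264))
    dy[c.S_ML] = (mlss - y[c.S_ML]) / tm
    hlss = 1.0 / (1.0 + math.exp((v + 87.61 - tsi) / 7.488))
    thl = p[c.P_THL] * q10
    dy[c.S_HL] = (hlss - y[c.S_HL]) / thl
    hlssp = 1.0 / (1.0 + math.exp((v + 93.81 - tsi) / 7.488))
    dy[c.S_HLP] = (hlssp - y[c.S_HLP]) / (3.0 * thl)
    gnal = p[c.P_GNAL] * (1.0 + p[c.P_CAMK_GNAL_COUP] * hcoup)
    inal = (gnal * (v - ena) * y[c.S_ML]
            * ((1.0 - fp) * y[c.S_HL] + fp * y[c.S_HLP]))

    # ---------------- Ito2 (Ca2+-activated Cl-) ----------------
    remod = p[c.P_REMOD_ON] * p[c.P_ACTIVE_TS1] * p[c.P_FRAC_TS1] / 0.22
    vh_to2 = p[c.P_VHALF_TO2] + p[c.P_TO2_SHIFT] + 20.7 * remod
    ato2ss = 1.0 / (1.0 + math.exp(-(v - vh_to2) / p[c.P_K_TO2]))
    dy[c.S_ATO2] = (ato2ss - y[c.S_ATO2]) / p[c.P_TAU_ATO2]
    kca = p[c.P_KM_TO2CA]
    aass = cass * cass / (cass * cass + kca * kca)
    dy[c.S_ITO2CA] = (aass - y[c.S_ITO2CA]) / p[c.P_TAU_AA]
    phicl = vffrt * (cli - clo * math.exp(vfrt)) / (1.0 - math.exp(vfrt))
    gto2 = p[c.P_GTO2] * p[c.P_TO2_GFAC] * (1.0 - 0.05 * remod)
    ito2 = gto2 * y[c.S_ATO2] * y[c.S_ITO2CA] * phicl

    # ---------------- L-type Ca2+ current (Markov) ----------------
    carrier = int(p[c.P_CARRIER_BA])
    open_wt = ((1.0 - fp) * _block_derivs(
        y, c.LTCC_BLOCKS[0],
        _ltcc_rates_arr(v, cass, p, 0, 0, carrier), dy)
        + fp * _block_derivs(
            y, c.LTCC_BLOCKS[1],
            _ltcc_rates_arr(v, cass, p, 0, 1, carrier), dy))
    open_ts1 = ((1.0 - fp) * _block_derivs(
        y, c.LTCC_BLOCKS[2],
        _ltcc_rates_arr(v, cass, p, 1, 0, carrier), dy)
        + fp * _block_derivs(
            y, c.LTCC_BLOCKS[3],
            _ltcc_rates_arr(v, cass, p, 1, 1, carrier), dy))
    frac = p[c.P_FRAC_TS1]
    mix = ((1.0 - frac) * p[c.P_ACTIVE_WT] * open_wt
           + frac * p[c.P_ACTIVE_TS1] * open_ts1)
    pcal = p[c.P_PCA]
    phical = (4.0 * vffrt * (cass * math.exp(2.0 * vfrt) - 0.341 * cao)
              / (math.exp(2.0 * vfrt) - 1.0))
    phicana = (vffrt * (0.75 * nass * math.exp(vfrt) - 0.75 * nao)
               / (math.exp(vfrt) - 1.0))
    phicak = (vffrt * (0.75 * kss * math.exp(vfrt) - 0.75 * ko)
              / (math.exp(vfrt) - 1.0))
    ical = pcal * phical * mix
    icana = 0.00125 * pcal * phicana * mix
    icak = 3.574e-4 * pcal * phicak * mix

    # ---------------- IKr ----------------
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337 - p[c.P_IKR_ACT_SHIFT])
                                 / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))
    dy[c.S_XRF] = (xrss - y[c.S_XRF]) / txrf
    dy[c.S_XRS] = (xrss - y[c.S_XRS]) / txrs
    axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    xr = axrf * y[c.S_XRF] + (1.0 - axrf) * y[c.S_XRS]
    vr = v - p[c.P_IKR_INACT_SHIFT]
    rkr = 1.0 / ((1.0 + math.exp((vr + 55.0) / 75.0))
                 * (1.0 + math.exp((vr - 10.0) / 30.0)))
    ikr = p[c.P_GKR] * math.sqrt(ko / 5.4) * xr * rkr * (v - ek)

    # ---------------- IKs ----------------
    xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    ksts = p[c.P_IKS_TAU_SCALE]
    txs1 = (817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80)
                           + 0.001292 * math.exp(-(v + 210.0) / 230.0))
            ) * ksts
    dy[c.S_XS1] = (xs1ss - y[c.S_XS1]) / txs1
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0)
                  + 0.0193 * math.exp(-(v + 66.54) / 31.0)) * ksts
    dy[c.S_XS2] = (xs1ss - y[c.S_XS2]) / txs2
    ksca = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    gks = p[c.P_GKS] * (1.0 - 0.4 * remod)
    iks = gks * ksca * y[c.S_XS1] * y[c.S_XS2] * (v - eks)

    # ---------------- IK1 ----------------
    xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * ko + 144.59)
                                  / (1.5692 * ko + 3.8115)))
    txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36)
                    + math.exp((v + 236.8) / 69.33))
    dy[c.S_XK1] = (xk1ss - y[c.S_XK1]) / txk1
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * ko) / 9.493))
    ik1 = p[c.P_GK1] * math.sqrt(ko) * rk1 * y[c.S_XK1] * (v - ek)

    # ---------------- Na+/Ca2+ exchanger ----------------
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    qna = 0.5224
    qca = 0.167
    hca = math.exp(qca * vfrt)
    hna = math.exp(qna * vfrt)
    kmcaact = 150.0e-6
    gncx = p[c.P_GNCX]

    # cytosolic exchanger
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = nai * hna / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
    h8 = nao / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + nao / kna1 * (1.0 + nao / kna2)
    h11 = nao * nao / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * cao * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    e1 = x1 / (x1 + x2 + x3 + x4)
    e2 = x2 / (x1 + x2 + x3 + x4)
    e3 = x3 / (x1 + x2 + x3 + x4)
    e4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (kmcaact / cai) ** 2)
    jncxna = 3.0 * (e4 * k7 - e1 * k8) + e3 * k4pp - e2 * k3pp
    jncxca = e2 * k2 - e1 * k1
    inaca_i = 0.8 * gncx * allo * (jncxna + 2.0 * jncxca)

    # subspace exchanger
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = nass * hna / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    e1 = x1 / (x1 + x2 + x3 + x4)
    e2 = x2 / (x1 + x2 + x3 + x4)
    e3 = x3 / (x1 + x2 + x3 + x4)
    e4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (kmcaact / cass) ** 2)
    jncxna = 3.0 * (e4 * k7 - e1 * k8) + e3 * k4pp - e2 * k3pp
    jncxca = e2 * k2 - e1 * k1
    inaca_ss = 0.2 * gncx * allo * (jncxna + 2.0 * jncxca)

    # ---------------- Na+/K+ pump ----------------
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3pk = 1899.0
    k3m = 79300.0
    k4pk = 639.0
    k4m = 40.0
    knai = 9.073 * math.exp(-0.155 * vfrt / 3.0)
    knao = 27.78 * math.exp((1.0 + 0.155) * vfrt / 3.0)
    kki = 0.5
    kko = 0.3582
    mgadp = 0.05
    mgatp = p[c.P_MGATP]
    kmgatp = 1.698e-7
    hp_ = 1.0e-7
    ep = 4.2
    khp = 1.698e-7
    knap = 224.0
    kxkur = 292.0
    pp = ep / (1.0 + hp_ / khp + nai / knap + ki / kxkur)
    a1 = (k1p * (nai / knai) ** 3
          / ((1.0 + nai / knai) ** 3 + (1.0 + ki / kki) ** 2 - 1.0))
    b1 = k1m * mgadp
    a2 = k2p
    b2 = (k2m * (nao / knao) ** 3
          / ((1.0 + nao / knao) ** 3 + (1.0 + ko / kko) ** 2 - 1.0))
    a3 = (k3pk * (ko / kko) ** 2
          / ((1.0 + nao / knao) ** 3 + (1.0 + ko / kko) ** 2 - 1.0))
    b3 = k3m * pp * hp_ / (1.0 + mgatp / kmgatp)
    a4 = k4pk * mgatp / kmgatp / (1.0 + mgatp / kmgatp)
    b4 = (k4m * (ki / kki) ** 2
          / ((1.0 + nai / knai) ** 3 + (1.0 + ki / kki) ** 2 - 1.0))
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b1 * a4
    e1 = x1 / (x1 + x2 + x3 + x4)
    e2 = x2 / (x1 + x2 + x3 + x4)
    e3 = x3 / (x1 + x2 + x3 + x4)
    e4 = x4 / (x1 + x2 + x3 + x4)
    jnakna = 3.0 * (e1 * a3 - e2 * b3)
    jnakk = 2.0 * (e4 * b1 - e3 * a1)
    inak = p[c.P_PNAK] * (jnakna + jnakk)

    # ---------------- minor currents ----------------
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    ikb = p[c.P_GKB] * xkb * (v - ek)
    inab = (p[c.P_PNAB] * vffrt * (nai * math.exp(vfrt) - nao)
            / (math.exp(vfrt) - 1.0))
    icab = (p[c.P_PCAB] * 4.0 * vffrt
            * (cai * math.exp(2.0 * vfrt) - 0.341 * cao)
            / (math.exp(2.0 * vfrt) - 1.0))
    ipca = p[c.P_GPCA] * cai / (0.0005 + cai)
    iclb = p[c.P_GCLB] * (v - ecl)

    # ---------------- stimulus ----------------
    istim = 0.0
    if mode == 0.0 and p[c.P_STIM_AMP] != 0.0:
        tb = t % p[c.P_STIM_PERIOD]
        if tb < p[c.P_STIM_DUR]:
            istim = p[c.P_STIM_AMP]

    # ---------------- SR Ca2+ release ----------------
    btfac = 1.0
    if p[c.P_RIPPLE_MAG] > 0.0:
        tb = t % p[c.P_STIM_PERIOD]
        tr = tb - p[c.P_RIPPLE_LAT]
        if 0.0 <= tr < p[c.P_RIPPLE_DUR]:
            btfac = 1.0 + p[c.P_RIPPLE_MAG] * math.sin(
                2.0 * math.pi * p[c.P_RIPPLE_FREQ] * tr)
            if btfac < 0.0:
                btfac = 0.0
    bt = p[c.P_BT] * btfac
    a_rel = 0.5 * bt
    jrel_inf = a_rel * (-ical) / (1.0 + (p[c.P_REL_KM_CAJSR] / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    dy[c.S_JRELNP] = (jrel_inf - y[c.S_JRELNP]) / tau_rel
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    jrelp_inf = a_relp * (-ical) / (1.0 + (p[c.P_REL_KM_CAJSR] / cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    dy[c.S_JRELP] = (jrelp_inf - y[c.S_JRELP]) / tau_relp
    jrel = (1.0 - fp) * y[c.S_JRELNP] + fp * y[c.S_JRELP]

    # ---------------- SERCA uptake / leak / translocation ----------------
    vmax = p[c.P_JUP_VMAX]
    kmup = p[c.P_KM_SERCA]
    jupnp = vmax * cai / (cai + kmup)
    jupp = 2.75 * vmax * cai / (cai + kmup - 0.00017)
    jleak = p[c.P_JLEAK_SCALE] * 0.0039375 * cansr / 15.0
    jup = (1.0 - fp) * jupnp + fp * jupp - jleak
    jtr = (cansr - cajsr) / p[c.P_TAU_TR]

    jdiffna = (nass - nai) / p[c.P_TAU_DIFF_NA]
    jdiffk = (kss - ki) / p[c.P_TAU_DIFF_K]
    jdiffca = (cass - cai) / p[c.P_TAU_DIFF_CA]

    # ---------------- mass balances ----------------
    dy[c.S_NAI] = (-(ina + inal + 3.0 * inaca_i + 3.0 * inak + inab)
                   * acap / (_F * vmyo) + jdiffna * vss / vmyo)
    dy[c.S_NASS] = (-(icana + 3.0 * inaca_ss) * acap / (_F * vss) - jdiffna)
    dy[c.S_KI] = (-(ikr + iks + ik1 + ikb + istim - 2.0 * inak)
                  * acap / (_F * vmyo) + jdiffk * vss / vmyo)
    dy[c.S_KSS] = -icak * acap / (_F * vss) - jdiffk
    dy[c.S_CLI] = (ito2 + iclb) * acap / (_F * vmyo)

    bcai = 1.0 / (1.0
                  + p[c.P_CMDN_MAX] * p[c.P_KM_CMDN]
                  / (p[c.P_KM_CMDN] + cai) ** 2
                  + p[c.P_TRPN_MAX] * p[c.P_KM_TRPN]
                  / (p[c.P_KM_TRPN] + cai) ** 2)
    dy[c.S_CAI] = bcai * (
        -(ipca + icab - 2.0 * inaca_i) * acap / (2.0 * _F * vmyo)
        - jup * vnsr / vmyo + jdiffca * vss / vmyo)
    bcass = 1.0 / (1.0
                   + p[c.P_BSR_MAX] * p[c.P_KM_BSR]
                   / (p[c.P_KM_BSR] + cass) ** 2
                   + p[c.P_BSL_MAX] * p[c.P_KM_BSL]
                   / (p[c.P_KM_BSL] + cass) ** 2)
    dy[c.S_CASS] = bcass * (
        -(ical - 2.0 * inaca_ss) * acap / (2.0 * _F * vss)
        + jrel * vjsr / vss - jdiffca)
    dy[c.S_CANSR] = jup - jtr * vjsr / vnsr
    bcajsr = 1.0 / (1.0 + p[c.P_CSQN_MAX] * p[c.P_KM_CSQN]
                    / (p[c.P_KM_CSQN] + cajsr) ** 2)
    dy[c.S_CAJSR] = bcajsr * (jtr - jrel)

    itot = (ina + inal + ito2 + ical + icana + icak + ikr + iks + ik1
            + inaca_i + inaca_ss + inak + inab + icab + ikb + ipca + iclb)
    if mode == 0.0:
        dy[c.S_V] = -(itot + istim)
    elif mode == 1.0:
        dy[c.S_V] = 0.0
    else:  # AP clamp: follow the waveform derivative
        nwave = wave_v.shape[0]
        period_w = wave_dt * (nwave - 1)
        tt = t % period_w
        k = int(tt / wave_dt)
        if k >= nwave - 1:
            k = nwave - 2
        dy[c.S_V] = wave_dv[k]

    cur[c.C_INA] = ina
    cur[c.C_INAL] = inal
    cur[c.C_ITO2] = ito2
    cur[c.C_ICAL] = ical
    cur[c.C_ICANA] = icana
    cur[c.C_ICAK] = icak
    cur[c.C_IKR] = ikr
    cur[c.C_IKS] = iks
    cur[c.C_IK1] = ik1
    cur[c.C_INACA_I] = inaca_i
    cur[c.C_INACA_SS] = inaca_ss
    cur[c.C_INAK] = inak
    cur[c.C_INAB] = inab
    cur[c.C_ICAB] = icab
    cur[c.C_IKB] = ikb
    cur[c.C_IPCA] = ipca
    cur[c.C_ICLB] = iclb
    cur[c.C_ISTIM] = istim
    cur[c.C_JREL] = jrel
    cur[c.C_JUP] = jup
    cur[c.C_CAMKA] = camka
    return dy, cur


@njit(cache=True)
def rhs(t, y, p, wave_dt, wave_v, wave_dv):
    dy, _ = rhs_full(t, y, p, wave_dt, wave_v, wave_dv)
    return dy


_EMPTY = np.zeros(2)


def derivatives_vector(t, y, pvec, wave_dt=1.0, wave_v=None, wave_dv=None):
    """Python entry point; returns dy only."""
    if wave_v is None:
        wave_v = _EMPTY
        wave_dv = _EMPTY
    return rhs(t, np.asarray(y, dtype=np.float64), pvec,
               wave_dt, wave_v, wave_dv)
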