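"""Markov L-type Ca2+ channel with separate VDI and CDI loops.

The channel is described by two four-state loops, each with closed (C),
open (O) and two inactivated (I1, I2) states.  The VDI loop carries
voltage-dependent activation (C<->O) and voltage-dependent inactivation;
the CDI loop shares the activation transition and inactivates as a
function of subspace Ca2+.  A channel conducts when its VDI loop is open
and its CDI loop is not inactivated, so the open fraction of a block is
``O_vdi * (C_cdi + O_cdi)``.

The G406R (TS1) variant slows exactly two VDI transitions - O->I1 and
C->I2 - by the fitted factors ``ts1_oi1_slow`` and ``ts1_ci2_slow``;
everything else is shared with the WT channel.  With Ba2+ as the charge
carrier the CDI-loop inactivation entry rates are zeroed (VDI only).
CaMKII-phosphorylated channels have VDI time constants scaled by
``phospho_slow``, which produces Ca2+/CaMKII-dependent facilitation of
peak current at fast pacing.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import constants as c

# edge order within a loop: C->O, O->C, O->I1, I1->O, I1->I2, I2->I1,
#                           I2->C, C->I2
N_EDGES = 8

WT, TS1 = 0, 1
CARRIER_CA, CARRIER_BA = 0, 1


@njit(cache=True)
def _ltcc_rates_arr(v, cass, p, variant, phospho, carrier):
    """Transition rates (1/ms): 16-vector, VDI edges then CDI edges."""
    act_shift = p[c.P_ACT_SHIFT]
    vhalf_act = -3.94 + act_shift
    dss = 1.0 / (1.0 + math.exp(-(v - vhalf_act) / 4.23))
    tau_d = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0))
                         + math.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tau_f1 = (7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0)
                           + 0.0045 * math.exp((v + 20.0) / 10.0))
              ) * p[c.P_VDI_T1_SCALE]
    tau_f2 = (1000.0 + 1.0 / (3.5e-5 * math.exp(-(v + 5.0) / 4.0)
                              + 3.5e-5 * math.exp((v + 5.0) / 6.0))
              ) * p[c.P_VDI_T2_SCALE]
    if phospho == 1:
        slow = p[c.P_PHOSPHO_SLOW]
        tau_f1 *= slow
        tau_f2 *= slow

    r = np.zeros(16)
    # activation, shared by both loops
    r[0] = dss / tau_d
    r[1] = (1.0 - dss) / tau_d
    # VDI inactivation
    r[2] = (1.0 - fss) / tau_f1        # O -> I1
    r[3] = fss / tau_f1                # I1 -> O
    r[4] = (1.0 - fss) / tau_f2        # I1 -> I2
    r[5] = fss / tau_f2                # I2 -> I1
    r[6] = fss / tau_f2                # I2 -> C (slow recovery)
    r[7] = (1.0 - fss) * p[c.P_K_CI2]  # C -> I2 (closed-state VDI)
    if variant == 1:
        r[2] *= p[c.P_TS1_OI1_SLOW]
        r[7] *= p[c.P_TS1_CI2_SLOW]

    # CDI loop: same activation transition, Ca2+-driven inactivation
    r[8] = r[0]
    r[9] = r[1]
    phi = cass * cass / (cass * cass + p[c.P_KM_CDI] * p[c.P_KM_CDI])
    if carrier == 1:  # Ba2+ carrier: no CDI
        phi = 0.0
    r[10] = phi / p[c.P_TAU_CDI]                 # O -> I1
    r[11] = (1.0 - phi) / p[c.P_TAU_CDI_REC]     # I1 -> O
    r[12] = phi / p[c.P_TAU_CDI2]                # I1 -> I2
    r[13] = (1.0 - phi) / p[c.P_TAU_CDI2]        # I2 -> I1
    r[14] = (1.0 - phi) / p[c.P_TAU_CDI2]        # I2 -> C
    r[15] = phi / (10.0 * p[c.P_TAU_CDI2])       # C -> I2
    return r


@njit(cache=True)
def _loop_derivs(s0, s1, s2, s3, rco, roc, roi1, ri1o, ri1i2, ri2i1,
                 ri2c, rci2):
    """Generator action on one 4-state loop (C, O, I1, I2)."""
    dc = -(rco + rci2) * s0 + roc * s1 + ri2c * s3
    do = rco * s0 - (roc + roi1) * s1 + ri1o * s2
    di1 = roi1 * s1 - (ri1o + ri1i2) * s2 + ri2i1 * s3
    di2 = rci2 * s0 + ri1i2 * s2 - (ri2i1 + ri2c) * s3
    return dc, do, di1, di2


@njit(cache=True)
def _block_derivs(y, off, rates, dy):
    """Fill dy for one 8-state block; return its conducting fraction."""
    dc, do, di1, di2 = _loop_derivs(
        y[off], y[off + 1], y[off + 2], y[off + 3],
        rates[0], rates[1], rates[2], rates[3],
        rates[4], rates[5], rates[6], rates[7])
    dy[off] = dc
    dy[off + 1] = do
    dy[off + 2] = di1
    dy[off + 3] = di2
    dc, do, di1, di2 = _loop_derivs(
        y[off + 4], y[off + 5], y[off + 6], y[off + 7],
        rates[8], rates[9], rates[10], rates[11],
        rates[12], rates[13], rates[14], rates[15])
    dy[off + 4] = dc
    dy[off + 5] = do
    dy[off + 6] = di1
    dy[off + 7] = di2
    return y[off + 1] * (y[off + 4] + y[off + 5])


# ----------------------------------------------------------------------
# Python-facing API


def ltcc_rates(v: float, cass: float, params, variant: str = "WT",
               carrier: str = "Ca", phospho: bool = False) -> dict:
    """Transition rates of both loops at (V, Ca_ss).

    Returns a dict keyed by edge name, e.g. ``vdi_o_i1`` / ``cdi_c_o``.
    """
    variants = {"WT": 0, "TS1": 1}
    carriers = {"Ca": 0, "Ba": 1}
    if variant not in variants:
        raise ValueError(f"unknown variant {variant!r}; use WT or TS1")
    if carrier not in carriers:
        raise ValueError(f"unknown carrier {carrier!r}; use Ca or Ba")
    if cass < 0:
        raise ValueError("Ca_ss must be non-negative")
    r = _ltcc_rates_arr(float(v), float(cass), params.to_vector(),
                        variants[variant], 1 if phospho else 0,
                        carriers[carrier])
    edges = ["c_o", "o_c", "o_i1", "i1_o", "i1_i2", "i2_i1", "i2_c", "c_i2"]
    out = {}
    for i, e in enumerate(edges):
        out["vdi_" + e] = float(r[i])
        out["cdi_" + e] = float(r[8 + i])
    return out


def loop_generator(rates: dict, loop: str) -> np.ndarray:
    """4x4 generator matrix of one loop (columns sum to zero)."""
    e = {k.split("_", 1)[1]: v for k, v in rates.items()
         if k.startswith(loop + "_")}
    g = np.zeros((4, 4))
    idx = {"c": 0, "o": 1, "i1": 2, "i2": 3}
    for name, rate in e.items():
        a, b = name.split("_")
        g[idx[b], idx[a]] += rate
        g[idx[a], idx[a]] -= rate
    return g


def active_fractions(desired_silencing_wt: float, desired_silencing_ts1: float,
                     gene_therapy: float) -> tuple[float, float]:
    """Fractions of WT/TS1 channels left active under gene silencing.

    active = 1 - desired_silencing * gene_therapy, with gene_therapy 0
    (no silencing) or 1 (therapy applied).
    """
    for x in (desired_silencing_wt, desired_silencing_ts1):
        if not 0.0 <= x <= 1.0:
            raise ValueError("silencing fractions must lie in [0, 1]")
    if gene_therapy not in (0, 1, 0.0, 1.0):
        raise ValueError("gene_therapy must be 0 or 1")
    return (1.0 - desired_silencing_wt * gene_therapy,
            1.0 - desired_silencing_ts1 * gene_therapy)


def ba_mode(params):
    """Parameters for Ba2+-carrier recordings: CDI-loop entry disabled.

    The driving-force constant is left unchanged (availability and FRC
    summaries are normalized, so only the VDI kinetics matter here).
    """
    return params.replace(carrier_ba=1.0)


def conducting_fraction(block: np.ndarray) -> float:
    """Conducting probability of one 8-state block [VDI C,O,I1,I2, CDI ...]."""
    return float(block[1] * (block[4] + block[5]))


def ltcc_current(v: float, cass: float, nass: float, kss: float, params,
                 open_wt: float, open_ts1: float) -> float:
    """Ca2+ component of I_CaL (A/F) for given subpopulation open fractions.

    The WT/TS1 subpopulations and gene-therapy active fractions are mixed
    linearly; the driving force is the ORd GHK term.
    """
    p = params
    for frac in (p.active_wt, p.active_ts1):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("active fractions must lie in [0, 1]")
    vfrt = v * c.FARADAY / (c.RGAS * c.TEMP)
    vffrt = v * c.FARADAY * c.FARADAY / (c.RGAS * c.TEMP)
    if abs(vfrt) < 1e-7:
        vfrt = 1e-7
        vffrt = vfrt * c.FARADAY
    phica = 4.0 * vffrt * (cass * math.exp(2 * vfrt) - 0.341 * p.cao) \
        / (math.exp(2 * vfrt) - 1.0)
    mix = ((1.0 - p.frac_ts1) * p.active_wt * open_wt
           + p.frac_ts1 * p.active_ts1 * open_ts1)
    return p.pca * phica * mix
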