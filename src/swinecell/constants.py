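"""State and parameter enumeration for the swine ventricular myocyte model.

The model comprises 61 ordinary differential equations: membrane potential,
ten ionic concentration / Ca2+-cycling variables, Hodgkin-Huxley gates for
INa/INaL/Ito2/IKr/IKs/IK1, four 8-state Markov blocks for the L-type Ca2+
channel (WT and G406R subpopulations, each with a CaMKII-phosphorylated
copy), the two ryanodine-release driver states and the trapped-CaMKII
fraction.

Index constants ``S_<NAME>`` (states) and ``P_<NAME>`` (parameters) are
generated from the ordered name lists below so the JIT-compiled right-hand
side and the Python API share a single enumeration.
"""

# fmt: off
STATE_NAMES = [
    "v",                                    # membrane potential (mV)
    "nai", "nass",                          # Na+ (mM), myoplasm / subspace
    "ki", "kss",                            # K+ (mM)
    "cai", "cass",                          # free Ca2+ (mM)
    "cansr", "cajsr",                       # SR Ca2+ (mM), network / junctional
    "cli",                                  # Cl- (mM)
    "m", "hf", "hs", "j", "hsp", "jp",      # fast Na+ current gates
    "ml", "hl", "hlp",                      # late Na+ current gates
    "ato2", "ito2ca",                       # Ito2 activation / Ca2+-activation gates
    "xrf", "xrs",                           # IKr
    "xs1", "xs2",                           # IKs
    "xk1",                                  # IK1
    # L-type Ca2+ channel Markov blocks; per block: VDI loop {C,O,I1,I2}
    # then CDI loop {C,O,I1,I2}
    "lw_vc", "lw_vo", "lw_vi1", "lw_vi2",   # WT, non-phosphorylated
    "lw_cc", "lw_co", "lw_ci1", "lw_ci2",
    "lwp_vc", "lwp_vo", "lwp_vi1", "lwp_vi2",   # WT, CaMKII-phosphorylated
    "lwp_cc", "lwp_co", "lwp_ci1", "lwp_ci2",
    "lt_vc", "lt_vo", "lt_vi1", "lt_vi2",   # TS1 (G406R), non-phosphorylated
    "lt_cc", "lt_co", "lt_ci1", "lt_ci2",
    "ltp_vc", "ltp_vo", "ltp_vi1", "ltp_vi2",   # TS1, CaMKII-phosphorylated
    "ltp_cc", "ltp_co", "ltp_ci1", "ltp_ci2",
    "jrelnp", "jrelp",                      # SR release driver states (mM/ms)
    "camkt",                                # trapped CaMKII fraction
]
# fmt: on

N_STATES = len(STATE_NAMES)
assert N_STATES == 61

# offsets of the four LTCC blocks (wt, wt-phospho, ts1, ts1-phospho)
LTCC_BLOCKS = (
    STATE_NAMES.index("lw_vc"),
    STATE_NAMES.index("lwp_vc"),
    STATE_NAMES.index("lt_vc"),
    STATE_NAMES.index("ltp_vc"),
)

PARAM_NAMES = [
    # external milieu (mM) and geometry (cm)
    "nao", "cao", "ko", "clo", "cell_len", "cell_rad",
    # maximal conductances (mS/uF) / permeabilities (cm/s)
    "gna", "gnal", "gkr", "gks", "gk1", "gto2", "pca",
    "gncx", "pnak", "pnab", "pcab", "gkb", "gpca", "gclb",
    # Ca2+ handling
    "jup_vmax", "km_serca", "jleak_scale", "bt", "rel_km_cajsr",
    "trpn_max", "km_trpn", "cmdn_max", "km_cmdn", "csqn_max", "km_csqn",
    "bsr_max", "km_bsr", "bsl_max", "km_bsl",
    "tau_tr", "tau_diff_ca", "tau_diff_na", "tau_diff_k",
    # CaMKII subsystem
    "camk_o", "km_cam", "a_camk", "b_camk", "km_camk",
    "camk_km_mult", "camk_gna_coup", "camk_gnal_coup", "camk_coup_km",
    # Na+ gate kinetics / temperature correction
    "thl", "tshift_act", "tshift_inact", "q10_tau_scale",
    # IKr gate shifts (drug interventions)
    "ikr_act_shift", "ikr_inact_shift", "iks_tau_scale",
    # Ito2
    "vhalf_to2", "k_to2", "tau_ato2", "km_to2ca", "tau_aa",
    "to2_shift", "to2_gfac",
    # LTCC Markov kinetics
    "act_shift", "tau_cdi", "tau_cdi_rec", "tau_cdi2", "km_cdi",
    "k_ci2", "phospho_slow", "ts1_oi1_slow", "ts1_ci2_slow",
    "vdi_t1_scale", "vdi_t2_scale",
    # subpopulation mixing (mutant fraction, gene-therapy activity) and
    # the secondary-remodeling switch (IKs / Ito2 linear dependencies)
    "frac_ts1", "active_wt", "active_ts1", "remod_on", "carrier_ba",
    # Na/K pump substrate
    "mgatp",
    # stimulus (A/F, ms, ms)
    "stim_amp", "stim_dur", "stim_period",
    # integration mode: 0 free-running/paced, 1 V-clamp, 2 AP-clamp
    "mode",
    # late-systolic Ca2+ ripple imposition on the release parameter bt
    "ripple_mag", "ripple_freq", "ripple_lat", "ripple_dur",
]

N_PARAMS = len(PARAM_NAMES)

CURRENT_NAMES = [
    "ina", "inal", "ito2", "ical", "icana", "icak", "ikr", "iks", "ik1",
    "inaca_i", "inaca_ss", "inak", "inab", "icab", "ikb", "ipca", "iclb",
    "istim", "jrel", "jup", "camka",
]
N_CURRENTS = len(CURRENT_NAMES)

_g = globals()
for _i, _n in enumerate(STATE_NAMES):
    _g["S_" + _n.upper()] = _i
for _i, _n in enumerate(PARAM_NAMES):
    _g["P_" + _n.upper()] = _i
for _i, _n in enumerate(CURRENT_NAMES):
    _g["C_" + _n.upper()] = _i

# physical constants (ORd unit convention: mV, ms, mM, A/F)
RGAS = 8314.0       # J / kmol / K
FARADAY = 96485.0   # C / mol
TEMP = 310.0        # K (physiological reference)
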