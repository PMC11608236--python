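"""Parameter handling for the swine ventricular myocyte model.

All values follow the ORd unit convention: potentials in mV, time in ms,
concentrations in mM, current densities in A/F (= pA/pF), conductances in
mS/uF, permeabilities in cm/s, fluxes in mM/ms.

The defaults constitute the wild-type (WT) large-white swine myocyte at
37 degC.  Defaults were obtained by refitting the ORd-2011 backbone (with
Markov L-type channel and Ca2+-activated Cl- Ito2) against the swine
calibration targets: TTX-sensitive late Na+ current of -0.12 A/F with a
175 ms inactivation time constant in a -120 -> -30 mV clamp at 22 degC,
biomarker bands at 0.5/1/2 Hz and the diastolic jSR Ca2+ level at 0.5 Hz.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from . import constants as c


@dataclass
class Params:
    """Complete parameter set; field order mirrors ``constants.PARAM_NAMES``."""

    # external milieu (mM) and cylindrical geometry (cm)
    nao: float = 140.0
    cao: float = 1.8
    ko: float = 4.0
    clo: float = 149.6
    cell_len: float = 0.0105
    cell_rad: float = 0.0006

    # maximal conductances / permeabilities
    gna: float = 100.0
    gnal: float = 0.00629
    gkr: float = 0.02
    gks: float = 0.07
    gk1: float = 0.10
    gto2: float = 2.0e-7
    pca: float = 1.35e-4
    gncx: float = 0.0009
    pnak: float = 24.0
    pnab: float = 3.75e-10
    pcab: float = 1.8e-8
    gkb: float = 0.003
    gpca: float = 0.0005
    gclb: float = 2.5e-4

    # Ca2+ handling (uptake, buffers, translocation, diffusion)
    jup_vmax: float = 0.0066
    km_serca: float = 0.00092
    jleak_scale: float = 1.0
    bt: float = 4.75
    rel_km_cajsr: float = 1.0
    trpn_max: float = 0.07
    km_trpn: float = 0.0011
    cmdn_max: float = 0.05
    km_cmdn: float = 0.00238
    csqn_max: float = 10.0
    km_csqn: float = 0.8
    bsr_max: float = 0.047
    km_bsr: float = 0.00087
    bsl_max: float = 1.124
    km_bsl: float = 0.0087
    tau_tr: float = 100.0
    tau_diff_ca: float = 0.2
    tau_diff_na: float = 2.0
    tau_diff_k: float = 2.0

    # CaMKII subsystem and its couplings to the Na+ currents
    camk_o: float = 0.05
    km_cam: float = 0.0015
    a_camk: float = 0.05
    b_camk: float = 0.00068
    km_camk: float = 0.15
    camk_km_mult: float = 1.0
    camk_gna_coup: float = 0.3
    camk_gnal_coup: float = 4.0
    camk_coup_km: float = 0.03

    # Na+ gate kinetics; temperature correction (reference 37 degC)
    thl: float = 61.55
    tshift_act: float = 0.0
    tshift_inact: float = 0.0
    q10_tau_scale: float = 1.0

    # IKr gate shifts (pharmacology)
    ikr_act_shift: float = 0.0
    ikr_inact_shift: float = 0.0
    iks_tau_scale: float = 0.3

    # Ca2+-activated Cl- current (Ito2)
    vhalf_to2: float = 10.0
    k_to2: float = 11.0
    tau_ato2: float = 3.0
    km_to2ca: float = 4.0e-4
    tau_aa: float = 2.0
    to2_shift: float = 0.0
    to2_gfac: float = 1.0

    # Markov L-type channel kinetics
    act_shift: float = 0.0
    tau_cdi: float = 3.0
    tau_cdi_rec: float = 40.0
    tau_cdi2: float = 150.0
    km_cdi: float = 0.002
    k_ci2: float = 0.002
    phospho_slow: float = 2.5
    ts1_oi1_slow: float = 0.05
    ts1_ci2_slow: float = 0.05
    vdi_t1_scale: float = 3.0
    vdi_t2_scale: float = 1.0

    # LTCC subpopulation mixing (G406R fraction; gene-therapy activities)
    frac_ts1: float = 0.0
    active_wt: float = 1.0
    active_ts1: float = 1.0
    remod_on: float = 1.0
    carrier_ba: float = 0.0

    # Na+/K+ pump substrate (mM), matched to pipette solution
    mgatp: float = 4.0

    # stimulus: rectangular current pulse
    stim_amp: float = -18.0
    stim_dur: float = 3.0
    stim_period: float = 1000.0

    # integration mode (0 paced/free, 1 V-clamp, 2 AP-clamp)
    mode: float = 0.0

    # late-systolic ripple imposition on the release parameter bt
    ripple_mag: float = 0.0
    ripple_freq: float = 0.0
    ripple_lat: float = 0.0
    ripple_dur: float = 0.0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        names = [f.name for f in dataclasses.fields(self)]
        if names != c.PARAM_NAMES:
            raise RuntimeError("Params fields out of sync with PARAM_NAMES")

    def to_vector(self) -> np.ndarray:
        return np.array(
            [getattr(self, n) for n in c.PARAM_NAMES], dtype=np.float64
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "Params":
        return cls(**{n: float(v) for n, v in zip(c.PARAM_NAMES, vec)})

    def replace(self, **kw) -> "Params":
        return dataclasses.replace(self, **kw)

    def scaled(self, factors: dict[str, float]) -> "Params":
        """Multiply the named parameters by scaling factors."""
        kw = {}
        for name, fac in factors.items():
            if name not in c.PARAM_NAMES:
                raise KeyError(f"unknown parameter {name!r}")
            kw[name] = getattr(self, name) * fac
        return self.replace(**kw)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` on physically inadmissible parameters."""
        vec = self.to_vector()
        if not np.all(np.isfinite(vec)):
            bad = c.PARAM_NAMES[int(np.nonzero(~np.isfinite(vec))[0][0])]
            raise ValueError(f"non-finite parameter: {bad}")
        for name in (
            "gna", "gnal", "gkr", "gks", "gk1", "gto2", "pca", "gncx",
            "pnak", "pnab", "pcab", "gkb", "gpca", "gclb", "jup_vmax", "bt",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"negative conductance/flux: {name}")
        if not 0.0 <= self.frac_ts1 <= 1.0:
            raise ValueError("frac_ts1 must lie in [0, 1]")
        for name in ("active_wt", "active_ts1"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.stim_period <= self.stim_dur:
            raise ValueError("stimulus period must exceed stimulus duration")
        for name in ("nao", "cao", "ko", "clo"):
            if getattr(self, name) <= 0:
                raise ValueError(f"non-positive external concentration: {name}")

    # ------------------------------------------------------------------
    def with_temperature(self, temp_c: float) -> "Params":
        """Return parameters transformed to a recording temperature.

        Steady-state V1/2 of Na+-current activation/inactivation shift by
        +4.3 / +4.7 mV per 10 degC of warming; time constants scale with
        Q10 = 2.  The reference parameterization is at 37 degC.
        """
        dt10 = (temp_c - 37.0) / 10.0
        return self.replace(
            tshift_act=4.3 * dt10,
            tshift_inact=4.7 * dt10,
            q10_tau_scale=2.0 ** (-dt10),
        )

    # derived geometry -------------------------------------------------
    @property
    def vcell(self) -> float:
        """Cell volume (uL)."""
        return 1000.0 * math.pi * self.cell_rad**2 * self.cell_len

    @property
    def ageo(self) -> float:
        """Geometric membrane area (cm^2)."""
        return (2 * math.pi * self.cell_rad**2
                + 2 * math.pi * self.cell_rad * self.cell_len)

    @property
    def acap(self) -> float:
        """Capacitive membrane area (cm^2), with the ORd folding factor 2."""
        return 2.0 * self.ageo


def wild_type() -> Params:
    """The calibrated WT swine myocyte parameter set (37 degC)."""
    return Params()
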