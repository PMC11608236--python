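"""TS1 phenotype construction and therapeutic / mechanistic perturbations.

All interventions are pure parameter transforms (simple-pore scaling and
gate shifting; no state-dependent drug binding).  They compose freely, so
e.g. gene therapy and a hERG activator can be applied to the same cell.

The TS1 phenotype introduces a G406R-mutated LTCC subpopulation (default
22 % of channels) plus secondary remodeling that scales linearly with the
active mutated fraction: G_Ks is reduced by 40 % at the reference 22 %
mutant load, and Ito2 is shifted by +20.7 mV with 5 % lower conductance.
The remodeling terms are evaluated inside the model from
``frac_ts1 * active_ts1 / 0.22``, so silencing mutated channels also
relieves the secondary remodeling.
"""

from __future__ import annotations

import numpy as np

from . import biomarkers, ltcc, model
from .params import Params

TS1_FRACTION = 0.22

DRUGS = {
    # verapamil: LTCC block, partial swine-ERG selectivity, marginal Nav1.5
    "verapamil": {"pca": 0.64, "gkr": 0.55, "gna": 0.998},
    # mexiletine 10 uM
    "mexiletine": {"gnal": 1 - 0.52, "gkr": 1 - 0.09, "pca": 1 - 0.20,
                   "gna": 1 - 0.06},
    # ranolazine 6.9 uM
    "ranolazine": {"gnal": 1 - 0.48, "gkr": 1 - 0.54, "gna": 1 - 0.06},
}
# ICA-105574 (hERG activator): +42 mV inactivation shift, -11 mV
# activation shift, 2.277-fold G_Kr
ICA_SCALE_GKR = 2.277
ICA_INACT_SHIFT = 42.0
ICA_ACT_SHIFT = -11.0


def make_ts1(base: Params, fraction: float = TS1_FRACTION,
             remodeling: bool = True) -> Params:
    """TS1 myocyte: mutant LTCC subpopulation + secondary remodeling."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return base.replace(frac_ts1=fraction,
                        remod_on=1.0 if remodeling else 0.0)


def apply_drug(params: Params, drug: str) -> Params:
    """Simulated drug application as a static parameter transform."""
    drug = drug.lower().replace("-", "")
    if drug == "ica105574":
        return params.replace(
            gkr=params.gkr * ICA_SCALE_GKR,
            ikr_inact_shift=params.ikr_inact_shift + ICA_INACT_SHIFT,
            ikr_act_shift=params.ikr_act_shift + ICA_ACT_SHIFT)
    if drug not in DRUGS:
        raise ValueError(
            f"unknown drug {drug!r}; available: "
            f"{sorted(DRUGS) + ['ica105574']}")
    return params.scaled(DRUGS[drug])


def undo_drug(params: Params, drug: str) -> Params:
    """Inverse of :func:`apply_drug` (exact, since transforms are scalings)."""
    drug = drug.lower().replace("-", "")
    if drug == "ica105574":
        return params.replace(
            gkr=params.gkr / ICA_SCALE_GKR,
            ikr_inact_shift=params.ikr_inact_shift - ICA_INACT_SHIFT,
            ikr_act_shift=params.ikr_act_shift - ICA_ACT_SHIFT)
    if drug not in DRUGS:
        raise ValueError(f"unknown drug {drug!r}")
    return params.scaled({k: 1.0 / v for k, v in DRUGS[drug].items()})


def gene_therapy(params: Params, desired_silencing_wt: float,
                 desired_silencing_ts1: float,
                 therapy_on: int = 1) -> Params:
    """LTCC gene silencing with allele-variable specificity."""
    aw, at = ltcc.active_fractions(desired_silencing_wt,
                                   desired_silencing_ts1, therapy_on)
    return params.replace(active_wt=aw, active_ts1=at)


def camkii_inhibition(params: Params, km_multiplier: float = 1000.0) -> Params:
    """CaMKII inhibition via a fold-increase of its Ca2+ sensing K_m."""
    if km_multiplier <= 0:
        raise ValueError("km_multiplier must be positive")
    return params.replace(camk_km_mult=params.camk_km_mult * km_multiplier)


def block_inal(params: Params, fraction: float = 0.95) -> Params:
    """Selective late Na+ current blockade by the given fraction."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("block fraction must lie in [0, 1]")
    return params.replace(gnal=params.gnal * (1.0 - fraction))


def shift_ltcc_activation(params: Params, shift_mv: float) -> Params:
    """Shift the LTCC voltage-dependent activation (negative = leftward)."""
    return params.replace(act_shift=params.act_shift + shift_mv)


def slow_hl_gate(params: Params, tau_ms: float) -> Params:
    """Override the hL inactivation time constant of I_NaL (at 37 degC)."""
    if tau_ms <= 0:
        raise ValueError("tau must be positive")
    return params.replace(thl=tau_ms)


# ----------------------------------------------------------------------
# quantitative endpoints


def _apd90(params: Params, freq_hz: float, y0=None, n_beats=40,
           **run_kw) -> float:
    period = 1000.0 / freq_hz
    p = params.replace(stim_period=period)
    if y0 is None:
        y0 = model.initial_state(p)
    tr = model.run(p, n_beats=n_beats, y0=y0, record_beats=3, **run_kw)
    return biomarkers.extract(tr, beats=2).apd90


def quantify_prolongation_share(apd90_ts1: float, apd90_blocked: float,
                                apd90_wt: float) -> float:
    """Percent of TS1 AP prolongation attributable to the blocked current.

    share = 100 * (APD90_TS1 - APD90_TS1+block) / (APD90_TS1 - APD90_WT)
    at matched steady-state pacing.
    """
    denom = apd90_ts1 - apd90_wt
    if denom == 0:
        raise ZeroDivisionError("TS1 and WT APD90 coincide")
    return 100.0 * (apd90_ts1 - apd90_blocked) / denom


def inal_share_of_prolongation(wt: Params, ts1: Params, freq_hz: float,
                               block_fraction: float = 0.95,
                               y0_wt=None, y0_ts1=None, n_beats=40,
                               **run_kw) -> float:
    """Run WT / TS1 / TS1+I_NaL-block to steady pacing and report the share."""
    blocked = block_inal(ts1, block_fraction)
    a_wt = _apd90(wt, freq_hz, y0=y0_wt, n_beats=n_beats, **run_kw)
    a_ts = _apd90(ts1, freq_hz, y0=y0_ts1, n_beats=n_beats, **run_kw)
    a_bl = _apd90(blocked, freq_hz, y0=y0_ts1, n_beats=n_beats, **run_kw)
    return quantify_prolongation_share(a_ts, a_bl, a_wt)


def ead_provocation(params: Params, freq_hz: float = 0.5, y0=None,
                    n_beats=30, record_beats=8, **run_kw):
    """Pace with the provocation applied; return (trajectory, events)."""
    p = params.replace(stim_period=1000.0 / freq_hz)
    if y0 is None:
        y0 = model.initial_state(p)
    tr = model.run(p, n_beats=n_beats, y0=y0, record_beats=record_beats,
                   **run_kw)
    return tr, biomarkers.detect_events(tr)


def scan_threshold(make_params, values, freq_hz: float = 0.5,
                   flag: str = "ead", y0=None, n_beats=30, **run_kw):
    """First value of a scanned knob at which an event flag fires.

    ``make_params(value)`` builds the parameter set for each scanned value
    (scanned in the given order).  Returns (threshold_value, results);
    threshold is None if the flag never fires.
    """
    results = {}
    for val in values:
        _, ev = ead_provocation(make_params(val), freq_hz, y0=y0,
                                n_beats=n_beats, **run_kw)
        if flag == "2:1":
            hit = ev["capture_ratio"] == "2:1"
        else:
            hit = bool(ev[flag])
        results[val] = ev
        if hit:
            return val, results
    return None, results


def therapy_score(bm_treated, bm_ts1, bm_wt,
                  fields=("apd90", "dvdt_max")) -> float:
    """Scalar distance-to-WT metric, mean over phenotype axes of
    |treated - WT| / |TS1 - WT| (0 = full rescue, 1 = untreated TS1)."""
    scores = []
    for f in fields:
        denom = abs(getattr(bm_ts1, f) - getattr(bm_wt, f))
        if denom < 1e-12:
            continue
        scores.append(abs(getattr(bm_treated, f) - getattr(bm_wt, f))
                      / denom)
    return float(np.mean(scores))
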