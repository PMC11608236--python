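import numpy as np
import pytest

from swinecell import constants as c
from swinecell import interventions as iv
from swinecell.params import wild_type
from swinecell.rhs import rhs_full

_EMPTY = np.zeros(2)


def _currents_at(params, y):
    _, cur = rhs_full(0.0, y, params.to_vector(), 1.0, _EMPTY, _EMPTY)
    return cur


def _probe_state(v=0.0):
    from swinecell.model import initial_state
    y = initial_state()
    y[c.S_V] = v
    y[c.S_XS1] = 0.7
    y[c.S_XS2] = 0.8
    y[c.S_ATO2] = 0.5
    y[c.S_ITO2CA] = 0.5
    return y


def test_zero_fraction_is_wild_type():
    assert iv.make_ts1(wild_type(), 0.0) == wild_type().replace(frac_ts1=0.0)


def test_fraction_bounds():
    with pytest.raises(ValueError):
        iv.make_ts1(wild_type(), 1.2)


def test_gks_remodeling_linear_form():
    """At the reference 22 % mutant load with fully active TS1 channels,
    G_Ks,TS1 = 0.6 x G_Ks,WT; the factor relaxes linearly with silencing."""
    y = _probe_state(0.0)
    wt = wild_type()
    i_wt = _currents_at(wt, y)[c.C_IKS]
    i_ts = _currents_at(iv.make_ts1(wt, 0.22), y)[c.C_IKS]
    assert i_ts / i_wt == pytest.approx(0.6, rel=1e-9)
    # fully silenced mutants remove the remodeling
    silenced = iv.gene_therapy(iv.make_ts1(wt, 0.22), 0.0, 1.0, 1)
    i_sil = _currents_at(silenced, y)[c.C_IKS]
    assert i_sil / i_wt == pytest.approx(1.0, rel=1e-9)
    # remodeling switch off
    i_off = _currents_at(iv.make_ts1(wt, 0.22, remodeling=False), y)[c.C_IKS]
    assert i_off / i_wt == pytest.approx(1.0, rel=1e-9)


def test_ito2_remodeling_shift_and_conductance():
    wt = wild_type()
    ts1 = iv.make_ts1(wt, 0.22)
    # with the gates pinned, only the 5 % conductance term differs
    y = _probe_state(20.0)
    i_wt = _currents_at(wt, y)[c.C_ITO2]
    i_ts = _currents_at(ts1, y)[c.C_ITO2]
    assert i_ts / i_wt == pytest.approx(0.95, rel=1e-9)


@pytest.mark.parametrize("drug,scalings", sorted(iv.DRUGS.items()))
def test_drug_scalings_verbatim(drug, scalings):
    wt = wild_type()
    treated = iv.apply_drug(wt, drug)
    for name, fac in scalings.items():
        assert getattr(treated, name) == pytest.approx(
            getattr(wt, name) * fac)
    # all other parameters untouched
    for name in c.PARAM_NAMES:
        if name not in scalings:
            assert getattr(treated, name) == getattr(wt, name)


def test_ica105574_gate_shifts():
    wt = wild_type()
    treated = iv.apply_drug(wt, "ICA-105574")
    assert treated.gkr == pytest.approx(wt.gkr * 2.277)
    assert treated.ikr_inact_shift == pytest.approx(42.0)
    assert treated.ikr_act_shift == pytest.approx(-11.0)


@pytest.mark.parametrize("drug", ["verapamil", "ranolazine", "mexiletine",
                                  "ica105574"])
def test_drug_undo_restores_parameters(drug):
    wt = wild_type()
    back = iv.undo_drug(iv.apply_drug(wt, drug), drug)
    for name in c.PARAM_NAMES:
        assert getattr(back, name) == pytest.approx(
            getattr(wt, name), rel=1e-12)


def test_unknown_drug_lists_available():
    with pytest.raises(ValueError, match="verapamil"):
        iv.apply_drug(wild_type(), "aspirin")


def test_gene_therapy_noop_and_camk_inhibition():
    wt = wild_type()
    assert iv.gene_therapy(wt, 0.0, 0.0, 1) == wt
    inhib = iv.camkii_inhibition(wt)
    assert inhib.camk_km_mult == pytest.approx(1000.0)
    assert iv.camkii_inhibition(wt, 2.0).camk_km_mult == pytest.approx(2.0)


def test_block_inal_scaling_and_share_formula():
    wt = wild_type()
    assert iv.block_inal(wt, 0.95).gnal == pytest.approx(0.05 * wt.gnal)
    assert iv.block_inal(wt, 0.0) == wt.replace(gnal=wt.gnal)
    # zero block -> zero share
    assert iv.quantify_prolongation_share(400.0, 400.0, 300.0) == 0.0
    assert iv.quantify_prolongation_share(400.0, 350.0, 300.0) == \
        pytest.approx(50.0)
    with pytest.raises(ZeroDivisionError):
        iv.quantify_prolongation_share(300.0, 250.0, 300.0)


def test_intervention_composition():
    wt = wild_type()
    p = iv.apply_drug(iv.gene_therapy(iv.make_ts1(wt), 0.25, 0.75, 1),
                      "verapamil")
    assert p.frac_ts1 == 0.22
    assert (p.active_wt, p.active_ts1) == (0.75, 0.25)
    assert p.pca == pytest.approx(wt.pca * 0.64)
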