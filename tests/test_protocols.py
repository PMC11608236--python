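import numpy as np
import pytest

import swinecell as sc
from swinecell import biomarkers as bm
from swinecell import protocols as pr

from conftest import RUN_KW


def _synthetic_family():
    t = np.arange(0.0, 100.0, 0.5)
    voltages = np.array([-20.0, 0.0, 20.0])
    i = np.vstack([a * (np.exp(-t / 40.0) - np.exp(-t / 2.0))
                   for a in (-1.0, -3.0, -2.0)])
    prot = pr.ClampProtocol(sweeps=tuple(voltages), test_duration=100.0)
    return pr.SweepFamily(voltages=voltages, t=t, i=i, current="ical",
                          protocol=prot)


def test_frc_is_one_at_the_peak_for_every_voltage():
    fam = _synthetic_family()
    _, frc = fam.frc()
    assert np.allclose(np.max(np.abs(frc), axis=1), 1.0)
    ipk = np.argmax(np.abs(fam.i), axis=1)
    for k, j in enumerate(ipk):
        assert frc[k, j] == pytest.approx(1.0)


def test_peak_iv_and_activation_normalization():
    fam = _synthetic_family()
    v, pk = fam.peak_iv()
    assert pk[1] == fam.i[1].min()
    va, act = fam.activation_curve()
    assert act.max() == pytest.approx(1.0)
    assert np.argmax(act) == 1


def test_clamp_refuses_unisolatable_current(wt):
    with pytest.raises(ValueError, match="isolated"):
        pr.voltage_clamp(wt, pr.ClampProtocol(sweeps=(0.0,)), "inaca_i")


def test_clamp_protocol_validation():
    with pytest.raises(ValueError):
        pr.ClampProtocol(test_duration=-1.0)
    with pytest.raises(ValueError):
        pr.ClampProtocol(temperature=30.0)


def test_availability_matches_gate_closed_form(wt):
    """The availability protocol on the late Na+ current reproduces the
    closed-form relaxation of its two gates (mL, hL) to ~0.1 %.

    With CaMKII disabled the clamped gate subsystem is linear per segment,
    so the normalized peak currents follow from the analytic exponential
    relaxations alone - an oracle independent of the ODE solver.
    """
    p = wt.replace(camk_o=0.0)
    prepulses = np.array([-120.0, -105.0, -95.0, -85.0, -75.0, -60.0])
    v_test, t_pre, thl = -30.0, 1000.0, p.thl

    def hlss(v):
        return 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))

    def mlss(v):
        return 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))

    def tm(v):
        return 1.0 / (6.765 * np.exp((v + 11.64) / 34.77)
                      + 8.552 * np.exp(-(v + 77.42) / 5.955))

    tt = np.arange(0.05, 50.0, 0.05)
    expected = []
    for vp in prepulses:
        h1 = hlss(vp) + (hlss(-120.0) - hlss(vp)) * np.exp(-t_pre / thl)
        m1 = mlss(vp) + (mlss(-120.0) - mlss(vp)) * np.exp(-t_pre / tm(vp))
        h_t = hlss(v_test) + (h1 - hlss(v_test)) * np.exp(-tt / thl)
        m_t = mlss(v_test) + (m1 - mlss(v_test)) * np.exp(-tt / tm(v_test))
        expected.append(np.max(m_t * h_t))
    expected = np.asarray(expected)
    expected /= expected.max()

    v, avail = pr.availability_curve(p, "inal", prepulses, v_test,
                                     prepulse_duration=t_pre,
                                     holding=-120.0, test_duration=50.0,
                                     dt=0.05)
    assert np.max(np.abs(avail - expected)) < 2e-3


def test_ripple_spec_validation_and_zero_magnitude(ts1, ts1_steady_05):
    with pytest.raises(ValueError):
        pr.RippleSpec(latency=-1.0)
    spec = pr.RippleSpec(latency=150.0, freq=0.01, magnitude=0.0,
                         duration=300.0)
    p0 = ts1.replace(stim_period=2000.0)
    p1 = pr.impose_ripples(p0, spec)
    tr0 = sc.run(p0, n_beats=2, y0=ts1_steady_05, record_beats=2, **RUN_KW)
    tr1 = sc.run(p1, n_beats=2, y0=ts1_steady_05, record_beats=2, **RUN_KW)
    assert np.max(np.abs(tr0.v - tr1.v)) < 1e-9


def test_ripples_modulate_release(ts1, ts1_steady_05):
    spec = pr.RippleSpec(latency=200.0, freq=0.01, magnitude=1.5,
                         duration=600.0)
    p = pr.impose_ripples(ts1.replace(stim_period=2000.0), spec)
    tr0 = sc.run(ts1.replace(stim_period=2000.0), n_beats=1,
                 y0=ts1_steady_05, record_beats=1, with_currents=True,
                 **RUN_KW)
    tr1 = sc.run(p, n_beats=1, y0=ts1_steady_05, record_beats=1,
                 with_currents=True, **RUN_KW)
    tb = tr1.t % 2000.0
    pre = tb < 180.0
    post = (tb > 220.0) & (tb < 800.0)
    jrel0, jrel1 = tr0.current("jrel"), tr1.current("jrel")
    assert np.allclose(jrel0[pre], jrel1[pre], atol=1e-6)
    assert np.max(np.abs(jrel0[post] - jrel1[post])) > 1e-4


def test_ap_clamp_self_consistency(wt, wt_steady_05):
    """A WT cell clamped to its own steady-state AP reproduces the
    free-running jSR Ca2+ and CaT amplitude within 2 %."""
    p = wt.replace(stim_period=2000.0)
    free = sc.run(p, n_beats=5, y0=wt_steady_05, record_beats=2, **RUN_KW)
    m = free.t >= free.beat_starts[-1]
    wave_t = free.t[m] - free.beat_starts[-1]
    wave_v = free.v[m]
    clamped = pr.ap_clamp(p, wave_t, wave_v, n_beats=8, record_beats=2,
                          y0=wt_steady_05, **RUN_KW)
    jsr_free = free.state("cajsr")[m].min()
    jsr_cl = clamped.state("cajsr")[clamped.t >= clamped.beat_starts[-1]]
    assert jsr_cl.min() == pytest.approx(jsr_free, rel=0.02)
    cat_free = free.cai[m].max() - free.cai[m].min()
    mc = clamped.t >= clamped.beat_starts[-1]
    cat_cl = clamped.cai[mc].max() - clamped.cai[mc].min()
    assert cat_cl == pytest.approx(cat_free, rel=0.02)


def test_ap_clamp_rejects_short_waveform(wt):
    with pytest.raises(ValueError, match="shorter"):
        pr.ap_clamp(wt, np.arange(0.0, 500.0, 0.1),
                    np.zeros(5000), n_beats=1)


def test_s1s2_restitution_structure(wt, wt_steady_1):
    res = pr.s1s2_restitution(
        wt, s1_freq=1.0, n_s1=21, y0=wt_steady_1,
        di_values=np.array([20.0, 60.0, 150.0, 400.0, 900.0]), **RUN_KW)
    assert len(res["di"]) >= 4
    # non-decreasing APD90 with diastolic interval
    assert np.all(np.diff(res["apd90"]) >= -0.5)
    # self-consistency: an S2 timed exactly like an S1 (DI = period -
    # APD90) reproduces the steady-state APD90
    di_native = 1000.0 - res["apd90_s1"]
    res2 = pr.s1s2_restitution(wt, s1_freq=1.0, n_s1=21, y0=wt_steady_1,
                               di_values=np.array([di_native]), **RUN_KW)
    assert res2["apd90"][0] == pytest.approx(res["apd90_s1"], abs=2.0)


def test_diastolic_threshold_and_margin(wt, wt_steady_1):
    thr = pr.find_diastolic_threshold(wt, 1.0, y0=wt_steady_1, tol=1.0)
    assert 1.0 < thr < 36.0
    p = pr.calibrate_stimulus(wt, 1.0, y0=wt_steady_1, tol=1.0)
    assert p.stim_amp == pytest.approx(-1.25 * thr, rel=0.3)
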