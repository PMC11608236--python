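import numpy as np
import pytest

from swinecell import biomarkers as bm
from swinecell.model import Trajectory
from swinecell.params import wild_type

from conftest import triangle_ap


def _traj_from_v(t, v, cai=None, period=1000.0, n_beats=None):
    p = wild_type().replace(stim_period=period)
    y = np.zeros((len(t), 61))
    y[:, 0] = v
    y[:, 5] = 1e-4 if cai is None else cai
    if n_beats is None:
        n_beats = int(round((t[-1] - t[0] + t[1] - t[0]) / period))
    starts = t[0] + period * np.arange(n_beats)
    return Trajectory(t=t, y=y, params=p, beat_starts=starts)


def test_triangle_ap_closed_form():
    """Instant rise -85 -> +35 mV with a 300 ms linear fall: APA = 120 mV
    and APD90 = 0.9 * 300 = 270 ms."""
    t, v = triangle_ap()
    res = bm.extract(_traj_from_v(t, v), beats=2)
    assert res.apa == pytest.approx(120.0, abs=0.5)
    assert res.apd90 == pytest.approx(270.0, abs=1.5)
    assert res.apd50 == pytest.approx(150.0, abs=1.5)
    assert res.apd20 == pytest.approx(60.0, abs=1.5)
    assert res.apd20 <= res.apd50 <= res.apd90
    assert res.rmp == pytest.approx(-85.0, abs=0.1)
    assert res.capture_ratio == "1:1"
    assert not res.ead


def test_constant_trace_flags_capture_failure():
    t = np.arange(0.0, 3000.0, 0.5)
    v = np.full_like(t, -85.0)
    res = bm.extract(_traj_from_v(t, v))
    assert res.capture_ratio == "failure"
    assert np.isnan(res.apd90)


def test_alternating_capture_is_2_to_1():
    t, v = triangle_ap(n_beats=6)
    period = 1000.0
    drop = (t % (2 * period)) >= period      # every second beat fails
    v = np.where(drop, -85.0, v)
    res = bm.extract(_traj_from_v(t, v, n_beats=6))
    assert res.capture_ratio == "2:1"


def test_time_shift_invariance():
    t, v = triangle_ap(n_beats=3)
    a = bm.extract(_traj_from_v(t, v), beats=2)
    shift = 40000.0
    b = bm.extract(_traj_from_v(t + shift, v, period=1000.0), beats=2)
    for f in ("apd90", "apa", "rmp", "apd20"):
        assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-9)


def test_apd_alternans_detection():
    parts = []
    for k in range(8):
        fall = 320.0 if k % 2 == 0 else 250.0
        tt, vv = triangle_ap(fall_ms=fall, n_beats=1)
        parts.append(vv)
    t = np.arange(0.0, 8000.0, 0.1)
    v = np.concatenate(parts)
    res = bm.extract(_traj_from_v(t, v, n_beats=8))
    assert res.alternans
    t2, v2 = triangle_ap(n_beats=8)
    assert not bm.extract(_traj_from_v(t2, v2, n_beats=8)).alternans


def test_ead_bump_detected_and_dome_excluded():
    """A depolarizing bump during late repolarization is an EAD; the
    physiological notch-dome redevelopment right after the spike is not."""
    t, v = triangle_ap(n_beats=2)
    tb = t % 1000.0
    bump = (tb > 180) & (tb < 230)
    v_ead = v + np.where(bump, 25.0 * np.sin(
        np.pi * (tb - 180) / 50.0), 0.0)
    assert bm.extract(_traj_from_v(t, v_ead), beats=2).ead
    # dome-like rise immediately after the spike is not flagged
    dome = (tb > 20) & (tb < 70)
    v_dome = v + np.where(dome, 15.0 * np.sin(
        np.pi * (tb - 20) / 50.0), 0.0)
    assert not bm.extract(_traj_from_v(t, v_dome), beats=2).ead


def test_cat_features_on_synthetic_transient():
    period = 1000.0
    t = np.arange(0.0, 2 * period, 0.5)
    tb = t % period
    base, amp = 1e-4, 4e-4
    tau_rise, tau_dec = 15.0, 80.0
    cai = base + amp * np.where(
        tb < 500, (1 - np.exp(-tb / tau_rise)) * np.exp(-tb / tau_dec), 0.0)
    tt, v = triangle_ap(n_beats=2, dt=0.5)
    res = bm.extract(_traj_from_v(t, v, cai=cai), beats=1)
    # model units are 1e-4 mM
    peak = np.max(cai) - base
    assert res.cat_amp == pytest.approx(peak * 1e4, rel=0.02)
    assert 0 < res.cat_ttp < 100
    assert res.cat_fdhm < 500
    assert res.cat_decay90 > res.cat_fdhm / 2


def test_extract_requires_recorded_beats():
    t, v = triangle_ap(n_beats=2)
    with pytest.raises(ValueError, match="2"):
        bm.extract(_traj_from_v(t, v), beats=5)
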