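import numpy as np
import pytest

import swinecell as sc
from swinecell import constants as c
from swinecell.model import SimulationError, compute_currents

from conftest import RUN_KW


def test_state_vector_has_61_variables():
    assert c.N_STATES == 61
    assert len(set(c.STATE_NAMES)) == 61
    y = sc.initial_state()
    assert y.shape == (61,)
    d = sc.derivatives(0.0, y, sc.wild_type())
    assert d.shape == (61,)
    assert np.all(np.isfinite(d))


def test_derivatives_name_offending_variable():
    p = sc.wild_type()
    y = sc.initial_state()
    y[c.S_CAJSR] = np.nan
    with pytest.raises(ValueError, match="cajsr"):
        sc.derivatives(0.0, y, p)
    y = sc.initial_state()
    y[c.S_KI] = -1.0
    with pytest.raises(ValueError, match="ki"):
        sc.derivatives(0.0, y, p)


def test_markov_occupancy_derivatives_sum_to_zero():
    """The occupancy derivatives of every LTCC loop sum to zero exactly
    (generator property), so total occupancy is conserved."""
    p = sc.wild_type().replace(frac_ts1=0.22)
    y = sc.initial_state()
    rng = np.random.default_rng(0)
    for off in c.LTCC_BLOCKS:
        occ = rng.dirichlet(np.ones(4))
        y[off:off + 4] = occ
        y[off + 4:off + 8] = rng.dirichlet(np.ones(4))
    y[c.S_V] = 1.5
    d = sc.derivatives(0.0, y, p)
    for off in c.LTCC_BLOCKS:
        assert abs(d[off:off + 4].sum()) < 1e-15
        assert abs(d[off + 4:off + 8].sum()) < 1e-15


def test_resting_fixed_point(wt):
    """From a long unpaced relaxation the derivative norm is tiny."""
    y = sc.steady_state("wt", 0.5)
    p = wt.replace(stim_amp=0.0)
    tr = sc.run(p, protocol="free-running", duration=120000.0,
                y0=y, record_beats=1, **RUN_KW)
    d = sc.derivatives(0.0, tr.y[-1], p)
    # scale-aware: V in mV/ms, gates 1/ms, concentrations mM/ms
    assert np.max(np.abs(d)) < 2e-4


def test_camk_active_contract():
    p = sc.wild_type()
    y = sc.initial_state()
    y[c.S_CASS] = 0.0
    y[c.S_CAMKT] = 0.0
    assert sc.camk_active(y, p) == 0.0
    # monotone in subspace Ca2+
    vals = []
    for ca in (1e-5, 1e-4, 1e-3, 1e-2):
        y[c.S_CASS] = ca
        vals.append(sc.camk_active(y, p))
    assert all(a < b for a, b in zip(vals, vals[1:]))
    assert 0.0 <= vals[-1] <= 1.0
    # 1000-fold Km increase silences it at physiological Ca2+
    y[c.S_CASS] = 2e-4
    inhibited = sc.camk_active(y, p.replace(camk_km_mult=1000.0))
    assert inhibited < 0.01 * sc.camk_active(y, p)


def test_run_rejects_nonpositive_duration(wt):
    with pytest.raises(ValueError):
        sc.run(wt, duration=0.0)
    with pytest.raises(ValueError):
        sc.run(wt, n_beats=0)


def test_gates_bounded_and_occupancy_conserved(wt_traj):
    y = wt_traj.y
    gate_idx = [c.STATE_NAMES.index(n) for n in
                ("m", "hf", "hs", "j", "hsp", "jp", "ml", "hl", "hlp",
                 "ato2", "ito2ca", "xrf", "xrs", "xs1", "xs2", "xk1")]
    g = y[:, gate_idx]
    assert g.min() >= -1e-9 and g.max() <= 1.0 + 1e-9
    for off in c.LTCC_BLOCKS:
        for loop in (slice(off, off + 4), slice(off + 4, off + 8)):
            s = y[:, loop].sum(axis=1)
            assert np.max(np.abs(s - 1.0)) < 1e-6


def test_charge_balance_along_trajectory(wt_traj):
    """Away from the stimulus, Cm dV/dt + sum(I_ion) = 0."""
    t, v = wt_traj.t, wt_traj.v
    cur = wt_traj.currents
    ion_idx = [i for i, n in enumerate(c.CURRENT_NAMES)
               if n not in ("istim", "jrel", "jup", "camka")]
    itot = cur[:, ion_idx].sum(axis=1) + cur[:, c.C_ISTIM]
    dvdt = np.gradient(v, t)
    tb = t % wt_traj.params.stim_period
    interior = (tb > 6.0) & (tb < wt_traj.params.stim_period - 2.0)
    err = np.abs(dvdt + itot)[interior]
    # finite-difference dV/dt limits the agreement on the upstroke;
    # compare on the 99th percentile to be robust to grid effects
    assert np.quantile(err, 0.99) < 0.5
    assert np.median(err) < 0.02


def test_steady_state_idempotence(wt, wt_steady_1):
    """Restarting from a stored steady state reproduces the same beat."""
    tr = sc.run(wt, n_beats=2, y0=wt_steady_1, record_beats=2, **RUN_KW)
    period = wt.stim_period
    m1 = tr.t < period
    v1 = tr.v[m1]
    v2 = np.interp(tr.t[m1] + period, tr.t, tr.v)
    assert np.max(np.abs(v1 - v2)) < 0.1


def test_currents_computed_on_demand(wt, wt_steady_1):
    tr = sc.run(wt, n_beats=1, y0=wt_steady_1, record_beats=1, **RUN_KW)
    assert tr.currents is None
    ina = tr.current("ina")
    assert tr.currents is not None
    ref = compute_currents(tr.t, tr.y, wt)
    assert np.allclose(ina, ref[:, c.C_INA])


def test_solver_failure_reports_cleanly(wt):
    """A parameter set that overflows the rate expressions either raises
    SimulationError (with a last-valid-time) or is caught by the state
    admissibility check - it never returns silently corrupted output."""
    bad = wt.replace(gna=1e8, gkr=1e6)
    try:
        tr = sc.run(bad, n_beats=3, record_beats=1, **RUN_KW)
    except SimulationError as err:
        assert err.last_valid_time is None or np.isfinite(err.last_valid_time)
    except ValueError:
        pass
    else:
        assert np.all(np.isfinite(tr.y))
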