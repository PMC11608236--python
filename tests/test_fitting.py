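import numpy as np
import pytest

from swinecell import fitting
from swinecell.fixtures import availability_fixture, boltzmann
from swinecell.model import SimulationError


class GateParams:
    """Analytic two-parameter Boltzmann gate used as a fitting stand-in."""

    def __init__(self, vhalf, k):
        self.vhalf = vhalf
        self.k = k

    def replace(self, **kw):
        return GateParams(kw.get("vhalf", self.vhalf), kw.get("k", self.k))


def _availability_sim(v):
    def simulate(p, _target):
        return 1.0 - boltzmann(v, p.vhalf, p.k)
    return simulate


def test_cost_single_pair_arithmetic():
    tg = fitting.FitTarget(label="x", kind="iv", values=np.array([1.0]),
                           weight=3.0)
    val = fitting.cost(None, [tg], lambda p, t: np.array([2.0]))
    assert val == pytest.approx(3.0)          # 3 * (2 - 1)^2


def test_cost_zero_iff_exact_match_and_weights():
    rng = np.random.default_rng(0)
    y = rng.normal(size=7)
    tg1 = fitting.FitTarget("a", "iv", y, weight=1.0)
    assert fitting.cost(None, [tg1], lambda p, t: y) == 0.0
    # weighted cost equals unweighted when all weights are 1
    tg_list = [fitting.FitTarget(f"t{i}", "iv", y + i, weight=1.0)
               for i in range(3)]
    c_w = fitting.cost(None, tg_list, lambda p, t: y)
    c_manual = sum(np.sum((y - t.values) ** 2) for t in tg_list)
    assert c_w == pytest.approx(c_manual)


def test_cost_rejects_bad_weight_and_nonfinite_targets():
    with pytest.raises(ValueError):
        fitting.FitTarget("w", "iv", np.array([1.0]), weight=0.0)
    with pytest.raises(ValueError):
        fitting.FitTarget("n", "iv", np.array([np.nan]))


def test_failed_simulation_yields_large_finite_penalty():
    tg = fitting.FitTarget("x", "iv", np.array([1.0]))

    def boom(p, t):
        raise SimulationError("diverged", last_valid_time=-3.0)

    val = fitting.cost(None, [tg], boom)
    assert np.isfinite(val)
    assert val >= fitting.FAIL_PENALTY


def test_boltzmann_parameter_recovery():
    """Nelder-Mead recovers (V1/2 = -80, k = 6) from noiseless synthetic
    availability data to better than 1 % from a perturbed start."""
    fx = availability_fixture(seed=0, vhalf=-80.0, k=6.0, noise_sd=0.0)
    v = fx["v_mv"].to_numpy()
    tg = fitting.FitTarget("avail", "availability",
                           fx["value"].to_numpy())
    res = fitting.fit_gating(GateParams(-65.0, 9.0), [tg],
                             _availability_sim(v), ["vhalf", "k"],
                             bounds={"vhalf": (-150.0, -10.0),
                                     "k": (1.0, 30.0)},
                             max_iter=400)
    assert abs(res.params.vhalf - (-80.0)) / 80.0 < 0.01
    assert abs(res.params.k - 6.0) / 6.0 < 0.01
    assert res.cost <= res.initial_cost


def test_self_target_start_is_stable():
    fx = availability_fixture(seed=1, vhalf=-80.0, k=6.0, noise_sd=0.0)
    v = fx["v_mv"].to_numpy()
    tg = fitting.FitTarget("avail", "availability", fx["value"].to_numpy())
    res = fitting.fit_gating(GateParams(-80.0, 6.0), [tg],
                             _availability_sim(v), ["vhalf", "k"],
                             bounds={"vhalf": (-150.0, -10.0),
                                     "k": (1.0, 30.0)})
    assert res.cost <= 1e-12
    assert abs(res.params.vhalf + 80.0) < 0.2
    assert abs(res.params.k - 6.0) < 0.2


def test_fit_independent_of_vary_ordering():
    fx = availability_fixture(seed=2, vhalf=-75.0, k=5.0, noise_sd=0.005)
    v = fx["v_mv"].to_numpy()
    tg = fitting.FitTarget("avail", "availability", fx["value"].to_numpy())
    kw = dict(bounds={"vhalf": (-150.0, -10.0), "k": (1.0, 30.0)},
              max_iter=400)
    r1 = fitting.fit_gating(GateParams(-60.0, 8.0), [tg],
                            _availability_sim(v), ["vhalf", "k"], **kw)
    r2 = fitting.fit_gating(GateParams(-60.0, 8.0), [tg],
                            _availability_sim(v), ["k", "vhalf"], **kw)
    assert r1.params.vhalf == pytest.approx(r2.params.vhalf, abs=0.05)
    assert r1.params.k == pytest.approx(r2.params.k, abs=0.05)


def test_duplicate_vary_rejected():
    with pytest.raises(ValueError):
        fitting.fit_gating(GateParams(-60, 8), [], lambda p, t: None,
                           ["k", "k"])


def test_perturbed_vhalf_has_positive_cost():
    fx = availability_fixture(seed=3, vhalf=-80.0, k=6.0, noise_sd=0.0)
    v = fx["v_mv"].to_numpy()
    tg = fitting.FitTarget("avail", "availability", fx["value"].to_numpy())
    sim = _availability_sim(v)
    assert fitting.cost(GateParams(-80.0, 6.0), [tg], sim) < 1e-20
    assert fitting.cost(GateParams(-75.0, 6.0), [tg], sim) > 1e-3
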