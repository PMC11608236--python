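import numpy as np
import pytest

import swinecell as sc
from swinecell import interventions as iv

# solver settings for desk-scale test simulations (the library default is
# the much tighter production setting)
RUN_KW = dict(rtol=1e-7, atol=1e-9)


@pytest.fixture(scope="session")
def wt():
    return sc.wild_type()


@pytest.fixture(scope="session")
def ts1(wt):
    return iv.make_ts1(wt)


@pytest.fixture(scope="session")
def wt_steady_05():
    return sc.steady_state("wt", 0.5)


@pytest.fixture(scope="session")
def wt_steady_1():
    return sc.steady_state("wt", 1.0)


@pytest.fixture(scope="session")
def ts1_steady_05():
    return sc.steady_state("ts1", 0.5)


@pytest.fixture(scope="session")
def wt_traj(wt, wt_steady_1):
    """Short 1 Hz steady-pacing trajectory reused by several tests."""
    return sc.run(wt, n_beats=6, y0=wt_steady_1, record_beats=6,
                  with_currents=True, **RUN_KW)


def triangle_ap(rmp=-85.0, peak=35.0, fall_ms=300.0, period=1000.0,
                dt=0.1, n_beats=3, stim_offset=0.0):
    """Piecewise-linear AP train: instant rise, linear fall, flat rest."""
    t = np.arange(0.0, n_beats * period, dt)
    tb = t % period
    v = np.full_like(t, rmp)
    rise = 1.0                       # 1 ms ramp stands in for instant rise
    m_up = (tb >= stim_offset) & (tb < stim_offset + rise)
    v[m_up] = rmp + (peak - rmp) * (tb[m_up] - stim_offset) / rise
    m_fall = (tb >= stim_offset + rise) & (tb < stim_offset + rise + fall_ms)
    v[m_fall] = peak - (peak - rmp) * (tb[m_fall] - stim_offset - rise) \
        / fall_ms
    return t, v
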