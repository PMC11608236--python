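"""Model core: state handling, derivative evaluation and simulation runs.

The cell is integrated with LSODA (via ``scipy.integrate.odeint``), a
stiff-capable variable-order solver, piecewise over stimulus segments so
the rectangular pulse never crosses an integration interval.  Default
tolerances are rtol 1e-10 / atol 1e-11 with a 1 ms maximum step; callers
may relax them for large parameter scans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.integrate import odeint

from . import constants as c
from .params import Params
from .rhs import rhs, rhs_full

_EMPTY = np.zeros(2)


class SimulationError(RuntimeError):
    """Integration failure; carries the last valid time reached."""

    def __init__(self, msg: str, last_valid_time: float | None = None):
        super().__init__(msg)
        self.last_valid_time = last_valid_time


@dataclass
class Trajectory:
    """Time-stamped record of one simulation."""

    t: np.ndarray                      # ms
    y: np.ndarray                      # (n, 61)
    params: Params
    currents: np.ndarray | None = None   # (n, N_CURRENTS), A/F
    beat_starts: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def state(self, name: str) -> np.ndarray:
        return self.y[:, c.STATE_NAMES.index(name)]

    def current(self, name: str) -> np.ndarray:
        if self.currents is None:
            self.currents = compute_currents(self.t, self.y, self.params)
        return self.currents[:, c.CURRENT_NAMES.index(name)]

    @property
    def v(self) -> np.ndarray:
        return self.y[:, c.S_V]

    @property
    def cai(self) -> np.ndarray:
        return self.y[:, c.S_CAI]

    @property
    def stim(self) -> np.ndarray:
        return self.current("istim")


def initial_state(params: Params | None = None) -> np.ndarray:
    """A quiescent starting state (all LTCC channels closed).

    This is a rough resting configuration; for steady-state work use the
    packaged paced steady states (:func:`steady_state`) or pace the model.
    """
    y = np.zeros(c.N_STATES)
    y[c.S_V] = -87.0
    y[c.S_NAI] = 7.0
    y[c.S_NASS] = 7.0
    y[c.S_KI] = 145.0
    y[c.S_KSS] = 145.0
    y[c.S_CAI] = 1.0e-4
    y[c.S_CASS] = 1.0e-4
    y[c.S_CANSR] = 1.2
    y[c.S_CAJSR] = 1.2
    y[c.S_CLI] = 29.0
    # gates at their V = -87 mV steady state (approximately)
    y[c.S_M] = 0.0074
    y[c.S_HF] = 0.70
    y[c.S_HS] = 0.70
    y[c.S_J] = 0.70
    y[c.S_HSP] = 0.45
    y[c.S_JP] = 0.70
    y[c.S_ML] = 2.0e-4
    y[c.S_HL] = 0.47
    y[c.S_HLP] = 0.26
    y[c.S_XK1] = 0.997
    for off in c.LTCC_BLOCKS:
        y[off] = 1.0      # VDI loop in C
        y[off + 4] = 1.0  # CDI loop in C
    return y


def _check_state(y: np.ndarray) -> None:
    y = np.asarray(y)
    if y.shape[-1] != c.N_STATES:
        raise ValueError(f"state must have length {c.N_STATES}")
    bad = ~np.isfinite(y)
    if bad.any():
        name = c.STATE_NAMES[int(np.nonzero(bad)[0][0])]
        raise ValueError(f"non-finite state variable: {name}")
    for idx in (c.S_NAI, c.S_NASS, c.S_KI, c.S_KSS, c.S_CAI, c.S_CASS,
                c.S_CANSR, c.S_CAJSR, c.S_CLI):
        if y[idx] <= 0:
            raise ValueError(
                f"non-positive concentration: {c.STATE_NAMES[idx]}")


def derivatives(t: float, state: np.ndarray, params: Params,
                stim=None) -> np.ndarray:
    """Time derivative of the full 61-state vector.

    ``stim`` may be a callable t -> current density (A/F) overriding the
    parameter-defined pulse train; voltage/AP clamping is selected through
    ``params.mode`` (see :mod:`swinecell.protocols`).
    """
    _check_state(state)
    params.validate()
    p = params.to_vector()
    if stim is not None:
        p[c.P_STIM_AMP] = 0.0
    dy, cur = rhs_full(t, np.asarray(state, float), p, 1.0, _EMPTY, _EMPTY)
    if stim is not None and params.mode == 0:
        s = float(stim(t))
        dy = dy.copy()
        dy[c.S_V] -= s
        dy[c.S_KI] -= s * params.acap / (c.FARADAY * 0.68 * params.vcell)
    return dy


def camk_active(state: np.ndarray, params: Params) -> float:
    """Active CaMKII fraction (bound + trapped), in [0, 1]."""
    cass = state[c.S_CASS]
    if cass < 0:
        raise ValueError("Ca_ss must be non-negative")
    km = params.km_cam * params.camk_km_mult
    if cass == 0:
        camkb = 0.0
    else:
        camkb = params.camk_o * (1.0 - state[c.S_CAMKT]) / (1.0 + km / cass)
    return float(camkb + state[c.S_CAMKT])


def compute_currents(t: np.ndarray, y: np.ndarray, params: Params,
                     wave_dt: float = 1.0, wave_v=None,
                     wave_dv=None) -> np.ndarray:
    """Evaluate all current densities along a trajectory."""
    p = params.to_vector()
    wv = _EMPTY if wave_v is None else wave_v
    wdv = _EMPTY if wave_dv is None else wave_dv
    out = np.empty((len(t), c.N_CURRENTS))
    for i in range(len(t)):
        _, cur = rhs_full(t[i], y[i], p, wave_dt, wv, wdv)
        out[i] = cur
    return out


# ----------------------------------------------------------------------
# integration


def _integrate(y0, t_eval, p, rtol, atol, hmax, wave_dt=1.0,
               wave_v=None, wave_dv=None):
    wv = _EMPTY if wave_v is None else wave_v
    wdv = _EMPTY if wave_dv is None else wave_dv
    sol, info = odeint(
        rhs, y0, t_eval, args=(p, wave_dt, wv, wdv), tfirst=True,
        rtol=rtol, atol=atol, hmax=hmax, mxstep=200000, full_output=True)
    if info["message"] != "Integration successful.":
        raise SimulationError(
            f"LSODA failed: {info['message']}",
            last_valid_time=float(info["tcur"][-1]))
    if not np.all(np.isfinite(sol[-1])):
        raise SimulationError("non-finite state during integration",
                              last_valid_time=float(t_eval[-1]))
    return sol


def _beat_grid(period, stim_dur, fine_window=20.0, dt_fine=0.05,
               dt_out=0.25):
    """Output grid for one recorded beat: dense around the upstroke."""
    a = np.arange(0.0, min(fine_window, period), dt_fine)
    b = np.arange(min(fine_window, period), period, dt_out)
    return np.concatenate([a, b])


def run(params: Params, protocol: str = "paced",
        duration: float | None = None, n_beats: int | None = None,
        y0: np.ndarray | None = None, record_beats: int = 10,
        rtol: float = 1e-10, atol: float = 1e-11, hmax: float = 1.0,
        dt_out: float = 0.25, dt_fine: float = 0.05,
        with_currents: bool = False) -> Trajectory:
    """Pace (or free-run) the cell and record the final beats densely.

    ``duration`` is in ms; alternatively give ``n_beats``.  The last
    ``record_beats`` pacing periods are sampled on a grid refined to
    ``dt_fine`` around the upstroke; the run-in is not recorded.
    """
    if protocol not in ("paced", "free-running"):
        raise ValueError("run() handles 'paced'/'free-running'; "
                         "use swinecell.protocols for clamp protocols")
    params.validate()
    period = params.stim_period
    if n_beats is None:
        if duration is None or duration <= 0:
            raise ValueError("duration must be positive")
        n_beats = int(round(duration / period))
        if n_beats < 1:
            raise ValueError("duration shorter than one pacing period")
    if n_beats <= 0:
        raise ValueError("n_beats must be positive")
    p = params.to_vector()
    if protocol == "free-running":
        p[c.P_STIM_AMP] = 0.0
    if y0 is None:
        y0 = initial_state(params)
    _check_state(y0)
    y = np.asarray(y0, dtype=float).copy()

    record_beats = min(record_beats, n_beats)
    n_runin = n_beats - record_beats
    stim_dur = params.stim_dur

    # run-in: integrate beat by beat, endpoints only
    for b in range(n_runin):
        t0 = b * period
        seg = np.array([t0, t0 + stim_dur, t0 + period])
        y = _integrate(y, seg, p, rtol, atol, hmax)[-1]

    grid = _beat_grid(period, stim_dur, dt_fine=dt_fine, dt_out=dt_out)
    ts, ys = [], []
    beat_starts = []
    for b in range(n_runin, n_beats):
        t0 = b * period
        beat_starts.append(t0)
        t_eval = np.concatenate([t0 + grid, [t0 + period]])
        # keep the stimulus edge on a grid point
        sol = _integrate(y, t_eval[t_eval <= t0 + stim_dur + 1e-9], p,
                         rtol, atol, hmax)
        n1 = sol.shape[0]
        sol2 = _integrate(sol[-1], t_eval[n1 - 1:], p, rtol, atol, hmax)
        y = sol2[-1]
        ts.append(t_eval[:-1])
        ys.append(np.vstack([sol[:-1], sol2[:-1]]))
    t_all = np.concatenate(ts + [[n_beats * period]])
    y_all = np.vstack(ys + [y[None, :]])
    traj = Trajectory(t=t_all, y=y_all, params=params,
                      beat_starts=np.asarray(beat_starts, dtype=float))
    if with_currents:
        traj.currents = compute_currents(t_all, y_all, params)
    return traj


# ----------------------------------------------------------------------
# packaged steady states


def steady_state(phenotype: str = "wt", freq_hz: float = 1.0) -> np.ndarray:
    """Packaged steady-state vector (long-run paced, shipped with the
    package like the initial conditions of published CellML models)."""
    key = f"{phenotype}_{freq_hz:g}"
    with resources.files("swinecell").joinpath(
            "data/steady_states.json").open() as fh:
        table = json.load(fh)
    if key not in table:
        raise KeyError(
            f"no packaged steady state for {key!r}; available: "
            f"{sorted(table)}")
    return np.asarray(table[key], dtype=float)


def save_steady_state_table(table: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump({k: list(map(float, v)) for k, v in table.items()}, fh,
                  indent=1)
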