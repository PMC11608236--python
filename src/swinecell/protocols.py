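"""Stimulation and clamp protocols.

Implements the simulated experiments: voltage-clamp sweep families with
derived summaries (peak I-V, activation, availability, recovery from
inactivation, fractional remaining current FRC), AP clamp with an
imposed periodic waveform, S1-S2 restitution (21-beat S1 train), the
late-systolic Ca2+-ripple imposition on the release parameter bt, and
diastolic-threshold calibration of the pacing stimulus.

Current isolation for clamp fits uses conductance masking: all other
sarcolemmal conductances are set to zero, leaving the named current as
the only charge carrier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import biomarkers
from . import constants as c
from .model import (Trajectory, _integrate, initial_state, run,
                    compute_currents)
from .params import Params

# conductance/permeability parameters zeroed to isolate each named current
_MASKABLE = ["gna", "gnal", "gkr", "gks", "gk1", "gto2", "pca", "gncx",
             "pnak", "pnab", "pcab", "gkb", "gpca", "gclb"]
_CURRENT_OF = {
    "ina": ("gna", "ina"),
    "inal": ("gnal", "inal"),
    "ikr": ("gkr", "ikr"),
    "iks": ("gks", "iks"),
    "ik1": ("gk1", "ik1"),
    "ito2": ("gto2", "ito2"),
    "ical": ("pca", "ical"),
}


@dataclass
class ClampProtocol:
    """Two-step voltage-clamp family (optional pre-pulse before the test).

    ``sweeps`` lists test-pulse voltages (mV).  For recovery protocols use
    :func:`recovery_protocol` instead.
    """

    holding: float = -80.0
    sweeps: tuple = ()
    test_duration: float = 300.0
    prepulse: float | None = None
    prepulse_duration: float = 0.0
    inter_sweep: float = 5000.0
    temperature: float = 37.0
    tail_duration: float = 0.0
    tail_voltage: float | None = None

    def __post_init__(self):
        if self.test_duration <= 0 or self.inter_sweep <= 0:
            raise ValueError("durations must be positive")
        if self.temperature not in (22.0, 36.0, 37.0):
            raise ValueError("temperature must be one of 22/36/37 degC")


@dataclass
class SweepFamily:
    """Per-sweep traces of one clamped current."""

    voltages: np.ndarray
    t: np.ndarray                     # time within test pulse (ms)
    i: np.ndarray                     # (n_sweeps, n_t) current density A/F
    current: str
    protocol: ClampProtocol

    def peak_iv(self) -> tuple[np.ndarray, np.ndarray]:
        """Peak (largest-magnitude) current per test voltage."""
        idx = np.argmax(np.abs(self.i), axis=1)
        return self.voltages, self.i[np.arange(len(idx)), idx]

    def end_pulse(self) -> tuple[np.ndarray, np.ndarray]:
        return self.voltages, self.i[:, -1]

    def activation_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """Normalized conductance-like activation from peak currents."""
        v, pk = self.peak_iv()
        g = np.abs(pk)
        return v, g / g.max()

    def frc(self, times=None) -> tuple[np.ndarray, np.ndarray]:
        """Fractional remaining current FRC(t, Vm) = I(t,Vm)/I_peak(Vm)."""
        ipk_idx = np.argmax(np.abs(self.i), axis=1)
        ipk = self.i[np.arange(len(ipk_idx)), ipk_idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            frc = self.i / ipk[:, None]
        if times is None:
            return self.t, frc
        cols = np.searchsorted(self.t, times)
        return np.asarray(times), frc[:, cols]


def _masked(params: Params, current: str) -> tuple[Params, str]:
    if current not in _CURRENT_OF:
        raise ValueError(
            f"current {current!r} has no isolated clamp mode; "
            f"available: {sorted(_CURRENT_OF)}")
    keep, name = _CURRENT_OF[current]
    kw = {g: 0.0 for g in _MASKABLE if g != keep}
    return params.replace(**kw, mode=1.0, stim_amp=0.0), name


def _hold_steady(y0, p, holding, duration, rtol, atol):
    y0 = y0.copy()
    y0[c.S_V] = holding
    t = np.array([0.0, duration])
    return _integrate(y0, t, p, rtol, atol, np.inf)[-1]


def voltage_clamp(params: Params, protocol: ClampProtocol, current: str,
                  dt: float = 0.5, rtol: float = 1e-8, atol: float = 1e-10,
                  y0: np.ndarray | None = None) -> SweepFamily:
    """Run a clamp sweep family on an isolated current.

    Each sweep starts from steady state at the holding potential; the
    parameter set is temperature-transformed to ``protocol.temperature``.
    """
    params.validate()
    masked, cname = _masked(
        params.with_temperature(protocol.temperature), current)
    p = masked.to_vector()
    ci = c.CURRENT_NAMES.index(cname)
    if y0 is None:
        y0 = initial_state(params)
    # steady state at holding: long relaxation, reused for every sweep
    yhold = _hold_steady(np.asarray(y0, float), p, protocol.holding,
                         max(protocol.inter_sweep, 30000.0), rtol, atol)
    tgrid = np.arange(0.0, protocol.test_duration + dt / 2, dt)
    traces = []
    for v_test in protocol.sweeps:
        y = yhold.copy()
        if protocol.prepulse is not None and protocol.prepulse_duration > 0:
            y[c.S_V] = protocol.prepulse
            seg = np.array([0.0, protocol.prepulse_duration])
            y = _integrate(y, seg, p, rtol, atol, np.inf)[-1]
        y[c.S_V] = v_test
        sol = _integrate(y, tgrid, p, rtol, atol, np.inf)
        cur = np.empty(len(tgrid))
        for k in range(len(tgrid)):
            _, cu = _rhs_currents(tgrid[k], sol[k], p)
            cur[k] = cu[ci]
        traces.append(cur)
    return SweepFamily(voltages=np.asarray(protocol.sweeps, float),
                       t=tgrid, i=np.vstack(traces), current=current,
                       protocol=protocol)


def _rhs_currents(t, y, p):
    from .rhs import rhs_full
    return rhs_full(t, y, p, 1.0, np.zeros(2), np.zeros(2))


def availability_curve(params: Params, current: str, prepulses,
                       test_voltage: float, prepulse_duration: float = 1000.0,
                       holding: float = -120.0, test_duration: float = 50.0,
                       temperature: float = 37.0, dt: float = 0.2,
                       rtol: float = 1e-8, atol: float = 1e-10):
    """Steady-state availability: conditioning pre-pulse family, fixed test.

    Returns (prepulse voltages, normalized peak test current).
    """
    params.validate()
    masked, cname = _masked(params.with_temperature(temperature), current)
    p = masked.to_vector()
    ci = c.CURRENT_NAMES.index(cname)
    yhold = _hold_steady(initial_state(params), p, holding, 30000.0,
                         rtol, atol)
    peaks = []
    tgrid = np.arange(0.0, test_duration + dt / 2, dt)
    for v_pre in prepulses:
        y = yhold.copy()
        y[c.S_V] = v_pre
        y = _integrate(y, np.array([0.0, prepulse_duration]), p,
                       rtol, atol, np.inf)[-1]
        y[c.S_V] = test_voltage
        sol = _integrate(y, tgrid, p, rtol, atol, np.inf)
        cur = np.array([_rhs_currents(tgrid[k], sol[k], p)[1][ci]
                        for k in range(len(tgrid))])
        peaks.append(cur[np.argmax(np.abs(cur))])
    peaks = np.asarray(peaks)
    ref = np.max(np.abs(peaks))
    return np.asarray(prepulses, float), np.abs(peaks) / ref


def recovery_curve(params: Params, current: str, intervals,
                   holding: float = -120.0, pulse_voltage: float = -30.0,
                   pulse_duration: float = 500.0, temperature: float = 37.0,
                   dt: float = 0.2, rtol: float = 1e-8, atol: float = 1e-10):
    """Two-pulse recovery from inactivation (P2/P1 peak ratio vs interval)."""
    params.validate()
    masked, cname = _masked(params.with_temperature(temperature), current)
    p = masked.to_vector()
    ci = c.CURRENT_NAMES.index(cname)
    yhold = _hold_steady(initial_state(params), p, holding, 30000.0,
                         rtol, atol)
    tgrid = np.arange(0.0, pulse_duration + dt / 2, dt)

    def pulse_peak(y):
        y = y.copy()
        y[c.S_V] = pulse_voltage
        sol = _integrate(y, tgrid, p, rtol, atol, np.inf)
        cur = np.array([_rhs_currents(tgrid[k], sol[k], p)[1][ci]
                        for k in range(len(tgrid))])
        return cur[np.argmax(np.abs(cur))], sol[-1]

    p1, y_end = pulse_peak(yhold)
    ratios = []
    for dt_rec in intervals:
        y = y_end.copy()
        y[c.S_V] = holding
        y = _integrate(y, np.array([0.0, dt_rec]), p, rtol, atol,
                       np.inf)[-1]
        p2, _ = pulse_peak(y)
        ratios.append(p2 / p1)
    return np.asarray(intervals, float), np.asarray(ratios)


# ----------------------------------------------------------------------
# AP clamp


def ap_clamp(params: Params, waveform_t: np.ndarray,
             waveform_v: np.ndarray, n_beats: int = 60,
             record_beats: int = 3, y0: np.ndarray | None = None,
             rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Clamp the cell to a periodic AP waveform; all other states free.

    The waveform is resampled to a 0.1 ms grid (linear interpolation) and
    must span one pacing period.
    """
    params.validate()
    period = params.stim_period
    if waveform_t[-1] - waveform_t[0] < period - 1e-6:
        raise ValueError("waveform shorter than the pacing period")
    wave_dt = 0.1
    tg = np.arange(0.0, period + wave_dt / 2, wave_dt)
    wv = np.interp(tg, waveform_t - waveform_t[0], waveform_v)
    wdv = np.gradient(wv, wave_dt)
    p = params.replace(mode=2.0, stim_amp=0.0).to_vector()
    if y0 is None:
        y0 = initial_state(params)
    y = np.asarray(y0, float).copy()
    y[c.S_V] = wv[0]
    for _ in range(n_beats - record_beats):
        y = _integrate(y, np.array([0.0, period]), p, rtol, atol, 1.0,
                       wave_dt=wave_dt, wave_v=wv, wave_dv=wdv)[-1]
    ts, ys, starts = [], [], []
    grid = np.arange(0.0, period, 0.25)
    for b in range(record_beats):
        t0 = b * period
        starts.append(t0)
        sol = _integrate(y, np.concatenate([grid, [period]]), p, rtol,
                         atol, 1.0, wave_dt=wave_dt, wave_v=wv,
                         wave_dv=wdv)
        y = sol[-1]
        ts.append(t0 + grid)
        ys.append(sol[:-1])
    t_all = np.concatenate(ts)
    y_all = np.vstack(ys)
    traj = Trajectory(t=t_all, y=y_all,
                      params=params.replace(mode=2.0, stim_amp=0.0),
                      beat_starts=np.asarray(starts))
    # under AP clamp V is imposed; store the imposed waveform for analysis
    traj.y = traj.y.copy()
    traj.y[:, c.S_V] = np.interp(t_all % period, tg, wv)
    return traj


# ----------------------------------------------------------------------
# S1-S2 restitution


def s1s2_restitution(params: Params, s1_freq: float = 1.0, n_s1: int = 21,
                     di_values=None, y0: np.ndarray | None = None,
                     rtol: float = 1e-8, atol: float = 1e-10) -> dict:
    """Restitution: APD90 of a premature S2 beat vs diastolic interval.

    A train of ``n_s1`` S1 beats at ``s1_freq`` is followed by an S2 at a
    diastolic interval measured from the APD90 point of the last S1.
    """
    period = 1000.0 / s1_freq
    p = params.replace(stim_period=period)
    if y0 is None:
        y0 = initial_state(p)
    tr = run(p, n_beats=n_s1, y0=y0, record_beats=2, rtol=rtol, atol=atol)
    bm = biomarkers.extract(tr, beats=1)
    apd90_s1 = bm.apd90
    t_up = bm.per_beat[-1].t_upstroke
    t_repol = t_up + apd90_s1          # absolute time of 90 % repolarization
    # restart the diastole from the recorded state at the APD90 point of
    # the 21st AP, so any positive diastolic interval is reachable
    i_rep = int(np.searchsorted(tr.t, t_repol))
    y_repol = tr.y[min(i_rep, len(tr.t) - 1)]
    t0 = tr.t[min(i_rep, len(tr.t) - 1)]
    if di_values is None:
        di_values = np.arange(10.0, 401.0, 10.0)
    pvec = p.to_vector()
    p_wait = pvec.copy()
    p_wait[c.P_STIM_AMP] = 0.0         # no S1 during the S2 wait
    out_di, out_apd = [], []
    for di in di_values:
        t_s2 = t_repol + di
        if t_s2 <= t0:
            continue
        y = _integrate(y_repol, np.array([t0, t_s2]), p_wait, rtol,
                       atol, 1.0)[-1]
        p2 = p.replace(stim_period=period * 4)
        tr2 = run(p2, n_beats=1, y0=y, record_beats=1, rtol=rtol,
                  atol=atol)
        bm2 = biomarkers.extract(tr2, beats=1)
        if bm2.capture_ratio == "failure":
            continue
        out_di.append(di)
        out_apd.append(bm2.apd90)
    return {"di": np.asarray(out_di), "apd90": np.asarray(out_apd),
            "apd90_s1": apd90_s1}


# ----------------------------------------------------------------------
# Ca2+ ripples and stimulus calibration


@dataclass
class RippleSpec:
    """Late-systolic oscillatory modulation of the release parameter bt."""

    latency: float = 150.0        # ms after the stimulus
    freq: float = 0.008           # oscillation frequency (1/ms)
    magnitude: float = 0.0        # relative modulation amplitude
    duration: float = 400.0       # modulation window (ms)

    def __post_init__(self):
        if self.latency < 0 or self.magnitude < 0 or self.duration < 0:
            raise ValueError("ripple latency/magnitude/duration must be >= 0")


def impose_ripples(params: Params, spec: RippleSpec) -> Params:
    """Return parameters with the ripple schedule applied: bt(t) is the
    baseline before ``latency`` and sinusoidally modulated afterwards
    within the beat."""
    return params.replace(ripple_mag=spec.magnitude, ripple_freq=spec.freq,
                          ripple_lat=spec.latency,
                          ripple_dur=spec.duration)


def find_diastolic_threshold(params: Params, freq_hz: float = 1.0,
                             y0: np.ndarray | None = None,
                             tol: float = 0.25, lo: float = 0.0,
                             hi: float = 60.0, n_beats: int = 3,
                             rtol: float = 1e-7, atol: float = 1e-9) -> float:
    """Diastolic stimulus threshold (A/F magnitude) by bisection."""
    period = 1000.0 / freq_hz
    if y0 is None:
        y0 = initial_state(params)

    def captures(amp):
        p = params.replace(stim_amp=-amp, stim_period=period)
        tr = run(p, n_beats=n_beats, y0=y0, record_beats=1, rtol=rtol,
                 atol=atol)
        return biomarkers.extract(tr).capture_ratio != "failure"

    if not captures(hi):
        raise RuntimeError("no capture even at the maximal test amplitude")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return hi


def calibrate_stimulus(params: Params, freq_hz: float = 1.0,
                       margin: float = 1.25, **kw) -> Params:
    """Set the pacing stimulus to ``margin`` x diastolic threshold."""
    thr = find_diastolic_threshold(params, freq_hz, **kw)
    return params.replace(stim_amp=-margin * thr,
                          stim_period=1000.0 / freq_hz)
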