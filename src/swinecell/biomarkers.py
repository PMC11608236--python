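"""Action-potential and Ca2+-transient biomarker extraction.

Biomarkers per captured beat:

* APD20/50/90 - AP duration from the time of maximal upstroke velocity to
  20/50/90 % repolarization of the AP amplitude (ms);
* max dV/dt (V/s), AP amplitude APA (mV), resting membrane potential RMP
  (V immediately before the stimulus, mV);
* CaT amplitude (peak - diastolic cytosolic Ca2+; reported both in mM and
  in model units of 1e-4 mM), time to peak (ms from stimulus), full
  duration at half magnitude FDHM (ms) and time to 90 % decay from peak.

Event detectors: early afterdepolarizations (a sustained depolarizing
episode during repolarization), APD alternans and the capture ratio.
Operational thresholds are configurable keyword arguments; the defaults
are conventional choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Trajectory


@dataclass
class BeatFeatures:
    captured: bool = False
    rmp: float = np.nan
    apa: float = np.nan
    dvdt_max: float = np.nan
    apd20: float = np.nan
    apd50: float = np.nan
    apd90: float = np.nan
    cat_amp: float = np.nan          # mM
    cat_ttp: float = np.nan
    cat_fdhm: float = np.nan
    cat_decay90: float = np.nan
    ead: bool = False
    t_upstroke: float = np.nan


@dataclass
class BiomarkerSet:
    """Aggregated biomarkers (means over analysed captured beats)."""

    apd20: float
    apd50: float
    apd90: float
    dvdt_max: float
    apa: float
    rmp: float
    cat_amp: float                  # model units (1e-4 mM)
    cat_ttp: float
    cat_fdhm: float
    cat_decay90: float
    ead: bool
    alternans: bool
    capture_ratio: str              # "1:1", "2:1", "failure", "n:m"
    n_beats: int
    per_beat: list = field(default_factory=list, repr=False)

    FIELDS = ("apd20", "apd50", "apd90", "dvdt_max", "apa", "rmp",
              "cat_amp", "cat_ttp", "cat_fdhm", "cat_decay90")

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.FIELDS}
        d.update(ead=self.ead, alternans=self.alternans,
                 capture_ratio=self.capture_ratio, n_beats=self.n_beats)
        return d


def _crossing_time(t, x, level, start_idx, direction=-1):
    """First time x crosses `level` after start_idx (linear interpolation)."""
    seg = x[start_idx:]
    if direction < 0:
        hits = np.nonzero(seg <= level)[0]
    else:
        hits = np.nonzero(seg >= level)[0]
    if len(hits) == 0 or hits[0] == 0:
        return np.nan
    i = start_idx + hits[0]
    x0, x1 = x[i - 1], x[i]
    if x1 == x0:
        return t[i]
    return t[i - 1] + (level - x0) / (x1 - x0) * (t[i] - t[i - 1])


def beat_features(t, v, cai, t_stim, period, *, capture_v=0.0,
                  capture_window=20.0, capture_vrest=-40.0,
                  baseline_window=50.0,
                  ead_dvdt=0.02, ead_min_dur=5.0,
                  ead_dome_excl=80.0) -> BeatFeatures:
    """Extract features of the beat stimulated at ``t_stim``."""
    f = BeatFeatures()
    m = (t >= t_stim) & (t < t_stim + period)
    tb = t[m]
    vb = v[m]
    cb = cai[m]
    if len(tb) < 5:
        return f
    f.rmp = vb[0]
    # capture: the cell must be excitable (repolarized) at the stimulus
    # and reach the depolarization criterion shortly afterwards
    early = vb[tb <= t_stim + capture_window]
    if early.max() < capture_v or vb[0] > capture_vrest:
        return f
    f.captured = True
    dvdt = np.gradient(vb, tb)
    up_win = tb <= t_stim + capture_window
    iup = int(np.argmax(np.where(up_win, dvdt, -np.inf)))
    f.dvdt_max = dvdt[iup]          # mV/ms = V/s
    f.t_upstroke = tb[iup]
    ipk = int(np.argmax(vb))
    vpk = vb[ipk]
    f.apa = vpk - f.rmp
    for frac, name in ((0.2, "apd20"), (0.5, "apd50"), (0.9, "apd90")):
        level = vpk - frac * f.apa
        tc = _crossing_time(tb, vb, level, ipk, direction=-1)
        if np.isfinite(tc):
            setattr(f, name, tc - f.t_upstroke)

    # EAD: sustained depolarizing episode during repolarization, i.e.
    # between APD20 time and 95 % repolarization.  Episodes beginning
    # within ``ead_dome_excl`` ms of the upstroke are the physiological
    # notch-dome redevelopment and do not count.
    if np.isfinite(f.apd20):
        t20 = f.t_upstroke + f.apd20
        v95 = vpk - 0.95 * f.apa
        t95 = _crossing_time(tb, vb, v95, ipk, direction=-1)
        if not np.isfinite(t95):
            t95 = tb[-1]
        t_min = max(t20, f.t_upstroke + ead_dome_excl)
        pos = (dvdt > ead_dvdt) & (tb < t95)
        run = 0.0
        t_start = None
        for i in np.nonzero(pos)[0]:
            prev = i - 1
            if prev >= 0 and pos[prev]:
                run += tb[i] - tb[prev]
            else:
                run = 0.0
                t_start = tb[i]
            if run >= ead_min_dur and t_start is not None \
                    and t_start > t_min:
                f.ead = True
                break

    # CaT features relative to the diastolic baseline
    pre = (t >= t_stim - baseline_window) & (t <= t_stim)
    base = cai[pre].min() if pre.any() else cb[0]
    icp = int(np.argmax(cb))
    peak = cb[icp]
    f.cat_amp = peak - base
    f.cat_ttp = tb[icp] - t_stim
    half = base + 0.5 * f.cat_amp
    t_up = _crossing_time(tb, cb, half, 0, direction=+1)
    t_dn = _crossing_time(tb, cb, half, icp, direction=-1)
    if np.isfinite(t_up) and np.isfinite(t_dn):
        f.cat_fdhm = t_dn - t_up
    t90 = _crossing_time(tb, cb, base + 0.1 * f.cat_amp, icp, direction=-1)
    if np.isfinite(t90):
        f.cat_decay90 = t90 - tb[icp]
    return f


def extract(traj: Trajectory, beats: int | None = None,
            **thresholds) -> BiomarkerSet:
    """Biomarkers averaged over the last ``beats`` recorded beats."""
    starts = traj.beat_starts
    if len(starts) == 0:
        raise ValueError("trajectory carries no stimulus markers")
    if beats is not None:
        if beats > len(starts):
            raise ValueError(
                f"trajectory has {len(starts)} recorded beats, "
                f"{beats} requested")
        starts = starts[-beats:]
    period = traj.params.stim_period
    feats = [beat_features(traj.t, traj.v, traj.cai, s, period,
                           **thresholds) for s in starts]
    cap = [f for f in feats if f.captured]
    ratio = _capture_ratio(feats)

    def mean(name):
        vals = [getattr(f, name) for f in cap
                if np.isfinite(getattr(f, name))]
        return float(np.mean(vals)) if vals else np.nan

    apd90s = [f.apd90 for f in cap if np.isfinite(f.apd90)]
    return BiomarkerSet(
        apd20=mean("apd20"), apd50=mean("apd50"), apd90=mean("apd90"),
        dvdt_max=mean("dvdt_max"), apa=mean("apa"), rmp=mean("rmp"),
        cat_amp=mean("cat_amp") * 1e4, cat_ttp=mean("cat_ttp"),
        cat_fdhm=mean("cat_fdhm"), cat_decay90=mean("cat_decay90"),
        ead=any(f.ead for f in feats),
        alternans=_alternans(apd90s),
        capture_ratio=ratio, n_beats=len(feats), per_beat=feats)


def _alternans(apd90s, threshold=5.0, n_last=10):
    seq = apd90s[-n_last:]
    if len(seq) < 3:
        return False
    d = np.diff(seq)
    return bool(np.all(np.abs(d) > threshold)
                and np.all(d[:-1] * d[1:] < 0))


def _capture_ratio(feats) -> str:
    caps = [f.captured for f in feats]
    n = len(caps)
    k = sum(caps)
    if k == n:
        return "1:1"
    if k == 0:
        return "failure"
    # alternating capture?
    if n >= 4 and all(caps[i] != caps[i + 1] for i in range(n - 1)):
        return "2:1"
    return f"{n}:{k}"


def detect_events(traj: Trajectory, **thresholds) -> dict:
    """EAD / alternans / capture summary of a steady-state trajectory."""
    bm = extract(traj, **thresholds)
    ead_times = [f.t_upstroke for f in bm.per_beat if f.ead]
    return {"ead": bm.ead, "ead_beats": ead_times,
            "alternans": bm.alternans, "capture_ratio": bm.capture_ratio}
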