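"""Two-tier calibration machinery.

Tier 1 (:func:`fit_gating`) fits gating/conductance parameters of a
single current against clamp summaries (I-V, activation, availability,
recovery, FRC).  Tier 2 (:func:`optimize_conductances`) fine-tunes the
main ionic conductances and Ca2+ release/uptake parameters against AP
and CaT biomarkers at several pacing frequencies.

Both tiers minimize the weighted sum of squared residuals

    Error = sum_i weight_i * sum_j (Y_ij,sim - Y_ij,exp)^2

with the Nelder-Mead simplex.  Box constraints are enforced by
reflecting the simplex coordinates at the bounds; a failed simulation
contributes a large finite penalty so the simplex retreats smoothly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import biomarkers, model
from .params import Params

FAIL_PENALTY = 1.0e12

# the 14 parameters of the automatic optimization; the same set is
# randomized by the sensitivity analysis
OPTIMIZED_PARAMETERS = (
    "gna", "gnal", "gkr", "gks", "gk1", "gto2", "pca", "gncx", "pnak",
    "gpca", "bt", "jup_vmax", "km_serca", "jleak_scale",
)


@dataclass
class FitTarget:
    """One dataset entering the cost: simulated vs target summary values."""

    label: str
    kind: str                        # iv/activation/availability/recovery/
    #                                  frc/biomarker
    values: np.ndarray               # target values
    weight: float = 1.0              # e.g. number of experimental sweeps
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.weight <= 0:
            raise ValueError("weights must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite target values in {self.label!r}")


@dataclass
class FitResult:
    params: Params
    cost: float
    initial_cost: float
    n_iter: int
    simplex_spread: float
    converged: bool
    warning: str | None = None


def cost(params: Params, targets, simulate) -> float:
    """Weighted sum-of-squares cost.

    ``simulate(params, target)`` must return the simulated counterpart of
    ``target.values``.  Failed simulations yield a large finite penalty.
    """
    total = 0.0
    for tg in targets:
        try:
            y_sim = np.asarray(simulate(params, tg), dtype=float)
        except model.SimulationError as err:
            shortfall = 0.0
            if err.last_valid_time is not None:
                shortfall = max(0.0, -err.last_valid_time)
            return FAIL_PENALTY + shortfall
        if y_sim.shape != tg.values.shape:
            raise ValueError(
                f"simulated summary shape {y_sim.shape} does not match "
                f"target {tg.label!r} shape {tg.values.shape}")
        total += tg.weight * float(np.sum((y_sim - tg.values) ** 2))
    return total


def _reflect(x, lo, hi):
    """Reflect coordinates into [lo, hi] (tent map, keeps NM smooth)."""
    x = np.asarray(x, dtype=float).copy()
    span = hi - lo
    for i in range(len(x)):
        if span[i] <= 0:
            x[i] = lo[i]
            continue
        z = (x[i] - lo[i]) % (2 * span[i])
        x[i] = lo[i] + (z if z <= span[i] else 2 * span[i] - z)
    return x


def fit_gating(initial: Params, targets, simulate, vary,
               bounds: dict | None = None, max_iter: int = 200,
               xatol: float = 1e-4, fatol: float = 1e-8) -> FitResult:
    """Nelder-Mead fit of the parameters named in ``vary``.

    ``bounds`` maps parameter names to (lo, hi); default is (0, 10x) of
    the initial value.  Returns the best parameters found, with a warning
    flag if the iteration budget was exhausted.
    """
    vary = list(vary)
    if len(set(vary)) != len(vary):
        raise ValueError("duplicate parameter in vary list")
    x0 = np.array([getattr(initial, n) for n in vary], dtype=float)
    lo = np.empty(len(vary))
    hi = np.empty(len(vary))
    for i, n in enumerate(vary):
        b = (bounds or {}).get(n)
        if b is None:
            b = (min(0.0, x0[i] * 10), abs(x0[i]) * 10 + 1e-12) \
                if x0[i] < 0 else (0.0, x0[i] * 10 + 1e-12)
        lo[i], hi[i] = b

    def build(x):
        x = _reflect(x, lo, hi)
        return initial.replace(**dict(zip(vary, x)))

    def f(x):
        return cost(build(x), targets, simulate)

    c0 = f(x0)
    res = minimize(f, x0, method="Nelder-Mead",
                   options={"maxiter": max_iter, "xatol": xatol,
                            "fatol": fatol, "adaptive": True})
    spread = float(np.max(np.abs(res.final_simplex[1] - res.final_simplex[1][0]))) \
        if hasattr(res, "final_simplex") else np.nan
    best = build(res.x)
    warning = None
    if not res.success:
        warning = f"Nelder-Mead stopped without convergence: {res.message}"
    final_cost = float(res.fun)
    if final_cost > c0:             # never return worse than the start
        best, final_cost = initial, c0
        warning = "no improvement over the initial parameters"
    return FitResult(params=best, cost=final_cost, initial_cost=float(c0),
                     n_iter=int(res.nit), simplex_spread=spread,
                     converged=bool(res.success), warning=warning)


# ----------------------------------------------------------------------
# tier 2: global conductance optimization against biomarkers


def biomarker_targets_from_model(params: Params, freqs=(0.5, 1.0, 2.0),
                                 n_beats: int = 60, weight: float = 1.0,
                                 fields=biomarkers.BiomarkerSet.FIELDS,
                                 y0_map: dict | None = None,
                                 **run_kw) -> list[FitTarget]:
    """Self-targets: the model's own biomarkers at the given frequencies."""
    targets = []
    for f in freqs:
        bm = _simulate_biomarkers(params, f, n_beats, fields,
                                  y0_map=y0_map, **run_kw)
        targets.append(FitTarget(label=f"biomarkers@{f}Hz",
                                 kind="biomarker", values=bm, weight=weight,
                                 meta={"freq": f, "fields": fields,
                                       "n_beats": n_beats}))
    return targets


def _simulate_biomarkers(params, freq, n_beats, fields, y0_map=None,
                         **run_kw):
    p = params.replace(stim_period=1000.0 / freq)
    y0 = (y0_map or {}).get(freq)
    if y0 is None:
        y0 = model.initial_state(p)
    tr = model.run(p, n_beats=n_beats, y0=y0, record_beats=3, **run_kw)
    bm = biomarkers.extract(tr, beats=2)
    if bm.capture_ratio == "failure":
        raise model.SimulationError("no capture during optimization",
                                    last_valid_time=0.0)
    return np.array([getattr(bm, f) for f in fields])


def optimize_conductances(initial: Params, targets,
                          vary=OPTIMIZED_PARAMETERS,
                          bounds: dict | None = None, max_iter: int = 100,
                          y0_map: dict | None = None,
                          **run_kw) -> FitResult:
    """Fine-tune the 14-parameter set against biomarker (and optional
    restitution) targets."""

    def simulate(p, tg):
        if tg.kind == "biomarker":
            return _simulate_biomarkers(
                p, tg.meta["freq"], tg.meta["n_beats"], tg.meta["fields"],
                y0_map=y0_map, **run_kw)
        if tg.kind == "restitution":
            from .protocols import s1s2_restitution
            res = s1s2_restitution(p, di_values=tg.meta["di"], **run_kw)
            return res["apd90"]
        raise ValueError(f"unknown target kind {tg.kind!r}")

    if bounds is None:
        bounds = {n: (0.25 * getattr(initial, n), 4.0 * getattr(initial, n))
                  for n in vary}
    return fit_gating(initial, targets, simulate, vary, bounds=bounds,
                      max_iter=max_iter)


def parameter_table(initial: Params, fitted: Params,
                    vary=OPTIMIZED_PARAMETERS):
    """Initial/final parameter table (pandas DataFrame)."""
    import pandas as pd
    rows = [{"parameter": n, "initial": getattr(initial, n),
             "fitted": getattr(fitted, n),
             "ratio": getattr(fitted, n) / getattr(initial, n)
             if getattr(initial, n) else np.nan} for n in vary]
    return pd.DataFrame(rows)
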