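"""Population-of-models sensitivity analysis.

Parameters are randomized with lognormal scaling factors (median 1,
sigma of the natural log 0.2, so ~98 % of draws fall between 0.5 and
1.5), the population is paced to steady state at 1 Hz, invalid members
(alternans, repolarization failure, loss of 1:1 capture) are dropped,
inputs and outputs are z-scored column-wise, and the sensitivity matrix

    B = (X^T X)^(-1) X^T Y

is obtained by multivariable linear regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import biomarkers, model
from .fitting import OPTIMIZED_PARAMETERS
from .params import Params

BIOMARKER_FIELDS = biomarkers.BiomarkerSet.FIELDS


@dataclass
class SensitivityResult:
    factors: np.ndarray          # (n, p) raw scaling factors
    X: np.ndarray                # (n_valid, p) z-scored log-factors
    Y: np.ndarray                # (n_valid, m) z-scored biomarkers
    B: np.ndarray                # (p, m)
    valid: np.ndarray            # (n,) bool mask
    biomarkers_raw: np.ndarray   # (n, m) with NaN rows for invalid members
    parameters: tuple
    features: tuple
    seed: int

    @property
    def validity_fraction(self) -> float:
        return float(np.mean(self.valid))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.B, index=list(self.parameters),
                            columns=list(self.features))


def sample_population(n: int, p: int = len(OPTIMIZED_PARAMETERS),
                      sigma: float = 0.2, seed: int = 0) -> np.ndarray:
    """Lognormal scaling-factor matrix (median 1 per column)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n < p + 2:
        raise ValueError("need at least p + 2 population members")
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(0.0, sigma, size=(n, p)))


def zscore(a: np.ndarray) -> np.ndarray:
    mu = a.mean(axis=0)
    sd = a.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(f"column {bad} has zero variance; cannot z-score")
    return (a - mu) / sd


def regress(X: np.ndarray, Y: np.ndarray,
            valid: np.ndarray | None = None) -> np.ndarray:
    """B = (X^T X)^(-1) X^T Y on z-scored valid rows."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if valid is not None:
        X = X[valid]
        Y = Y[valid]
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError("not enough valid rows for the regression")
    Xz = zscore(X)
    Yz = zscore(Y)
    xtx = Xz.T @ Xz
    rank = np.linalg.matrix_rank(xtx)
    if rank < Xz.shape[1]:
        # name the collinear columns for the error message
        _, r = np.linalg.qr(Xz)
        dep = np.nonzero(np.abs(np.diag(r)) < 1e-10)[0]
        raise np.linalg.LinAlgError(
            f"rank-deficient input matrix; collinear columns: {dep}")
    return np.linalg.solve(xtx, Xz.T @ Yz)


def member_biomarkers(base: Params, factors_row, parameters,
                      freq_hz: float = 1.0, n_beats: int = 60,
                      y0=None, record_beats: int = 12,
                      **run_kw):
    """Simulate one population member; returns (biomarker vector, valid)."""
    scaling = dict(zip(parameters, factors_row))
    p = base.scaled(scaling).replace(stim_period=1000.0 / freq_hz)
    if y0 is None:
        y0 = model.initial_state(p)
    try:
        tr = model.run(p, n_beats=n_beats, y0=y0,
                       record_beats=record_beats, **run_kw)
        bm = biomarkers.extract(tr)
    except (model.SimulationError, ValueError):
        return np.full(len(BIOMARKER_FIELDS), np.nan), False
    valid = (bm.capture_ratio == "1:1" and not bm.alternans
             and np.isfinite(bm.apd90))
    vec = np.array([getattr(bm, f) for f in BIOMARKER_FIELDS])
    return vec, bool(valid and np.all(np.isfinite(vec)))


def run_population(base: Params, n: int = 500, seed: int = 0,
                   parameters=OPTIMIZED_PARAMETERS, sigma: float = 0.2,
                   freq_hz: float = 1.0, n_beats: int = 60, y0=None,
                   progress: bool = False,
                   **run_kw) -> SensitivityResult:
    """Full population analysis at 1 Hz pacing.

    Individual member failures mark the member invalid and never abort
    the batch.  Invalid members are excluded from both X and Y before
    z-scoring.
    """
    parameters = tuple(parameters)
    factors = sample_population(n, len(parameters), sigma, seed)
    Yraw = np.empty((n, len(BIOMARKER_FIELDS)))
    valid = np.zeros(n, dtype=bool)
    it = range(n)
    if progress:
        from tqdm import tqdm
        it = tqdm(it)
    for i in it:
        Yraw[i], valid[i] = member_biomarkers(
            base, factors[i], parameters, freq_hz=freq_hz,
            n_beats=n_beats, y0=y0, **run_kw)
    B = regress(np.log(factors), Yraw, valid)
    return SensitivityResult(
        factors=factors, X=zscore(np.log(factors[valid])),
        Y=zscore(Yraw[valid]), B=B, valid=valid, biomarkers_raw=Yraw,
        parameters=parameters, features=tuple(BIOMARKER_FIELDS),
        seed=seed)
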