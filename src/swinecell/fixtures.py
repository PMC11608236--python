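"""Synthetic fixture generation for the fitting machinery.

Real voltage-clamp and biomarker target tables are laboratory data; the
generators here produce synthetic stand-ins with known ground truth -
Boltzmann activation/availability curves, noisy peak I-V relationships
and biomarker tables centred on the model's own output - sufficient to
exercise every fitting path without any download.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import biomarkers, model
from .params import Params


def boltzmann(v, vhalf, k):
    return 1.0 / (1.0 + np.exp((vhalf - np.asarray(v, float)) / k))


def activation_fixture(seed: int = 0, vhalf: float = -20.0, k: float = 6.0,
                       v_range=(-80.0, 40.0), n: int = 25,
                       noise_sd: float = 0.01) -> pd.DataFrame:
    """Boltzmann activation curve with known (V1/2, k) plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    v = np.linspace(*v_range, n)
    y = boltzmann(v, vhalf, k) + rng.normal(0, noise_sd, n)
    return pd.DataFrame({"v_mv": v, "value": y,
                         "true_vhalf": vhalf, "true_k": k})


def availability_fixture(seed: int = 0, vhalf: float = -80.0, k: float = 6.0,
                         v_range=(-130.0, -20.0), n: int = 23,
                         noise_sd: float = 0.01) -> pd.DataFrame:
    """Boltzmann availability (descending) with known parameters."""
    rng = np.random.default_rng(seed)
    v = np.linspace(*v_range, n)
    y = 1.0 - boltzmann(v, vhalf, k) + rng.normal(0, noise_sd, n)
    return pd.DataFrame({"v_mv": v, "value": y,
                         "true_vhalf": vhalf, "true_k": k})


def iv_fixture(seed: int = 0, gmax: float = 1.0, vhalf: float = -35.0,
               k: float = 6.0, erev: float = 60.0, v_range=(-80.0, 60.0),
               n: int = 29, noise_sd: float = 0.02) -> pd.DataFrame:
    """Peak I-V of a Boltzmann-activated ohmic channel, with noise."""
    rng = np.random.default_rng(seed)
    v = np.linspace(*v_range, n)
    i = gmax * boltzmann(v, vhalf, k) * (v - erev)
    i = i + rng.normal(0, noise_sd * np.max(np.abs(i)), n)
    return pd.DataFrame({"v_mv": v, "i_apf": i, "true_gmax": gmax,
                         "true_vhalf": vhalf, "true_k": k,
                         "true_erev": erev})


def biomarker_table_fixture(params: Params | None = None, seed: int = 0,
                            freqs=(0.5, 1.0, 2.0), rel_sd: float = 0.0,
                            n_beats: int = 40,
                            y0_map: dict | None = None,
                            **run_kw) -> pd.DataFrame:
    """Biomarker targets centred on the model's own output.

    ``rel_sd`` adds multiplicative Gaussian scatter (0 reproduces the
    model exactly, for self-target optimization tests).
    """
    if params is None:
        from .params import wild_type
        params = wild_type()
    rng = np.random.default_rng(seed)
    rows = []
    for f in freqs:
        p = params.replace(stim_period=1000.0 / f)
        y0 = (y0_map or {}).get(f)
        if y0 is None:
            y0 = model.initial_state(p)
        tr = model.run(p, n_beats=n_beats, y0=y0, record_beats=3, **run_kw)
        bm = biomarkers.extract(tr, beats=2)
        row = {"freq_hz": f}
        for name in biomarkers.BiomarkerSet.FIELDS:
            val = getattr(bm, name)
            row[name] = val * (1.0 + rng.normal(0, rel_sd)) \
                if rel_sd > 0 else val
        rows.append(row)
    return pd.DataFrame(rows)


def generate_fixtures(seed: int = 0, out_dir=None) -> dict:
    """All synthetic fixtures; written as CSV when ``out_dir`` is given."""
    fx = {
        "activation": activation_fixture(seed),
        "availability": availability_fixture(seed + 1),
        "iv": iv_fixture(seed + 2),
    }
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in fx.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return fx
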