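"""Configuration, table readers/writers and provenance records.

CSV is the interchange default (long format for trajectories: time,
variable, value); HDF5 is available for long trajectories when h5py is
installed.  Run configurations are YAML mappings validated against a
schema; unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import constants as c
from .model import Trajectory
from .params import Params

_CONFIG_KEYS = {
    "phenotype": str,           # wt | ts1
    "freq_hz": (int, float),
    "duration_s": (int, float),
    "rtol": (int, float),
    "atol": (int, float),
    "max_step": (int, float),
    "seed": int,
    "out_dir": str,
    "interventions": dict,
    "parameters": dict,         # raw parameter overrides
}
_INTERVENTION_KEYS = {
    "fraction_ts1", "drug", "gene_silencing_wt", "gene_silencing_ts1",
    "gene_therapy", "camk_km_mult", "inal_block", "thl_override",
    "ltcc_act_shift", "remodeling",
    "ripple_latency", "ripple_freq", "ripple_magnitude", "ripple_duration",
}


@dataclass
class RunConfig:
    phenotype: str = "wt"
    freq_hz: float = 1.0
    duration_s: float = 800.0
    rtol: float = 1e-10
    atol: float = 1e-11
    max_step: float = 1.0
    seed: int = 0
    out_dir: str = "."
    interventions: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(_CONFIG_KEYS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in raw.items():
            if not isinstance(v, _CONFIG_KEYS[k]):
                raise ValueError(
                    f"config key {k!r} has type {type(v).__name__}")
        bad = set(raw.get("interventions", {})) - _INTERVENTION_KEYS
        if bad:
            raise ValueError(f"unknown intervention keys: {sorted(bad)}")
        cfg = cls(**raw)
        if cfg.phenotype not in ("wt", "ts1"):
            raise ValueError("phenotype must be 'wt' or 'ts1'")
        if cfg.freq_hz <= 0 or cfg.duration_s <= 0:
            raise ValueError("freq_hz and duration_s must be positive")
        return cfg

    def build_params(self) -> Params:
        from . import interventions as iv
        from .params import wild_type
        from .protocols import RippleSpec, impose_ripples
        p = wild_type()
        if self.phenotype == "ts1":
            spec = self.interventions
            p = iv.make_ts1(p, spec.get("fraction_ts1", iv.TS1_FRACTION),
                            remodeling=spec.get("remodeling", True))
        spec = self.interventions
        if "drug" in spec:
            p = iv.apply_drug(p, spec["drug"])
        if "gene_silencing_wt" in spec or "gene_silencing_ts1" in spec:
            p = iv.gene_therapy(p, spec.get("gene_silencing_wt", 0.0),
                                spec.get("gene_silencing_ts1", 0.0),
                                spec.get("gene_therapy", 1))
        if "camk_km_mult" in spec:
            p = iv.camkii_inhibition(p, spec["camk_km_mult"])
        if "inal_block" in spec:
            p = iv.block_inal(p, spec["inal_block"])
        if "thl_override" in spec:
            p = iv.slow_hl_gate(p, spec["thl_override"])
        if "ltcc_act_shift" in spec:
            p = iv.shift_ltcc_activation(p, spec["ltcc_act_shift"])
        if "ripple_magnitude" in spec:
            p = impose_ripples(p, RippleSpec(
                latency=spec.get("ripple_latency", 150.0),
                freq=spec.get("ripple_freq", 0.008),
                magnitude=spec["ripple_magnitude"],
                duration=spec.get("ripple_duration", 400.0)))
        p = p.replace(stim_period=1000.0 / self.freq_hz)
        for k, v in self.parameters.items():
            if k not in c.PARAM_NAMES:
                raise ValueError(f"unknown parameter override {k!r}")
            p = p.replace(**{k: float(v)})
        return p


# ----------------------------------------------------------------------
# tables


def trajectory_to_frame(traj: Trajectory, states=("v", "cai", "cass",
                                                  "cajsr", "nai"),
                        currents=()) -> pd.DataFrame:
    """Long-format table: time, variable, value."""
    parts = []
    for s in states:
        parts.append(pd.DataFrame(
            {"time_ms": traj.t, "variable": s, "value": traj.state(s)}))
    for cu in currents:
        parts.append(pd.DataFrame(
            {"time_ms": traj.t, "variable": cu, "value": traj.current(cu)}))
    return pd.concat(parts, ignore_index=True)


def write_trajectory(traj: Trajectory, path, **kw) -> None:
    path = Path(path)
    df = trajectory_to_frame(traj, **kw)
    if path.suffix in (".h5", ".hdf5"):
        import h5py
        with h5py.File(path, "w") as fh:
            fh.create_dataset("t", data=traj.t)
            fh.create_dataset("y", data=traj.y)
            fh.attrs["state_names"] = ",".join(c.STATE_NAMES)
    else:
        df.to_csv(path, index=False)


def read_trajectory_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"time_ms", "variable", "value"}
    if set(df.columns) != expected:
        raise ValueError(
            f"malformed trajectory table {path}: columns {list(df.columns)}"
            f" != {sorted(expected)}")
    return df


def write_sweeps(fam, path) -> None:
    """Tidy sweep family: sweep id, time, V, I."""
    rows = []
    for k, v in enumerate(fam.voltages):
        rows.append(pd.DataFrame({
            "sweep": k, "time_ms": fam.t, "v_mv": v, "i_apf": fam.i[k]}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_sweeps(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"sweep", "time_ms", "v_mv", "i_apf"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"malformed sweep table: missing {sorted(missing)}")
    return df


def write_biomarkers(bm_by_freq: dict, path) -> None:
    rows = []
    for freq, bm in bm_by_freq.items():
        d = bm.as_dict()
        d["freq_hz"] = freq
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_b_matrix(result, path) -> None:
    result.to_frame().to_csv(path, index_label="parameter")


def read_b_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="parameter")


def write_provenance(path, config: dict, seed: int | None = None) -> None:
    blob = json.dumps(config, sort_keys=True, default=str)
    rec = {
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "config": config,
        "seed": seed,
        "swinecell_version": __version__,
        "numpy_version": np.__version__,
    }
    with open(path, "w") as fh:
        json.dump(rec, fh, indent=1)
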