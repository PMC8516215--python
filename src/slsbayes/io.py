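"""CSV/YAML readers and writers for datasets and prior configurations.

CSV is the interchange format throughout (there is no community-standard
container for SLS data). The dataset schema is one row per (condition,
level): ``condition_id``, ``level``, ``c_measured_g_per_mL``,
``rayleigh_1_per_cm``, ``delta_n``, ``ri_valid`` and optionally ``n0``
(solvent refractive index per condition, default 1.33). Numeric columns
round-trip at 17 significant digits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ExperimentDataset, OligomerSpec, PriorConfig
from .physics import PhysicalConstants

__all__ = [
    "SchemaError",
    "read_dataset",
    "write_dataset",
    "load_prior_config",
    "save_prior_config",
    "config_hash",
]

_REQUIRED = ["condition_id", "c_measured_g_per_mL", "rayleigh_1_per_cm", "ri_valid"]


class SchemaError(ValueError):
    """A dataset file violates the interchange schema."""


def read_dataset(
    path: str | Path, constants: PhysicalConstants = PhysicalConstants()
) -> ExperimentDataset:
    """Load and validate a processed dataset CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if "delta_n" not in df.columns:
        df["delta_n"] = np.nan
    bad = df.index[df["c_measured_g_per_mL"] <= 0]
    if len(bad):
        raise SchemaError(f"{path}: nonpositive concentration at row {bad[0]}")
    cond_ids = list(dict.fromkeys(df["condition_id"]))
    cond_idx = df["condition_id"].map({c: i for i, c in enumerate(cond_ids)}).to_numpy()
    if "level" in df.columns:
        # levels strictly increase within a replicate run; a drop is only a
        # valid run restart if it returns to the condition's first level
        for cid, grp in df.groupby("condition_id", sort=False):
            lv = grp["level"].to_numpy()
            first = lv[0]
            for j in range(1, lv.size):
                ok = lv[j] > lv[j - 1] or lv[j] == first
                if not ok:
                    raise SchemaError(
                        f"{path}: non-monotone levels in condition {cid!r} "
                        f"at row {grp.index[j]}"
                    )
    valid = df["ri_valid"].astype(bool).to_numpy()
    delta_n = df["delta_n"].to_numpy(dtype=float)
    delta_n = np.where(valid, delta_n, np.nan)
    if "n0" in df.columns:
        n0 = df.groupby(cond_idx)["n0"].first().to_numpy(dtype=float)
    else:
        n0 = np.full(len(cond_ids), constants.solvent_index)
    return ExperimentDataset(
        c_measured=df["c_measured_g_per_mL"].to_numpy(dtype=float),
        rayleigh=df["rayleigh_1_per_cm"].to_numpy(dtype=float),
        delta_n=delta_n,
        ri_valid=valid,
        cond_idx=cond_idx,
        n0=n0,
        constants=constants,
        condition_ids=[str(c) for c in cond_ids],
    )


def write_dataset(dataset: ExperimentDataset, path: str | Path) -> None:
    df = dataset.to_frame()
    df.insert(1, "level", _level_ordinals(dataset))
    df["n0"] = dataset.n0[dataset.cond_idx]
    df.to_csv(path, index=False, float_format="%.17g")


def _level_ordinals(dataset: ExperimentDataset) -> np.ndarray:
    """Per-condition ordinal restarting whenever concentration decreases."""
    out = np.zeros(dataset.n_obs, dtype=int)
    for l in range(dataset.n_conditions):
        idx = np.where(dataset.cond_idx == l)[0]
        c = dataset.c_measured[idx]
        ordinal = 1
        for j, i in enumerate(idx):
            if j > 0 and c[j] <= c[j - 1]:
                ordinal = 1
            out[i] = ordinal
            ordinal += 1
    return out


# ---------------------------------------------------------------------------
# prior configuration files
# ---------------------------------------------------------------------------


def _prior_to_dict(priors: PriorConfig) -> dict:
    d = dataclasses.asdict(priors)
    olig = d.pop("oligomer")
    d.pop("ig_parameterization", None)
    d["oligomer"] = {k: olig[k] for k in ("kind", "x", "low", "high")}
    return d


def save_prior_config(priors: PriorConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_prior_to_dict(priors), fh, sort_keys=True)


def load_prior_config(path: str | Path) -> PriorConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    olig = d.pop("oligomer", {})
    spec = OligomerSpec(
        kind=olig.get("kind", "fixed_multiple"),
        x=int(olig.get("x", 1)),
        low=float(olig.get("low", 1.0)),
        high=float(olig.get("high", 2.0)),
    )
    return PriorConfig(oligomer=spec, **d)


def config_hash(priors: PriorConfig) -> str:
    """Short stable hash identifying a prior configuration in artifacts."""
    payload = json.dumps(_prior_to_dict(priors), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
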