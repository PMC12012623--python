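"""CSV/JSON persistence for cohorts, fits, deviation and severity tables.

All CSV writers prepend ``#``-prefixed metadata comment lines (seed, config
hash, package version); the readers skip them, so tables round-trip
losslessly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import SyntheticConfig
from .reference import ReferenceModelFit


def config_hash(config: SyntheticConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:16]


def make_metadata(seed=None, cfg_hash=None, **extra) -> dict:
    meta = {"package": "msrefcurve", "version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if cfg_hash is not None:
        meta["config_hash"] = cfg_hash
    meta.update(extra)
    return meta


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_cohort_csv(df: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    write_table(df, path, make_metadata(seed, cfg_hash))


def read_cohort_csv(path) -> pd.DataFrame:
    df = read_table(path)
    for col in ("phenotype", "sex", "dmt_ever", "dmt_efficacy", "fu_phenotype"):
        if col in df.columns:
            df[col] = df[col].astype(object).where(df[col].notna(), None)
    return df


def write_config_json(config: SyntheticConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = json.loads(config.model_dump_json())
    payload["_metadata"] = make_metadata(config.seed, config_hash(config))
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_config_json(path) -> SyntheticConfig:
    payload = json.loads(Path(path).read_text())
    payload.pop("_metadata", None)
    return SyntheticConfig.model_validate(payload)


def write_fit_json(fit: ReferenceModelFit, path, seed=None, cfg_hash=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = fit.to_dict()
    payload["_metadata"] = make_metadata(seed, cfg_hash)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_fit_json(path) -> ReferenceModelFit:
    payload = json.loads(Path(path).read_text())
    payload.pop("_metadata", None)
    return ReferenceModelFit.from_dict(payload)


def write_results_json(results: dict, path, seed=None, cfg_hash=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"_metadata": make_metadata(seed, cfg_hash), **results}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
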