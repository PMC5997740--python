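"""Configuration files, tab-separated outputs and run manifests.

All tabular output is plain tab-separated text; series files carry a
commented header with the configuration hash and seed so any file can be
traced back to the exact run that produced it.  A run manifest echoes the
full configuration and seed list and is sufficient to reproduce every output
byte for byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import PRESETS, ScenarioConfig, preset_config
from .errors import ConfigurationError
from .genome import ChromosomeTable

__all__ = [
    "read_chromosome_table", "config_to_dict", "config_from_dict",
    "load_config", "config_hash", "write_series", "read_series",
    "write_profiles", "read_profiles", "write_manifest", "read_manifest",
]

_CONFIG_FIELDS = {f.name for f in fields(ScenarioConfig)}


def read_chromosome_table(path, basic_length: int = 128) -> ChromosomeTable:
    return ChromosomeTable.from_tsv(path, basic_length=basic_length)


def config_to_dict(config: ScenarioConfig) -> dict:
    d = config.to_dict()
    if not isinstance(d["chromosome_table"], str):
        raise ConfigurationError(
            "an in-memory chromosome table cannot be serialized; "
            "write it to TSV and reference the path")
    return d


def config_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    preset = d.pop("preset", None)
    unknown = set(d) - _CONFIG_FIELDS
    if unknown:
        raise ConfigurationError(f"unknown configuration fields: {sorted(unknown)}")
    if preset is not None:
        cfg = preset_config(preset, **d)
    else:
        cfg = ScenarioConfig(**d)
        cfg.validate()
    return cfg


def load_config(path) -> ScenarioConfig:
    """Parse a YAML scenario file; a ``preset`` key expands before overrides."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping of config fields")
    return config_from_dict(data)


def config_hash(config: ScenarioConfig) -> str:
    payload = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def write_series(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Tab-separated time series with '# key<TAB>value' comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}\t{v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_series(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_profiles(path, profiles: dict[str, np.ndarray],
                   meta: dict | None = None) -> None:
    """Locus profiles in long form: chromosome, locus_rank, fraction."""
    frames = [
        pd.DataFrame({"chromosome": name,
                      "locus_rank": np.arange(len(vals)),
                      "fraction": np.asarray(vals, float)})
        for name, vals in profiles.items()
    ]
    write_series(pd.concat(frames, ignore_index=True), path, meta)


def read_profiles(path) -> pd.DataFrame:
    return read_series(path)


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
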