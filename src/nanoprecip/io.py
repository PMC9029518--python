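"""Record-table and configuration I/O plus run manifests.

External units follow lab convention (concentrations in mM, diameters in
nm); all internal computation is mol/L and m.  Every artifact written is
reproducible bit-for-bit from (config, seed), and each run directory gets
a manifest recording seed, configuration hash and package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

RECORD_COLUMNS = ["compound", "protocol", "portion", "c0_mM", "dh_nm", "replicate", "seed"]


class SchemaError(ValueError):
    """A data table is missing required columns."""


@dataclass
class StudyConfig:
    """Parsed simulation study configuration (YAML)."""

    seed: int = 0
    compounds_file: Optional[str] = None
    protocols_file: Optional[str] = None
    study_file: Optional[str] = None
    simulator: dict = None  # keyword overrides for SimConfig
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.simulator is None:
            self.simulator = {}


def read_study_config(path: Union[str, Path]) -> StudyConfig:
    """Parse a study configuration YAML file."""
    try:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ValueError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    known = {"seed", "compounds_file", "protocols_file", "study_file", "simulator", "output_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    return StudyConfig(**raw)


def write_records(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a tidy record table as UTF-8 comma-separated text."""
    frame.to_csv(path, index=False, float_format="%.6g")


def read_records(path: Union[str, Path], required: tuple[str, ...] = ("compound", "protocol", "c0_mM", "dh_nm")) -> pd.DataFrame:
    """Read a record table, validating the required columns."""
    frame = pd.read_csv(path)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return frame


def config_hash(config: StudyConfig) -> str:
    payload = json.dumps(vars(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(path: Union[str, Path], config: StudyConfig) -> None:
    """Write a small JSON provenance manifest next to run outputs."""
    from . import __version__

    manifest = {
        "seed": config.seed,
        "config_sha256_16": config_hash(config),
        "nanoprecip_version": __version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
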