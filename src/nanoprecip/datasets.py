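"""Packaged study fixtures and loaders.

Ships the compound-constant table, the five-protocol design table, the
variant/antisolvent pairings, the measured hydrodynamic-diameter ranges
per (variant, protocol), and the zeta-potential/pH measurements, all as
small plain-text files.  Loaders return the package's domain objects or
tidy DataFrames.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .compounds import Compound
from .process import AntisolventSpec, Protocol

__all__ = [
    "load_compounds",
    "load_protocol_table",
    "load_study_design",
    "load_dh_ranges",
    "load_zeta_ph",
    "build_protocols",
    "variant_compound_map",
]

_DATA = resources.files("nanoprecip") / "data"


def _path(name: str, override: Optional[Union[str, Path]]) -> Path:
    return Path(override) if override is not None else Path(str(_DATA / name))


def load_compounds(path: Optional[Union[str, Path]] = None) -> dict[str, Compound]:
    """Compound constants, keyed by compound name."""
    with open(_path("compounds.yaml", path), encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, rec in raw.items():
        out[name] = Compound(
            name=name,
            acid_base=rec["acid_base"],
            pka=float(rec["pka"]),
            logp_values=tuple(rec["logp_values"]),
            free_base_solubility=float(rec["free_base_solubility"]),
            molecular_volume=float(rec["molecular_volume"]),
            cmc=float(rec["cmc"]) if "cmc" in rec else None,
            surface_active=bool(rec.get("surface_active", False)),
            aggregation_number=rec.get("aggregation_number"),
        )
    return out


def load_protocol_table(path: Optional[Union[str, Path]] = None) -> pd.DataFrame:
    """The five-protocol design table (flow rate, C0solvent mode, SAS)."""
    return pd.read_csv(_path("protocols.csv", path))


def load_study_design(path: Optional[Union[str, Path]] = None) -> dict:
    """Variant table: compound, Cs (mM), antisolvent NaOH (mM), nominal pH."""
    with open(_path("study.yaml", path), encoding="utf-8") as fh:
        return yaml.safe_load(fh)["variants"]


def load_dh_ranges(path: Optional[Union[str, Path]] = None) -> pd.DataFrame:
    """Measured DH ranges (nm) per (variant, protocol) — wet-lab fixture."""
    return pd.read_csv(_path("dh_ranges.csv", path))


def load_zeta_ph(path: Optional[Union[str, Path]] = None) -> pd.DataFrame:
    """Measured zeta potential (mV) and dispersion pH — wet-lab fixture."""
    return pd.read_csv(_path("zeta_ph.csv", path))


def variant_compound_map(design: Optional[dict] = None) -> dict[str, str]:
    """Map of dispersion-variant label -> parent compound name."""
    design = design if design is not None else load_study_design()
    return {variant: rec["compound"] for variant, rec in design.items()}


def _parse_sas(text: str) -> tuple[int, int]:
    num, den = text.split(":")
    return int(num), int(den)


def build_protocols(
    variant: str,
    design: Optional[dict] = None,
    protocol_table: Optional[pd.DataFrame] = None,
) -> list[Protocol]:
    """Concrete protocols for one dispersion variant.

    Combines the protocol design table (flow rate, C0solvent mode, SAS
    ratio) with the variant's saturation concentration and antisolvent:
    ``Cs`` rows use the variant's Cs, ``half_Cs`` rows half of it; the
    antisolvent volume follows from the SAS ratio and the fixed 10 mL of
    solvent.
    """
    design = design if design is not None else load_study_design()
    table = protocol_table if protocol_table is not None else load_protocol_table()
    if variant not in design:
        raise KeyError(f"unknown variant {variant!r}")
    rec = design[variant]
    cs = float(rec["cs_mM"]) * 1e-3  # mol/L
    antisolvent = AntisolventSpec(
        naoh_concentration=float(rec["naoh_mM"]) * 1e-3,
        nominal_ph=float(rec["nominal_ph"]),
    )
    protocols = []
    for _, row in table.iterrows():
        c0 = cs if row["c0_mode"] == "Cs" else cs / 2.0
        protocols.append(
            Protocol(
                id=str(row["id"]),
                flow_rate=float(row["flow_rate_ml_min"]),
                c0_mode=str(row["c0_mode"]),
                c0_solvent=c0,
                sas_ratio=_parse_sas(str(row["sas_ratio"])),
                antisolvent=antisolvent,
            )
        )
    return protocols
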