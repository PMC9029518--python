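"""Final-size analysis: DHf extraction, (DHf)av, and the size-vs-logP fit.

The headline analysis of the study: for every (compound variant, protocol)
series the final hydrodynamic diameter DHf is the DH at the largest
cumulative concentration C0; per-compound (DHf)av averages DHf over the
five protocols (pooling dispersion variants of the same compound); and an
ordinary least-squares line of (DHf)av on (logP)av summarizes the
size-lipophilicity trend, the slope sign being the headline result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from scipy import stats

from .compounds import Compound, logp_average
from .simulator import DLSRecord

__all__ = [
    "SizeAnalysisResult",
    "TrendReport",
    "extract_dhf",
    "dhf_average",
    "fit_size_vs_logp",
    "trend_report",
    "CONTRAST_PAIRS",
]

#: Protocol pairs that isolate one process parameter in the design table
#: (the second member of each pair is the reference level).
CONTRAST_PAIRS: dict[str, list[tuple[str, str]]] = {
    "flow_rate": [("No. 3", "No. 1")],
    "c0_solvent": [("No. 1", "No. 4"), ("No. 5", "No. 2")],
    "sas_ratio": [("No. 2", "No. 4"), ("No. 5", "No. 1")],
}


@dataclass
class SizeAnalysisResult:
    """Per-compound size summary and/or a size-vs-logP regression.

    ``dhf_by_protocol`` maps protocol id to DHf (nm) and ``dhf_av`` is
    their arithmetic mean; ``slope`` (nm per logP unit), ``intercept``
    (nm) and ``r_squared`` describe the OLS line (squared Pearson
    correlation of observed vs fitted).  A bare regression result carries
    an empty protocol map and NaN ``dhf_av``.
    """

    dhf_by_protocol: dict[str, float] = field(default_factory=dict)
    dhf_av: float = math.nan
    slope: float = math.nan
    intercept: float = math.nan
    r_squared: float = math.nan


@dataclass
class TrendReport:
    """Full study summary: per-variant DHf, per-compound (DHf)av, the
    global regression, and single-parameter protocol contrasts."""

    dhf_table: pd.DataFrame  # columns: compound, protocol, dhf_nm
    dhf_av: dict[str, float]  # parent compound -> (DHf)av (nm)
    fit: Optional[SizeAnalysisResult]
    contrasts: pd.DataFrame  # columns: effect, compound, protocols, delta_dhf_nm


def _records_to_frame(series: Union[pd.DataFrame, Iterable[DLSRecord]]) -> pd.DataFrame:
    if isinstance(series, pd.DataFrame):
        return series
    rows = [
        {
            "compound": r.compound_name,
            "protocol": r.protocol_id,
            "c0_mM": r.c0 * 1e3,
            "dh_nm": r.dh_nm,
            "replicate": r.replicate,
        }
        for r in series
    ]
    return pd.DataFrame(rows)


def extract_dhf(series: Union[pd.DataFrame, Iterable[DLSRecord]]) -> float:
    """Final hydrodynamic diameter DHf (nm) of one protocol's series.

    DHf is the DH measured at the maximal cumulative concentration C0
    (the end of the staged addition); ties on C0 resolve to the last
    record.  Order-invariant apart from that tie-break.
    """
    frame = _records_to_frame(series)
    if frame.empty:
        raise ValueError("series must be non-empty")
    c0 = frame["c0_mM"].to_numpy()
    idx = len(c0) - 1 - int((c0[::-1]).argmax())  # last occurrence of the max
    return float(frame["dh_nm"].iloc[idx])


def dhf_average(dhf_values: Sequence[float]) -> float:
    """Arithmetic mean of DHf values; variant pooling is the caller's
    concern (pass the pooled list, e.g. ten values for two variants)."""
    if len(dhf_values) == 0:
        raise ValueError("dhf_values must be non-empty")
    return math.fsum(float(v) for v in dhf_values) / len(dhf_values)


def fit_size_vs_logp(points: Sequence[tuple[float, float]]) -> SizeAnalysisResult:
    """Ordinary least squares of (DHf)av (nm) on (logP)av.

    Needs at least three points with non-constant x; returns slope,
    intercept and R^2 (squared Pearson correlation, identical to the OLS
    coefficient of determination for a simple linear fit).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points for a regression")
    x = [p[0] for p in points]
    y = [p[1] for p in points]
    if max(x) == min(x):
        raise ValueError("degenerate fit: all x values identical")
    res = stats.linregress(x, y)
    return SizeAnalysisResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def trend_report(
    study: pd.DataFrame,
    compounds: Mapping[str, Compound],
    variant_map: Optional[Mapping[str, str]] = None,
) -> TrendReport:
    """Study-level size analysis of a tidy DLS record table.

    ``study`` needs columns compound (variant label), protocol, c0_mM,
    dh_nm.  ``variant_map`` maps variant labels to parent compounds
    (identity by default), so e.g. two pH variants of one compound pool
    into a single ten-value (DHf)av.  The global fit requires at least
    three parent compounds; contrasts for absent protocol pairs are
    simply omitted.
    """
    required = {"compound", "protocol", "c0_mM", "dh_nm"}
    missing = required - set(study.columns)
    if missing:
        raise ValueError(f"study table lacks columns: {sorted(missing)}")
    variants = list(dict.fromkeys(study["compound"]))
    vmap = dict(variant_map) if variant_map is not None else {v: v for v in variants}

    rows = []
    for (variant, protocol), group in study.groupby(["compound", "protocol"], sort=False):
        rows.append(
            {"compound": variant, "protocol": protocol, "dhf_nm": extract_dhf(group)}
        )
    dhf_table = pd.DataFrame(rows)

    dhf_av: dict[str, float] = {}
    for variant in variants:
        parent = vmap.get(variant, variant)
        dhf_av.setdefault(parent, [])  # type: ignore[arg-type]
    pooled: dict[str, list[float]] = {p: [] for p in dhf_av}
    for _, row in dhf_table.iterrows():
        pooled[vmap.get(row["compound"], row["compound"])].append(row["dhf_nm"])
    dhf_av = {parent: dhf_average(vals) for parent, vals in pooled.items()}

    fit = None
    if len(dhf_av) >= 3:
        points = [
            (logp_average(compounds[parent]), av) for parent, av in dhf_av.items()
        ]
        fit = fit_size_vs_logp(points)

    contrast_rows = []
    by_key = {
        (row["compound"], row["protocol"]): row["dhf_nm"] for _, row in dhf_table.iterrows()
    }
    for effect, pairs in CONTRAST_PAIRS.items():
        for variant in variants:
            for hi, lo in pairs:
                if (variant, hi) in by_key and (variant, lo) in by_key:
                    contrast_rows.append(
                        {
                            "effect": effect,
                            "compound": variant,
                            "protocols": f"{hi} - {lo}",
                            "delta_dhf_nm": by_key[(variant, hi)] - by_key[(variant, lo)],
                        }
                    )
    # pH contrast: paired dispersion variants of the same parent compound
    parents_to_variants: dict[str, list[str]] = {}
    for variant in variants:
        parents_to_variants.setdefault(vmap.get(variant, variant), []).append(variant)
    for parent, vs in parents_to_variants.items():
        if len(vs) == 2:
            va, vb = vs
            for protocol in dict.fromkeys(dhf_table["protocol"]):
                if (va, protocol) in by_key and (vb, protocol) in by_key:
                    contrast_rows.append(
                        {
                            "effect": "antisolvent_ph",
                            "compound": parent,
                            "protocols": f"{va} - {vb} @ {protocol}",
                            "delta_dhf_nm": by_key[(va, protocol)] - by_key[(vb, protocol)],
                        }
                    )
    contrasts = pd.DataFrame(
        contrast_rows, columns=["effect", "compound", "protocols", "delta_dhf_nm"]
    )
    return TrendReport(dhf_table=dhf_table, dhf_av=dhf_av, fit=fit, contrasts=contrasts)
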