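"""Staged solvent-into-antisolvent addition: volumes, pH, C0, C*, beta.

The preparation adds 10 mL of drug-in-solvent solution to 100-200 mL of
aqueous antisolvent in 1 mL portions at a fixed flow rate.  This module
tracks, after each portion: the mixture volumes, the solvent volume
fraction phi, the NaOH-dilution-corrected pH, the dissolved compound
concentration C0, the mixture solubility C*, and the supersaturation
beta = C0 / C*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .compounds import Compound, ph_dependent_solubility
from .constants import DEFAULT_PKW, DEFAULT_TEMPERATURE

__all__ = [
    "AntisolventSpec",
    "Protocol",
    "ProcessState",
    "naoh_dilution_ph",
    "c0_trajectory",
    "mixture_solubility",
    "supersaturation",
    "protocol_end_ph",
    "mean_alpha_percent",
]


@dataclass(frozen=True)
class AntisolventSpec:
    """Aqueous antisolvent: dilute NaOH (or plain water).

    ``naoh_concentration`` is in mol/L; zero means distilled water.  The
    strong base is assumed fully dissociated and the organic solvent
    acid-base inert, so pH follows from [OH-] and pKw alone.
    """

    naoh_concentration: float = 0.0
    nominal_ph: float = 7.0
    temperature: float = DEFAULT_TEMPERATURE
    pkw: float = DEFAULT_PKW

    def __post_init__(self) -> None:
        if self.naoh_concentration < 0:
            raise ValueError("naoh_concentration must be non-negative")


@dataclass(frozen=True)
class Protocol:
    """One preparation recipe (one row of the protocol design table).

    ``sas_ratio`` is the solvent:antisolvent volume ratio, e.g. (1, 20);
    with the default 10 mL total solvent this fixes the antisolvent volume
    at 200 mL (1:20) or 100 mL (1:10).  ``c0_solvent`` is the compound
    concentration in the solvent solution (mol/L); ``c0_mode`` records
    whether that is the saturation concentration Cs or half of it.
    """

    id: str
    flow_rate: float  # mL/min
    c0_mode: str  # "Cs" | "half_Cs"
    c0_solvent: float  # mol/L
    sas_ratio: tuple[int, int]
    antisolvent: AntisolventSpec
    solvent_volume_total: float = 10.0  # mL
    portion_volume: float = 1.0  # mL

    def __post_init__(self) -> None:
        if self.c0_mode not in ("Cs", "half_Cs"):
            raise ValueError("c0_mode must be 'Cs' or 'half_Cs'")
        if not self.c0_solvent > 0:
            raise ValueError("c0_solvent must be positive")
        if not self.flow_rate > 0:
            raise ValueError("flow_rate must be positive")
        n = self.solvent_volume_total / self.portion_volume
        if abs(n - round(n)) > 1e-9:
            raise ValueError("portion_volume must divide solvent_volume_total")

    @property
    def antisolvent_volume(self) -> float:
        """Antisolvent volume in mL implied by the SAS ratio."""
        num, den = self.sas_ratio
        return self.solvent_volume_total * den / num

    @property
    def n_portions(self) -> int:
        return round(self.solvent_volume_total / self.portion_volume)


@dataclass(frozen=True)
class ProcessState:
    """Mixture state after k portions of solvent have been added.

    ``c0`` is the dissolved compound concentration in the whole mixture
    (mol/L, before any precipitation), ``c_star`` the mixture solubility,
    and ``beta = c0 / c_star`` the supersaturation.  When the trajectory is
    built without a compound, ``c_star`` and ``beta`` are NaN.
    """

    added_solvent_volume: float  # mL
    total_volume: float  # mL
    solvent_fraction: float  # phi in [0, 1]
    c0: float  # mol/L
    ph: float
    c_star: float = math.nan
    beta: float = math.nan


def naoh_dilution_ph(
    antisolvent: AntisolventSpec,
    added_solvent_volume: float,
    antisolvent_volume: float,
) -> float:
    """pH of the mixture after diluting the NaOH antisolvent with solvent.

    The added organic solvent contributes volume but no acid or base, so
    [OH-] = c_NaOH * V_antisolvent / (V_antisolvent + V_added) and
    pH = pKw + log10[OH-].  Plain water (zero NaOH) returns pH 7.0.
    """
    if antisolvent_volume <= 0:
        raise ValueError("antisolvent_volume must be positive")
    if added_solvent_volume < 0:
        raise ValueError("added_solvent_volume must be non-negative")
    if antisolvent.naoh_concentration == 0:
        return 7.0
    oh = antisolvent.naoh_concentration * antisolvent_volume / (
        antisolvent_volume + added_solvent_volume
    )
    return antisolvent.pkw + math.log10(oh)


def mixture_solubility(
    compound: Compound, state: ProcessState, cosolvency_slope: float = 0.0
) -> float:
    """Compound solubility C* (mol/L) in the solvent/antisolvent mixture.

    Log-linear cosolvency model: log10 C* rises linearly with the solvent
    volume fraction phi on top of the pH-dependent aqueous solubility,
    log10 C* = log10 CB*,w(pH) + slope * phi.  A slope of zero disables the
    cosolvent effect.
    """
    if cosolvency_slope < 0:
        raise ValueError("cosolvency_slope must be non-negative")
    aqueous = ph_dependent_solubility(compound, state.ph)
    return aqueous * 10.0 ** (cosolvency_slope * state.solvent_fraction)


def supersaturation(state: ProcessState) -> float:
    """Supersaturation beta = C0 / C* of a mixture state."""
    if not state.c_star > 0:
        raise ValueError("c_star must be positive")
    return state.c0 / state.c_star


def c0_trajectory(
    protocol: Protocol,
    compound: Optional[Compound] = None,
    cosolvency_slope: float = 0.0,
) -> list[ProcessState]:
    """Mixture states after each 1 mL portion of the staged addition.

    After k portions, C0 = c0_solvent * k*v / (V_as + k*v) and
    phi = k*v / (V_as + k*v).  C0 is the total dissolved concentration
    assuming no precipitation (the simulator handles depletion).  When a
    compound is supplied, each state also carries C*(pH, phi) and beta.
    """
    v_as = protocol.antisolvent_volume
    states: list[ProcessState] = []
    for k in range(1, protocol.n_portions + 1):
        added = k * protocol.portion_volume
        total = v_as + added
        phi = added / total
        c0 = protocol.c0_solvent * added / total
        ph = naoh_dilution_ph(protocol.antisolvent, added, v_as)
        state = ProcessState(
            added_solvent_volume=added,
            total_volume=total,
            solvent_fraction=phi,
            c0=c0,
            ph=ph,
        )
        if compound is not None:
            c_star = mixture_solubility(compound, state, cosolvency_slope)
            state = replace(state, c_star=c_star, beta=c0 / c_star)
        states.append(state)
    return states


def protocol_end_ph(protocol: Protocol) -> float:
    """Dilution-corrected pH of the end dispersion (all solvent added)."""
    return naoh_dilution_ph(
        protocol.antisolvent, protocol.solvent_volume_total, protocol.antisolvent_volume
    )


def mean_alpha_percent(
    compound: Compound, protocols: Sequence[Protocol]
) -> tuple[float, list[float]]:
    """Mean ionized percentage of the end dispersions across protocols.

    For each protocol the end-dispersion pH (NaOH antisolvent diluted by
    the full added solvent volume) is evaluated and the Henderson-
    Hasselbalch alpha% computed; the protocol-wise values and their mean
    are returned.  The protocol-to-protocol spread comes only from the
    SAS-ratio (100 vs 200 mL of antisolvent diluted by the same 10 mL).
    """
    from .compounds import ionized_fraction

    if not protocols:
        raise ValueError("need at least one protocol")
    values = [
        ionized_fraction(compound, protocol_end_ph(p)).alpha_percent for p in protocols
    ]
    return math.fsum(values) / len(values), values
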