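"""Compound constants and single-compound physical chemistry.

A :class:`Compound` bundles the immutable constants of one drug (pKa,
literature logP values, intrinsic free-base water solubility, optional CMC,
molecular volume).  The functions in this module implement the per-compound
calculations of the precipitation model:

* ``logp_average`` — mean of the literature octanol-water partition
  coefficients, (logP)av;
* ``ionized_fraction`` — Henderson–Hasselbalch ionized percentage alpha%;
* ``ph_dependent_solubility`` — weak-base (or weak-acid) aqueous solubility
  as a function of pH;
* ``classify_colloidal_stability`` — the conventional |ZP| > 30 mV rule;
* ``effective_interfacial_tension`` — truncated-Szyszkowski surface-tension
  reduction by the ionized (surfactant-like) species below its CMC.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

from .constants import GAMMA_FLOOR, SURFACE_ACTIVITY_THRESHOLD

__all__ = [
    "AcidBase",
    "Compound",
    "IonizationResult",
    "Stability",
    "logp_average",
    "ionized_fraction",
    "ph_dependent_solubility",
    "classify_colloidal_stability",
    "effective_interfacial_tension",
]


class AcidBase(str, enum.Enum):
    """Protonation character of a compound."""

    WEAK_BASE = "weak_base"
    WEAK_ACID = "weak_acid"
    NEUTRAL = "neutral"


class Stability(str, enum.Enum):
    """Colloidal-stability class of a dispersion."""

    STABLE = "stable"
    UNSTABLE = "unstable"


@dataclass(frozen=True)
class Compound:
    """Immutable physical-chemistry constants of one drug.

    Parameters
    ----------
    name
        Short identifier, e.g. ``"AMI"``.
    acid_base
        Protonation character (weak base, weak acid, or neutral).
    pka
        Ionization constant as pKa (dimensionless), 0 < pKa < 14.
    logp_values
        Literature octanol-water partition coefficients (dimensionless).
    free_base_solubility
        Intrinsic water solubility of the neutral (free) form, mol/L.
    molecular_volume
        Volume of one molecule in the solid, m^3 (Omega in the nucleation
        model).
    cmc
        Critical micelle concentration, mol/L; required when
        ``surface_active`` is set.
    surface_active
        Whether the ionized form behaves as a surfactant.
    aggregation_number
        Micellar aggregation number; stored as metadata only, no operation
        uses it.
    """

    name: str
    acid_base: AcidBase
    pka: float
    logp_values: tuple[float, ...]
    free_base_solubility: float
    molecular_volume: float
    cmc: Optional[float] = None
    surface_active: bool = False
    aggregation_number: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "acid_base", AcidBase(self.acid_base))
        object.__setattr__(self, "logp_values", tuple(float(v) for v in self.logp_values))
        if not self.logp_values:
            raise ValueError(f"{self.name}: logp_values must be non-empty")
        if not self.free_base_solubility > 0:
            raise ValueError(f"{self.name}: free_base_solubility must be positive")
        if not self.molecular_volume > 0:
            raise ValueError(f"{self.name}: molecular_volume must be positive")
        if not 0 < self.pka < 14:
            raise ValueError(f"{self.name}: pKa must lie in (0, 14)")
        if self.surface_active and self.cmc is None:
            raise ValueError(f"{self.name}: surface-active compounds need a CMC")
        if self.cmc is not None and not self.cmc > 0:
            raise ValueError(f"{self.name}: cmc must be positive")


@dataclass(frozen=True)
class IonizationResult:
    """Ionization state of a compound at one pH.

    ``alpha_percent`` is the Henderson–Hasselbalch ionized percentage in
    [0, 100]; ``charged`` flags whether it exceeds the configured
    surface-activity threshold.
    """

    ph: float
    alpha_percent: float
    charged: bool


def logp_average(compound: Compound) -> float:
    """Arithmetic mean of the literature logP values, (logP)av.

    Computed at full precision; the conventional reporting form rounds to
    one decimal.
    """
    if not compound.logp_values:
        raise ValueError("logp_values must be non-empty")
    return math.fsum(compound.logp_values) / len(compound.logp_values)


def ionized_fraction(
    compound: Compound,
    ph: float,
    threshold: float = SURFACE_ACTIVITY_THRESHOLD,
) -> IonizationResult:
    """Ionized percentage alpha% of a compound at a given pH.

    For a weak base, alpha% = 100 / (1 + 10^(pH - pKa)); for a weak acid the
    sign of the exponent flips; a neutral compound has alpha% = 0 by
    convention.  The neutral fraction is exactly 100 - alpha%.
    """
    if compound.acid_base is AcidBase.WEAK_BASE:
        alpha = 100.0 / (1.0 + 10.0 ** (ph - compound.pka))
    elif compound.acid_base is AcidBase.WEAK_ACID:
        alpha = 100.0 / (1.0 + 10.0 ** (compound.pka - ph))
    else:
        alpha = 0.0
    return IonizationResult(ph=ph, alpha_percent=alpha, charged=alpha >= threshold)


def ph_dependent_solubility(compound: Compound, ph: float) -> float:
    """Aqueous solubility (mol/L) of an ionizable compound at a given pH.

    For a weak base whose salt is much more soluble than the free base,
    CB*,w = Cf.b.*,w (1 + 10^(pKa - pH)): solubility is bounded below by the
    intrinsic free-base solubility, doubles at pH = pKa, and decreases
    strictly with pH.  A weak acid mirrors the relation
    (1 + 10^(pH - pKa)); a neutral compound has pH-independent solubility.
    """
    s0 = compound.free_base_solubility
    if compound.acid_base is AcidBase.WEAK_BASE:
        return s0 * (1.0 + 10.0 ** (compound.pka - ph))
    if compound.acid_base is AcidBase.WEAK_ACID:
        return s0 * (1.0 + 10.0 ** (ph - compound.pka))
    return s0


def classify_colloidal_stability(zeta_potential_mv: float) -> Stability:
    """Conventional colloidal-stability rule: stable iff |ZP| > 30 mV."""
    return Stability.STABLE if abs(zeta_potential_mv) > 30.0 else Stability.UNSTABLE


def effective_interfacial_tension(
    compound: Compound,
    ionized_concentration: float,
    gamma0: float,
    slope: float,
    floor: float = GAMMA_FLOOR,
) -> float:
    """Interfacial tension (N/m) reduced by the ionized surfactant species.

    Sub-CMC the tension decreases linearly with the ionized concentration
    (truncated Szyszkowski model); at and above the CMC it plateaus at
    gamma0 - slope * cmc.  The result is clamped below at ``floor`` so it
    stays physically positive.
    """
    if ionized_concentration < 0:
        raise ValueError("ionized_concentration must be non-negative")
    if not gamma0 > 0:
        raise ValueError("gamma0 must be positive")
    if slope < 0:
        raise ValueError("slope must be non-negative")
    conc = ionized_concentration
    if compound.cmc is not None:
        conc = min(conc, compound.cmc)
    return max(gamma0 - slope * conc, floor)
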