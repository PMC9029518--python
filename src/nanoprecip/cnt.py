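"""Classical nucleation theory and Smoluchowski collision kinetics.

Pure functions for the energetics and kinetics of precipitation from a
supersaturated solution:

* critical free-energy barrier  dG* = 16 pi gamma^3 Omega^2 / (3 kB^2 T^2 (ln beta)^2)
* critical nucleus radius       r*  = 2 Omega gamma / (kB T ln beta)
* nucleation rate               J   = An exp(-dG* / (kB T))
* Smoluchowski rapid-coagulation rate constant ks = 8 kB T / (3 mu)
* collision rate                rs  = ks np^2

The identities dG* = (4 pi / 3) gamma r*^2 and ln(J/An) = -dG*/(kB T) hold
exactly and are asserted by the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import BOLTZMANN, DEFAULT_PREFACTOR

__all__ = [
    "CNTParams",
    "AggregationParams",
    "critical_energy",
    "critical_radius",
    "nucleation_rate",
    "smoluchowski_rate_constant",
    "collision_rate",
]


@dataclass(frozen=True)
class CNTParams:
    """Parameters of the classical nucleation model.

    gamma: solid/solution interfacial tension, N/m.
    omega: volume of one molecule in the nucleus, m^3.
    temperature: K.
    prefactor: kinetic prefactor An, m^-3 s^-1.
    """

    gamma: float
    omega: float
    temperature: float
    prefactor: float = DEFAULT_PREFACTOR

    def __post_init__(self) -> None:
        for name in ("gamma", "omega", "temperature", "prefactor"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class AggregationParams:
    """Parameters of the diffusion-limited aggregation step.

    viscosity: dynamic viscosity of the medium, Pa.s.
    rate_constant: Smoluchowski rate constant ks, m^3/s.
    number_density: particles per unit volume np, m^-3.
    """

    viscosity: float
    rate_constant: float
    number_density: float

    def __post_init__(self) -> None:
        if not self.rate_constant > 0:
            raise ValueError("rate_constant must be positive")
        if self.number_density < 0:
            raise ValueError("number_density must be non-negative")


def critical_energy(params: CNTParams, beta: float) -> float:
    """Free-energy barrier dG* (J) for homogeneous nucleation at beta > 1.

    Strictly decreasing in beta, strictly increasing in gamma; diverges as
    beta -> 1+ (no finite barrier at saturation).
    """
    if beta <= 1:
        raise ValueError("critical_energy requires beta > 1")
    kT = BOLTZMANN * params.temperature
    ln_b = math.log(beta)
    return 16.0 * math.pi * params.gamma**3 * params.omega**2 / (3.0 * kT**2 * ln_b**2)


def critical_radius(params: CNTParams, beta: float) -> float:
    """Critical nucleus radius r* (m) at beta > 1.

    r* = 2 Omega gamma / (kB T ln beta): decreasing in beta, linear in
    gamma.  Nuclei smaller than r* redissolve; larger ones grow.
    """
    if beta <= 1:
        raise ValueError("critical_radius requires beta > 1")
    kT = BOLTZMANN * params.temperature
    return 2.0 * params.omega * params.gamma / (kT * math.log(beta))


def nucleation_rate(params: CNTParams, beta: float) -> float:
    """Homogeneous nucleation rate J (m^-3 s^-1).

    J = An exp(-dG*/(kB T)); zero at or below saturation so a staged
    process can pass through undersaturated early portions, and approaching
    the prefactor An asymptotically as beta -> infinity.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if beta <= 1:
        return 0.0
    kT = BOLTZMANN * params.temperature
    return params.prefactor * math.exp(-critical_energy(params, beta) / kT)


def smoluchowski_rate_constant(temperature: float, viscosity: float) -> float:
    """Rapid-coagulation rate constant ks = 8 kB T / (3 mu), m^3/s.

    Diffusion-limited Smoluchowski kernel for equal spheres; uses the
    dynamic viscosity of the medium.
    """
    if not temperature > 0 or not viscosity > 0:
        raise ValueError("temperature and viscosity must be positive")
    return 8.0 * BOLTZMANN * temperature / (3.0 * viscosity)


def collision_rate(agg: AggregationParams) -> float:
    """Particle collision rate rs = ks np^2, m^-3 s^-1."""
    return agg.rate_constant * agg.number_density**2
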