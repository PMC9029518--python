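"""Staged-addition precipitation simulator emulating DLS size series.

Per 1 mL portion of solvent solution added to the antisolvent the model

1. updates the mixture state (volumes, NaOH-dilution pH, solvent fraction
   phi, total dissolved concentration, mixture solubility C*, beta);
2. draws a local supersaturation multiplier whose spread shrinks with
   mixing uniformity and flow rate (better mixing -> more uniform beta);
3. nucleates ``J V dt`` particles of diameter 2 r* (classical nucleation
   theory), capped so nucleation consumes at most a small fraction of the
   currently dissolved excess;
4. grows every size bin at a rate linear in (C0 - C*) until the dissolved
   concentration relaxes to C*, with exact solute-mass bookkeeping;
5. applies one Smoluchowski aggregation step: pairwise, volume-conserving
   merges at total rate ks np^2 V, largest particles first;
6. reports the intensity-weighted (d^6-weighted) mean hydrodynamic
   diameter with multiplicative lognormal measurement noise.

The per-compound interfacial tension is an affine map of (logP)av,
gamma = intercept + slope * (logP)av, optionally reduced by the ionized
surfactant-like species below its CMC; this is the mechanism by which a
higher partition coefficient produces a larger final particle size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .cnt import CNTParams, critical_radius, nucleation_rate, smoluchowski_rate_constant
from .compounds import Compound, effective_interfacial_tension, ionized_fraction, logp_average
from .constants import AVOGADRO, DEFAULT_PREFACTOR, DEFAULT_TEMPERATURE, DEFAULT_VISCOSITY
from .process import Protocol, c0_trajectory
from . import datasets

__all__ = [
    "SimConfig",
    "ParticlePopulation",
    "DLSRecord",
    "StepAudit",
    "simulate_protocol",
    "simulate_study",
    "study_grid",
]


class ConfigError(ValueError):
    """Raised when a simulator configuration is physically inconsistent."""


@dataclass
class ParticlePopulation:
    """Discretized particle population: one diameter and count per bin.

    Counts are absolute particle numbers in the vessel (number density is
    count / mixture volume).  Aggregation and consolidation conserve total
    particulate volume exactly.
    """

    diameters: np.ndarray = field(default_factory=lambda: np.empty(0))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def total_number(self) -> float:
        return float(self.counts.sum()) if self.counts.size else 0.0

    @property
    def particulate_volume(self) -> float:
        """Total solid volume, m^3."""
        if not self.counts.size:
            return 0.0
        return float(np.sum(self.counts * (math.pi / 6.0) * self.diameters**3))

    def particulate_moles(self, omega: float) -> float:
        return self.particulate_volume / (omega * AVOGADRO)

    def add_bin(self, diameter: float, count: float) -> None:
        self.diameters = np.append(self.diameters, diameter)
        self.counts = np.append(self.counts, count)

    def intensity_weighted_diameter(self) -> float:
        """Intensity-weighted mean diameter (m), ~ sum(n d^6)/sum(n d^5).

        Rayleigh-regime weighting: scattering intensity scales with d^6,
        mimicking what a DLS instrument reports for small particles.
        """
        if not self.counts.size or self.counts.sum() <= 0:
            return math.nan
        d, n = self.diameters, self.counts
        return float(np.sum(n * d**6) / np.sum(n * d**5))

    def consolidate(self, max_bins: int = 64) -> None:
        """Merge nearest-diameter bins (count- and volume-conserving)."""
        while self.diameters.size > max_bins:
            order = np.argsort(self.diameters)
            d, n = self.diameters[order], self.counts[order]
            gaps = np.diff(d)
            i = int(np.argmin(gaps))
            vol = (math.pi / 6.0) * (n[i] * d[i] ** 3 + n[i + 1] * d[i + 1] ** 3)
            cnt = n[i] + n[i + 1]
            d_new = (6.0 * vol / (math.pi * cnt)) ** (1.0 / 3.0)
            d = np.concatenate([d[:i], [d_new], d[i + 2:]])
            n = np.concatenate([n[:i], [cnt], n[i + 2:]])
            self.diameters, self.counts = d, n


@dataclass(frozen=True)
class DLSRecord:
    """One emulated DLS measurement: mean DH at a cumulative C0."""

    c0: float  # mol/L, compound concentration in the whole mixture
    dh_nm: float
    protocol_id: str
    compound_name: str  # dispersion-variant label, e.g. "AMIa"
    replicate: int = 1


@dataclass(frozen=True)
class StepAudit:
    """Per-portion bookkeeping for conservation checks."""

    portion: int
    added_moles: float
    dissolved_moles: float
    particulate_moles: float
    count_before_aggregation: float
    count_after_aggregation: float
    volume_before_aggregation: float
    volume_after_aggregation: float
    beta_before_nucleation: float


@dataclass
class SimConfig:
    """Configuration of one simulated preparation run.

    The interfacial tension used in nucleation is
    ``gamma_logp_intercept + gamma_logp_slope * (logP)av`` (N/m), reduced
    sub-CMC by the ionized species for surface-active compounds.
    ``mixing_uniformity`` in [0, 1] and the flow rate control the spread
    of the local supersaturation seen by nucleation (1 = perfectly
    uniform).  ``nucleation_mass_fraction`` caps the solute fraction a
    single portion may convert directly into nuclei; the remainder is
    consumed by growth.  ``noise_sigma`` is the lognormal scale of the
    multiplicative DLS measurement noise.
    """

    compound: Compound
    protocol: Protocol
    label: Optional[str] = None  # dispersion-variant label; defaults to compound name
    cosolvency_slope: float = 5.0  # decades of solubility per unit phi
    growth_coefficient: float = 1e-4  # m/s per (mol/L) of excess
    mixing_uniformity: float = 0.8
    mixing_spread_scale: float = 0.5
    gamma_logp_intercept: float = 0.002  # N/m
    gamma_logp_slope: float = 0.002  # N/m per logP unit
    surfactant_gamma_slope: float = 1.0  # N/m per (mol/L) ionized species
    nucleation_mass_fraction: float = 1e-3
    noise_sigma: float = 0.05
    temperature: float = DEFAULT_TEMPERATURE
    viscosity: float = DEFAULT_VISCOSITY
    prefactor: float = DEFAULT_PREFACTOR
    growth_substeps: int = 20
    max_bins: int = 64
    ripening: bool = False
    seed: int = 0
    replicate: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing_uniformity <= 1.0:
            raise ConfigError("mixing_uniformity must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be non-negative")
        if self.base_gamma() <= 0:
            raise ConfigError(
                f"logP->gamma mapping yields non-positive interfacial tension "
                f"for {self.compound.name}"
            )

    def base_gamma(self) -> float:
        return self.gamma_logp_intercept + self.gamma_logp_slope * logp_average(self.compound)

    @property
    def variant(self) -> str:
        return self.label if self.label is not None else self.compound.name


def _effective_gamma(config: SimConfig, dissolved_conc: float, ph: float) -> float:
    """Interfacial tension at the current composition.

    Surface-active compounds lower gamma in proportion to the dissolved
    ionized concentration (sub-CMC, clamped at the CMC plateau).
    """
    gamma0 = config.base_gamma()
    if not config.compound.surface_active:
        return gamma0
    alpha = ionized_fraction(config.compound, ph).alpha_percent
    ionized_conc = dissolved_conc * alpha / 100.0
    return effective_interfacial_tension(
        config.compound, ionized_conc, gamma0, config.surfactant_gamma_slope
    )


def _grow(
    pop: ParticlePopulation,
    available_moles: float,
    excess_conc: float,
    dt: float,
    config: SimConfig,
) -> float:
    """One growth sub-step; returns moles consumed (exact bookkeeping).

    Diameters advance by dd = 2 G (C0 - C*) dt; if the implied solid
    volume exceeds the available dissolved excess, the advance is scaled
    back by bisection so consumption equals availability.
    """
    if not pop.counts.size or excess_conc <= 0 or available_moles <= 0:
        return 0.0
    omega = config.compound.molecular_volume
    dd = 2.0 * config.growth_coefficient * excess_conc * dt

    def consumed(scale: float) -> float:
        d_new = pop.diameters + scale * dd
        dv = (math.pi / 6.0) * np.sum(pop.counts * (d_new**3 - pop.diameters**3))
        return dv / (omega * AVOGADRO)

    scale = 1.0
    if consumed(1.0) > available_moles:
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if consumed(mid) > available_moles:
                hi = mid
            else:
                lo = mid
        scale = lo
    used = consumed(scale)
    pop.diameters = pop.diameters + scale * dd
    return used


def _aggregate(pop: ParticlePopulation, events: float) -> None:
    """Volume-conserving pairwise merges, largest bins first.

    ``events`` is the Smoluchowski event budget ks np^2 V dt; each event
    merges one pair within a bin into a particle of doubled volume.  The
    number of merges per bin is capped at half its count, so the total
    particle number strictly decreases whenever any merge occurs.
    """
    if events <= 0 or not pop.counts.size:
        return
    order = np.argsort(pop.diameters)[::-1]
    new_d, new_n = [], []
    remaining = events
    for idx in order:
        d, n = pop.diameters[idx], pop.counts[idx]
        pairs = min(n / 2.0, remaining)
        if pairs > 0:
            new_d.append(d * 2.0 ** (1.0 / 3.0))
            new_n.append(pairs)
            pop.counts[idx] = n - 2.0 * pairs
            remaining -= pairs
    keep = pop.counts > 0
    pop.diameters = np.concatenate([pop.diameters[keep], np.array(new_d)])
    pop.counts = np.concatenate([pop.counts[keep], np.array(new_n)])


def _ripen(pop: ParticlePopulation) -> None:
    """Optional post-hoc coarsening: redissolve sub-mean bins onto the rest.

    Heuristic Ostwald-ripening stand-in (volume-conserving): bins below
    the number-mean diameter dissolve and their volume deposits on the
    surviving bins in proportion to their surface area.
    """
    if pop.counts.size < 2:
        return
    mean_d = float(np.average(pop.diameters, weights=pop.counts))
    small = pop.diameters < mean_d
    if not small.any() or small.all():
        return
    vol_small = (math.pi / 6.0) * np.sum(pop.counts[small] * pop.diameters[small] ** 3)
    d, n = pop.diameters[~small], pop.counts[~small]
    area = n * d**2
    dv_per_bin = vol_small * area / area.sum()
    d_new = (d**3 + 6.0 * dv_per_bin / (math.pi * np.maximum(n, 1e-300))) ** (1.0 / 3.0)
    pop.diameters, pop.counts = d_new, n


def run_precipitation(config: SimConfig) -> Iterator[tuple[DLSRecord, StepAudit]]:
    """Run one staged-addition simulation, yielding a record per portion."""
    rng = np.random.default_rng(config.seed)
    protocol, compound = config.protocol, config.compound
    omega = compound.molecular_volume
    trajectory = c0_trajectory(protocol, compound, config.cosolvency_slope)
    ks = smoluchowski_rate_constant(config.temperature, config.viscosity)
    dt = protocol.portion_volume / protocol.flow_rate * 60.0  # s per portion
    sigma_local = config.mixing_spread_scale * (1.0 - config.mixing_uniformity) / protocol.flow_rate

    pop = ParticlePopulation()
    added_moles = 0.0
    dissolved_moles = 0.0
    portion_moles = protocol.c0_solvent * protocol.portion_volume * 1e-3

    for k, state in enumerate(trajectory, start=1):
        added_moles += portion_moles
        dissolved_moles += portion_moles
        volume_l = state.total_volume * 1e-3
        volume_m3 = state.total_volume * 1e-6
        c_star = state.c_star
        dissolved_conc = dissolved_moles / volume_l
        beta = dissolved_conc / c_star

        # local supersaturation seen by nucleation
        beta_local = beta * math.exp(sigma_local * rng.standard_normal()) if sigma_local > 0 else beta
        gamma = _effective_gamma(config, dissolved_conc, state.ph)
        cnt = CNTParams(gamma=gamma, omega=omega, temperature=config.temperature,
                        prefactor=config.prefactor)

        # (3) nucleation at diameter 2 r*, mass-capped
        if beta_local > 1.0:
            excess_moles = max(dissolved_moles - c_star * volume_l, 0.0)
            r_star = critical_radius(cnt, beta_local)
            d0 = 2.0 * r_star
            nucleus_vol = (math.pi / 6.0) * d0**3
            moles_per_nucleus = nucleus_vol / (omega * AVOGADRO)
            j = nucleation_rate(cnt, beta_local)
            n_cap = config.nucleation_mass_fraction * excess_moles / moles_per_nucleus
            n_new = min(j * volume_m3 * dt, n_cap)
            if n_new > 0:
                pop.add_bin(d0, n_new)
                dissolved_moles -= n_new * moles_per_nucleus

        # (4) growth: relax dissolved concentration toward C*
        sub_dt = dt / config.growth_substeps
        for _ in range(config.growth_substeps):
            excess_conc = dissolved_moles / volume_l - c_star
            if excess_conc <= 0:
                break
            available = dissolved_moles - c_star * volume_l
            dissolved_moles -= _grow(pop, available, excess_conc, sub_dt, config)

        count_before = pop.total_number
        vol_before = pop.particulate_volume

        # (5) one Smoluchowski aggregation step
        np_dens = pop.total_number / volume_m3
        events = ks * np_dens**2 * volume_m3 * dt
        _aggregate(pop, events)
        pop.consolidate(config.max_bins)

        if config.ripening and k == len(trajectory):
            _ripen(pop)

        dh = pop.intensity_weighted_diameter()
        if config.noise_sigma > 0 and math.isfinite(dh):
            dh *= math.exp(config.noise_sigma * rng.standard_normal())
        record = DLSRecord(
            c0=state.c0,
            dh_nm=dh * 1e9,
            protocol_id=protocol.id,
            compound_name=config.variant,
            replicate=config.replicate,
        )
        audit = StepAudit(
            portion=k,
            added_moles=added_moles,
            dissolved_moles=dissolved_moles,
            particulate_moles=pop.particulate_moles(omega),
            count_before_aggregation=count_before,
            count_after_aggregation=pop.total_number,
            volume_before_aggregation=vol_before,
            volume_after_aggregation=pop.particulate_volume,
            beta_before_nucleation=beta,
        )
        yield record, audit


def simulate_protocol(config: SimConfig) -> list[DLSRecord]:
    """DLS-like size series for one (compound, protocol) run."""
    return [record for record, _ in run_precipitation(config)]


def simulate_study(configs: Sequence[SimConfig]) -> pd.DataFrame:
    """Run a batch of configurations and return a tidy record table.

    Columns: compound (variant label), protocol, portion, c0_mM, dh_nm,
    replicate, seed.  Raises on duplicate (compound, protocol, replicate)
    keys.
    """
    if not configs:
        raise ValueError("configs must be non-empty")
    keys = [(c.variant, c.protocol.id, c.replicate) for c in configs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (compound, protocol, replicate) keys in configs")
    rows = []
    for config in configs:
        for portion, record in enumerate(simulate_protocol(config), start=1):
            rows.append(
                {
                    "compound": record.compound_name,
                    "protocol": record.protocol_id,
                    "portion": portion,
                    "c0_mM": record.c0 * 1e3,
                    "dh_nm": record.dh_nm,
                    "replicate": record.replicate,
                    "seed": config.seed,
                }
            )
    return pd.DataFrame(rows)


def study_grid(
    seed: int = 0,
    compounds: Optional[dict[str, Compound]] = None,
    design: Optional[dict] = None,
    replicate: int = 1,
    **overrides,
) -> list[SimConfig]:
    """Configurations for the full study grid (6 variants x 5 protocols).

    Each configuration gets an independent stream seed derived from
    ``seed``.  Keyword overrides are applied to every configuration
    (e.g. ``noise_sigma=0`` for mechanism checks).
    """
    compounds = compounds if compounds is not None else datasets.load_compounds()
    design = design if design is not None else datasets.load_study_design()
    variants = list(design)
    protocol_lists = {v: datasets.build_protocols(v, design=design) for v in variants}
    n = sum(len(p) for p in protocol_lists.values())
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    configs = []
    i = 0
    for variant in variants:
        compound = compounds[design[variant]["compound"]]
        for protocol in protocol_lists[variant]:
            configs.append(
                SimConfig(
                    compound=compound,
                    protocol=protocol,
                    label=variant,
                    seed=int(child_seeds[i]),
                    replicate=replicate,
                    **overrides,
                )
            )
            i += 1
    return configs
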