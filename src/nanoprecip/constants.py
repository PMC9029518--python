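"""Physical constants and package-wide defaults (SI units)."""

BOLTZMANN = 1.380649e-23
"""Boltzmann constant kB, J/K (2019 SI definition)."""

AVOGADRO = 6.02214076e23
"""Avogadro constant NA, 1/mol."""

DEFAULT_TEMPERATURE = 298.15
"""Default process temperature, K (DLS instrument setting of 25 degC)."""

DEFAULT_VISCOSITY = 8.872e-4
"""Dynamic viscosity of the aqueous medium, Pa.s (0.8872 cP, the DLS setting)."""

DEFAULT_PKW = 14.0
"""Water ion product -log10(Kw) at 25 degC; configurable on AntisolventSpec."""

DEFAULT_PREFACTOR = 1e30
"""Default classical-nucleation-theory kinetic prefactor An, m^-3 s^-1.
Typical order of magnitude for solution nucleation; the prefactor is a free
parameter of the model and is configurable everywhere it appears."""

GAMMA_FLOOR = 1e-4
"""Lower clamp for the effective interfacial tension, N/m.  Prevents a
surfactant-style linear decrease from producing nonphysical gamma <= 0."""

SURFACE_ACTIVITY_THRESHOLD = 5.0
"""Default ionized-percentage threshold (alpha%, percent) above which a
surface-active compound is flagged as effectively charged in a dispersion."""
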