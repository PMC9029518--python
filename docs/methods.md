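# Methods

`nanoprecip` models the bottom-up preparation of excipient-free drug
nanoparticles by antisolvent precipitation: a drug dissolved in a good
solvent (ethanol or acetone) is added in portions to a miscible aqueous
antisolvent, the resulting supersaturation drives nucleation, growth and
aggregation, and dynamic light scattering (DLS) follows the mean
hydrodynamic diameter D_H as a function of the cumulative compound
concentration C0 in the mixture. This note documents the model chain, its
assumptions, the defaults, and what the synthetic-data generator does and
does not emulate.

## Ionization and pH-dependent solubility

For a weak base the ionized percentage at a given pH is the
Henderson–Hasselbalch fraction

    alpha% = 100 / (1 + 10^(pH − pKa)),

with the exponent sign flipped for a weak acid and alpha% = 0 for a
neutral compound. A compound is flagged as effectively charged
(surface-active in dispersion) when alpha% exceeds a configurable
threshold, default 5%. The threshold resolves an ambiguity: in the study
conditions the two variants around 9.7% behave as charged surfactants
while those at 2.6% and 0.05% do not, so any cut between roughly 3% and
9% encodes the same classification; 5% is a round number inside that
window.

Weak-base aqueous solubility follows the standard salt/free-base
relation

    C_B*,w = C_f.b.*,w (1 + 10^(pKa − pH)),

valid when the salt is much more soluble than the free base
(amitriptyline hydrochloride being the canonical example). It is bounded
below by the intrinsic free-base solubility, doubles at pH = pKa, and
decreases strictly with pH. The weak-acid mirror uses 10^(pH − pKa).

The end-dispersion pH is reconstructed from NaOH dilution: the organic
solvent is treated as acid-base inert, so after adding volume V_s to
antisolvent volume V_as, [OH−] = c_NaOH V_as/(V_as + V_s) and
pH = pKw + log10[OH−] with pKw = 14.0 (25 °C; configurable). The
protocol design fixes V_s = 10 mL and V_as = 200 mL (1:20
solvent:antisolvent) or 100 mL (1:10); the 1.0 mM and 0.25 mM NaOH
antisolvents give undiluted pH 11.0 and 10.4 and end-dispersion pH
10.979/10.959 and 10.377/10.357 respectively. Averaging alpha% over the
five protocols at these end pH values is the package's reconstruction of
the reported per-variant ionization means; the protocol-to-protocol
spread comes entirely from the two SAS ratios.

## Nucleation, growth and aggregation

Classical nucleation theory (CNT) supplies the energetics at
supersaturation beta = C0/C*:

    ΔG* = 16 π γ³ Ω² / (3 kB² T² (ln β)²)        (barrier, J)
    r*  = 2 Ω γ / (kB T ln β)                    (critical radius, m)
    J   = A_n exp(−ΔG*/(kB T))                   (nucleation rate, m⁻³ s⁻¹)

with γ the solid/solution interfacial tension, Ω the molecular volume in
the solid and A_n a kinetic prefactor (default 1e30 m⁻³ s⁻¹, a typical
order for solution nucleation; no measured value exists). The exponent of
J is written as −ΔG*/(kB T), which makes the identities
ΔG* = (4π/3) γ r*² and ln(J/A_n) = −ΔG*/(kB T) exact; the test suite
asserts both to 1e−10 relative tolerance. J is defined as 0 for β ≤ 1 so
a staged process can pass through undersaturated portions.

Aggregation uses the Smoluchowski rapid-coagulation kernel for equal
spheres, ks = 8 kB T/(3 μ) with μ the dynamic viscosity (default
8.872e−4 Pa·s, the DLS instrument setting), giving a collision rate
rs = ks np² for number density np.

Mixture solubility uses the standard log-linear cosolvency model,
log10 C* = log10 C_B*,w(pH) + σ φ, with φ the solvent volume fraction
and σ a per-compound free parameter (default 5 decades per unit φ, a
typical ethanol–water slope for poorly soluble organics). The study
never quantifies the cosolvent effect, only its direction.

## The staged-addition simulator

The generator emulates one DLS record per 1 mL portion. Per portion it

1. updates volumes, pH, φ, the dissolved concentration and C*;
2. draws a local supersaturation multiplier
   β_local = β exp(s Z), Z ~ N(0,1), with
   s = 0.5 (1 − mixing_uniformity)/flow_rate — better mixing and faster
   addition narrow the local-supersaturation spread;
3. nucleates min(J V Δt, cap) particles of diameter 2r*, where the cap
   limits direct nucleation to a fraction (default 1e−3) of the dissolved
   excess in that portion — nucleation consumes little mass, growth the
   bulk;
4. grows all size bins at dd/dt = 2 G (C0 − C*) (diffusion-limited
   linear law, G default 1e−4 m·L·mol⁻¹·s⁻¹) in sub-steps until the
   dissolved concentration relaxes to C*, with exact mole bookkeeping
   (a bisection scales the last increment so consumption never exceeds
   availability);
5. applies one aggregation step with event budget ks np² V Δt: pairwise
   merges, largest bins first, each merge replacing two particles by one
   of doubled volume, capped at half of each bin's count — particle
   number strictly decreases, particulate volume is conserved exactly;
6. reports the intensity-weighted mean diameter Σn d⁶ / Σn d⁵ (Rayleigh
   d⁶ weighting, what a Zetasizer-class instrument returns) with
   multiplicative lognormal noise (default σ = 0.05, a typical DLS
   repeatability).

Solute mass is conserved identically at every step
(dissolved + particulate = added, asserted to 1e−9 relative). Bin count
is kept bounded (default 64) by merging nearest-diameter bins in a
count- and volume-conserving way. An optional `ripening` flag applies a
final heuristic coarsening (sub-mean bins redissolve onto larger ones,
volume-conserving); it is a qualitative stand-in, not a calibrated
Ostwald-ripening law.

### The logP → γ mapping

Per-compound interfacial tensions are never measured, so the simulator
derives them from lipophilicity: γ = a + b (logP)av with defaults
a = 0.002 N/m, b = 0.002 N/m per logP unit, spanning 8–12 mN/m across
the five compounds — the range typical of drug/water interfaces. This is
the mechanism that makes the final size increase with (logP)av: a higher
γ enlarges r* and suppresses J, so the same mass distributes over fewer,
larger particles. For surface-active compounds the mapped γ is further
reduced sub-CMC in proportion to the dissolved ionized concentration
(truncated Szyszkowski, slope 1.0 N·m⁻¹ per mol/L, the order observed
for ionic surfactants), clamped at the CMC plateau and at a 0.1 mN/m
floor. At the ~1e−4 M ionized concentrations of these dispersions the
reduction is small, so the pH effect on β usually dominates the
pH-variant contrast — consistent with the two opposing pH effects the
mechanism predicts, either of which may win.

### Study conditions

The packaged design tables encode the five preparation protocols
(flow 1 or 2 mL/min; C0solvent = Cs or Cs/2; SAS 1:10 or 1:20) and six
dispersion variants (two pH variants for amitriptyline). Saturation
concentrations are the printed ones (79.7, 6.28, 6.79, 50.0, 9.07 mM).
Constants not printed anywhere — intrinsic solubilities other than
amitriptyline's 3.5e−5 M, molecular volumes, non-amitriptyline CMCs —
are single literature-order estimates fixed in the fixture file and
flagged there as representative; they set the supersaturation scale of
the simulator and nothing else. Each protocol run uses 10 portions and
~20 growth sub-steps; a full 30-run grid takes about a second, so the
hundred-replicate sign-recovery study stays within a couple of minutes.

## Size analysis

DHf of a series is the DH at the maximal cumulative C0 (final portion;
ties resolve to the last record). Per-compound (DHf)av averages DHf over
the five protocols, pooling the two amitriptyline pH variants into one
ten-value mean. The trend fit is ordinary least squares of (DHf)av on
(logP)av; R² is the squared Pearson correlation, identical to the OLS
coefficient of determination for a simple linear fit. Single-factor
contrasts exploit the design structure: flow rate is isolated by
protocols No. 3 − No. 1; C0solvent by No. 1 − No. 4 and No. 5 − No. 2;
SAS ratio by No. 2 − No. 4 and No. 5 − No. 1; antisolvent pH by the
AMIa/AMIb pairing per protocol.

## What the generator does and does not emulate

Emulated: the rising DH-vs-C0 shape, the size ordering with
lipophilicity, protocol effects with the right directions and
cancellation tendencies, intensity weighting, multiplicative DLS noise,
and occasional large-particle excursions when an early portion sits at
low supersaturation (the wet-lab data likewise contain rare micron-scale
detections). Not emulated: crystal polymorphism and morphology,
multimodal size distributions, hydrodynamic mixing detail, sedimentation
and centrifugation, zeta-potential physics, or any quantitative match to
the measured DH tables — those are wet-lab observations kept as
fixtures, not targets. Consequently, passing tests show that the model
chain is internally consistent and that the analysis recovers the
mechanisms the generator encodes; they cannot show that real
formulations obey the same parameter values.

## Numerical choices and degenerate inputs

Full precision is kept everywhere; rounding ((logP)av to one decimal,
solubilities to two significant figures) happens only at reporting.
β ≤ 1 yields J = 0 rather than an error; β = 1 exactly has no finite
CNT barrier and raises in the energy/radius functions. Degenerate
regression inputs (fewer than three points, constant x) raise. The
growth bisection runs 60 iterations (float-exact for this purpose); the
aggregation tie-break (largest-with-largest, within-bin) makes the
population update deterministic given the seed. All randomness flows
from a single `numpy` generator per run; grid runs derive independent
child seeds (< 2³¹) from one study seed.

## Known limitations

- CNT's γ³ sensitivity means the nucleation-limited/mass-limited
  crossover is sharp; defaults keep the study grid mostly in the
  mass-limited regime, and excursions outside it produce heavy upper
  size tails rather than failures.
- The aggregation kernel is size-independent; real Brownian kernels
  weakly favor dissimilar pairs.
- The pH model ignores the drug's own acid-base buffering, carbonate
  uptake, and activity corrections — adequate at ≤ 1 mM NaOH.
- The linear sub-CMC surface-tension law is a directional simplification
  of the Szyszkowski isotherm.
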