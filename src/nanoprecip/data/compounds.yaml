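# Physical-chemistry constants of the five study compounds.
#
# pka, logp_values and the AMI free_base_solubility / cmc / aggregation_number
# are literature values quoted in the study tables.  free_base_solubility for
# the other compounds, molecular_volume (solid-state volume per molecule) and
# the non-AMI cmc values are representative literature-order estimates chosen
# for the simulator (synthetic stand-ins; no measured values exist in the
# study): they set the supersaturation scale, not any reported quantity.
# Units: free_base_solubility mol/L; cmc mol/L; molecular_volume m^3.
AMI:
  acid_base: weak_base
  pka: 9.4
  logp_values: [5.84, 4.97, 4.54, 4.86, 4.7]
  free_base_solubility: 3.5e-5
  cmc: 3.6e-2
  aggregation_number: 7
  molecular_volume: 4.4e-28
  surface_active: true
COU:
  acid_base: weak_acid
  pka: 2.98
  logp_values: [4.89, 4.92, 3.47, 5.48]
  free_base_solubility: 1.2e-12   # intrinsic neutral-form solubility (synthetic estimate)
  molecular_volume: 5.3e-28
  surface_active: false
CUR:
  acid_base: weak_base
  pka: 8.11
  logp_values: [3.20, 3.15, 1.47, 4.04, 2.5]
  free_base_solubility: 3.0e-9    # synthetic estimate; total ~4e-8 M at pH 7
  molecular_volume: 4.7e-28
  surface_active: false
NOR:
  acid_base: weak_base
  pka: 10.0
  logp_values: [5.31, 4.63, 4.31, 4.92, 3.57]
  free_base_solubility: 2.0e-5    # synthetic estimate (amitriptyline analogue)
  cmc: 5.0e-2                     # synthetic estimate
  molecular_volume: 4.2e-28
  surface_active: true
PRO:
  acid_base: weak_base
  pka: 7.66
  logp_values: [2.86, 2.21, 3.85, 3]
  free_base_solubility: 1.0e-6    # synthetic estimate
  cmc: 4.0e-2                     # synthetic estimate
  molecular_volume: 5.6e-28
  surface_active: true
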