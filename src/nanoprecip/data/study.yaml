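# Study design: the six dispersion variants (compound + antisolvent pairing).
# cs_mM is the saturation concentration of the compound in its solvent
# (C0solvent for the Cs protocols; half_Cs protocols use cs_mM / 2).
# naoh_mM is the NaOH concentration of the aqueous antisolvent (0 = water).
variants:
  AMIa: {compound: AMI, cs_mM: 79.7, naoh_mM: 0.25, nominal_ph: 10.4, solvent: ethanol}
  AMIb: {compound: AMI, cs_mM: 79.7, naoh_mM: 1.0, nominal_ph: 11.0, solvent: ethanol}
  COU:  {compound: COU, cs_mM: 6.28, naoh_mM: 0.0, nominal_ph: 7.0, solvent: ethanol}
  CUR:  {compound: CUR, cs_mM: 6.79, naoh_mM: 0.0, nominal_ph: 7.0, solvent: ethanol}
  NOR:  {compound: NOR, cs_mM: 50.0, naoh_mM: 1.0, nominal_ph: 11.0, solvent: ethanol}
  PRO:  {compound: PRO, cs_mM: 9.07, naoh_mM: 1.0, nominal_ph: 11.0, solvent: acetone_naoh}
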