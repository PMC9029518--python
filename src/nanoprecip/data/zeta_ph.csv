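compound,zp_mv,zp_sd,ph,ph_sd
AMI,45.3,6.9,6.676,0.071
COU,-22.8,0.3,7.203,0.042
CUR,1.0,0.1,6.784,0.078
NOR,15.6,0.7,9.605,0.019
PRO,-44.1,4.4,12.426,0.026
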