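id,flow_rate_ml_min,c0_mode,sas_ratio,antisolvent
No. 1,1,Cs,1:20,per_variant
No. 2,1,half_Cs,1:10,per_variant
No. 3,2,Cs,1:20,per_variant
No. 4,1,half_Cs,1:20,per_variant
No. 5,1,Cs,1:10,per_variant
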