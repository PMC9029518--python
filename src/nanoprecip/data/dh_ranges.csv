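variant,protocol,dh_min_nm,dh_max_nm
AMIa,No. 1,216,313
AMIa,No. 2,222,369
AMIa,No. 3,213,301
AMIa,No. 4,227,361
AMIa,No. 5,225,254
AMIb,No. 1,197,284
AMIb,No. 2,231,513
AMIb,No. 3,306,745
AMIb,No. 4,246,265
AMIb,No. 5,467,582
COU,No. 1,193,347
COU,No. 2,243,344
COU,No. 3,273,392
COU,No. 4,337,401
COU,No. 5,235,308
CUR,No. 1,119,152
CUR,No. 2,126,159
CUR,No. 3,104,168
CUR,No. 4,91,157
CUR,No. 5,120,168
NOR,No. 1,56,216
NOR,No. 2,200,224
NOR,No. 3,151,235
NOR,No. 4,152,261
NOR,No. 5,282,577
PRO,No. 1,163,264
PRO,No. 2,160,230
PRO,No. 3,155,255
PRO,No. 4,120,169
PRO,No. 5,171,199
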