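column_id,f_L3_L1,f_L4_L1
ZORBAX SB-C18,0.991,1.802
GL InertSustain C18,0.978,1.813
Sagix Copsil C18,0.984,1.798
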