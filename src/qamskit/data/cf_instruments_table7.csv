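instrument_id,f_L3_L1,f_L4_L1
UltiMate 3000,0.980,1.807
Waters 2695,0.979,1.818
Agilent 1290 Infinity II,0.992,1.810
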