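component_id,slope,intercept,r,range_low_ug,range_high_ug
L1,1244.6,10.218,0.9999,0.1008,2.016
L3,1516.8,-12.176,0.9998,0.1005,2.010
L4,597.4,11.613,0.9999,0.1505,3.010
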