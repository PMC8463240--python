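injection_volume,f_L3_L1,f_L4_L1
1,0.992,1.802
2,0.978,1.791
5,0.994,1.806
10,0.971,1.835
15,0.986,1.794
20,0.989,1.753
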