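run,methanol_fraction,flow_rate,column_temperature,injection_volume,resolution
1,60,1.2,20,5,1.62
2,70,1.2,30,5,0.89
3,60,0.8,30,15,1.53
4,60,1.2,30,15,0.85
5,60,0.8,20,15,3.23
6,70,0.8,30,15,0.78
7,70,1.2,20,15,1.45
8,70,0.8,20,5,2.88
9,70,0.8,30,5,0.91
10,60,0.8,20,5,3.12
11,70,1.2,20,15,0.86
12,60,1.2,30,5,1.94
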