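run,methanol_fraction,column_temperature,resolution
1,65,25,1.56
2,65,25,1.12
3,65,25,0.98
4,72.07,25,1.33
5,65,17.93,3.19
6,65,25,0.86
7,65,25,1.11
8,60,20,1.87
9,65,32.07,1.96
10,60,30,2.08
11,70,20,1.84
12,57.93,25,2.35
13,70,30,0.19
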