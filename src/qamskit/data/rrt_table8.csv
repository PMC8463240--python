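instrument_id,column_id,rrt_L3_L1,rrt_L4_L1
UltiMate 3000,Sagix Copsil C18,0.5591,1.1251
UltiMate 3000,ZORBAX SB-C18,0.5671,1.1302
Waters 2695,Sagix Copsil C18,0.5904,1.1260
Waters 2695,GL InertSustain C18,0.5681,1.1311
Agilent 1290 Infinity II,ZORBAX SB-C18,0.5802,1.1265
Agilent 1290 Infinity II,GL InertSustain C18,0.5719,1.1235
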