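term,ss,ms,f,p,df,significance
Model,5.7,1.14,5.97,0.0182,5,Remarkable
X1,1.41,1.41,7.41,0.0292,1,Remarkable
X2,1.26,1.26,6.62,0.0368,1,Remarkable
X1X2,0.86,0.86,4.53,0.0708,1,
X1^2,0.22,0.22,1.17,0.3159,1,
X2^2,2.08,2.08,10.88,0.0131,1,
Residual,1.34,0.19,,,7,
Lack of fit,1.06,0.35,5.01,0.0768,3,Not significant
Pure error,0.28,0.07,,,4,
Total,7.04,,,,12,
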