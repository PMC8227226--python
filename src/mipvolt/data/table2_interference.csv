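interferent,conc_uM,delta_i_uA,pct_change
4-MU,10,0.004,1.73
4-MU,50,0.03,12.98
4-MU,100,0.037,16.01
CMP,10,0.009,3.89
CMP,50,-0.007,3.03
CMP,100,-0.025,10.82
DSX,10,-0.001,0.43
DSX,50,-0.02,8.65
DSX,100,-0.039,16.88
PPX,10,-0.002,0.86
PPX,50,-0.023,9.56
PPX,100,-0.024,10.38
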