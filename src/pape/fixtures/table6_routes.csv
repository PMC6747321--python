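Route,PM2.5,Exposure
A,89.34,0.80
B,86.08,0.77
C,100.17,0.89
Actual,111.43,0.99
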