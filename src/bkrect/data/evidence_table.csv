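name,req_mean,req_sd,req_n,q_mean,q_sd,q_n,dq_e,cys_labels,source
WT-beta2,1.85,0.05,12,0.07,0.0068,12,,,printed
mSlo1,1.15,0.04,10,,,0,,,printed
C1S,1.38,0.03,8,0.48,0.04,5,,C1,printed
C2S,1.43,0.04,7,0.09,0.0074,6,,C2,printed
C3S,1.47,0.04,7,0.09,0.0075,7,,C3,reconstructed-req
C4S,1.62,0.04,7,0.08,0.0066,7,,C4,reconstructed-req
C5S,1.40,0.04,4,0.66,0.08,4,,C5,reconstructed-req
C6S,1.43,0.05,4,0.41,0.04,4,,C6,reconstructed-req
C7S,1.45,0.05,8,0.08,0.0066,8,,C7,reconstructed-req
C8S,1.45,0.04,4,0.38,0.05,4,,C8,reconstructed-req
C1S/C5S,1.36,0.05,5,0.55,0.06,5,,C1;C5,reconstructed
C3S/C7S,1.49,0.05,6,0.10,0.01,6,,C3;C7,reconstructed
C6S/C8S,1.47,0.06,5,0.45,0.05,5,,C6;C8,reconstructed
C1S/C4S,1.50,0.05,6,0.40,0.05,6,,C1;C4,reconstructed
S173K,2.13,0.02,8,0.07,0.007,8,1,C8,printed
S173D,1.69,0.02,6,0.07,0.007,6,-1,C8,printed
S173K/K141A,1.83,0.05,8,0.07,0.007,8,0,C6;C8,printed
S173K/K141D,1.65,0.05,7,0.07,0.007,7,-1,C6;C8,printed
Q83K,1.88,0.03,8,0.07,0.007,8,1,C1,printed
L114K,1.85,0.05,7,0.07,0.007,7,1,C5,printed
S100K,2.13,0.03,8,0.07,0.007,8,1,C3,printed
S100D,1.68,0.04,7,0.07,0.007,7,-1,C3,printed
S100K/K147D,1.69,0.04,6,0.07,0.007,6,-1,C3;C7,printed
S100K/K147A,1.85,0.05,6,0.07,0.007,6,0,C3;C7,printed
N96K,2.45,0.08,6,0.07,0.007,6,1,C2,printed
D104A,1.71,0.07,8,0.07,0.007,8,1,C4,printed
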