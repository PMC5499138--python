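cycle,scope,entry_mean,h2,check_mean
C0,Agua Fria,6.65,0.27,5.47
C1,Agua Fria,6.49,0.06,5.73
C2,Agua Fria,7.02,0.26,6.02
C3,Agua Fria,6.88,0.38,5.64
C4,Agua Fria,7.13,0.21,5.70
C0,Tlaltizapan,10.40,0.65,8.08
C1,Tlaltizapan,10.29,0.59,9.32
C2,Tlaltizapan,10.20,0.46,9.30
C3,Tlaltizapan,10.95,0.59,9.31
C4,Tlaltizapan,10.96,0.25,9.30
C0,combined,8.52,0.42,6.77
C1,combined,8.40,0.63,7.52
C2,combined,8.62,0.47,7.52
C3,combined,8.92,0.67,7.52
C4,combined,9.05,0.43,7.61
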