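group,shannon,heterozygosity,n_snps
parents,0.0661,0.1104,950248
C0_1000,0.0728,0.1226,952825
C0_sel50,0.020,0.1208,943344
C1_157,0.0776,0.1297,951390
C1_sel25,0.052,0.1250,947868
C2_91,0.0765,0.1276,953199
C2_sel18,0.043,0.1228,953453
C3_44,0.0588,0.0973,954058
C3_sel22,0.063,0.0923,954924
all_entries,0.0740,0.1245,954960
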