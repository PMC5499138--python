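chrom,allele_swaps,poly_to_mono,mono_to_poly,total_changed,pct_changed,total_snps
1,12,124,7,143,0.096,148745
2,12,105,1,118,0.102,115152
3,7,97,1,105,0.097,108195
4,11,64,1,76,0.080,94716
5,20,166,9,195,0.177,110303
6,12,91,3,106,0.139,76450
7,7,90,2,99,0.123,80514
8,10,86,0,96,0.118,81427
9,21,71,2,94,0.130,72355
10,11,74,3,88,0.131,67103
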