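chrom,category,cluster_size,n_clusters
1,allele_swap,4,1
1,poly_to_mono,3,3
1,poly_to_mono,4,4
1,poly_to_mono,6,2
1,mono_to_poly,4,1
2,allele_swap,3,1
2,allele_swap,5,1
2,poly_to_mono,3,4
2,poly_to_mono,4,1
2,poly_to_mono,5,1
2,poly_to_mono,6,1
3,poly_to_mono,7,1
3,poly_to_mono,9,1
4,poly_to_mono,3,2
4,poly_to_mono,4,2
4,poly_to_mono,5,1
4,poly_to_mono,7,1
5,allele_swap,3,2
5,poly_to_mono,3,9
5,poly_to_mono,4,3
5,poly_to_mono,5,2
5,poly_to_mono,7,1
5,poly_to_mono,8,1
5,mono_to_poly,5,1
6,poly_to_mono,3,1
6,poly_to_mono,4,3
6,poly_to_mono,5,2
6,poly_to_mono,6,1
6,mono_to_poly,3,1
7,poly_to_mono,3,2
7,poly_to_mono,4,2
7,poly_to_mono,5,1
7,poly_to_mono,6,1
8,allele_swap,3,2
8,poly_to_mono,3,4
8,poly_to_mono,4,2
8,poly_to_mono,5,2
9,allele_swap,7,1
9,poly_to_mono,3,2
9,poly_to_mono,4,1
9,poly_to_mono,5,3
9,poly_to_mono,7,1
10,allele_swap,3,1
10,poly_to_mono,3,4
10,poly_to_mono,4,3
10,poly_to_mono,8,1
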