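chrom	snps	bins	map_cm
1H	346	195	133.3
2H	383	231	153.2
3H	385	231	154.9
4H	237	135	115.5
5H	474	265	173.3
6H	362	188	122.7
7H	450	253	143.9
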