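chrom	sequenced	anchored
1H	6983	6410
2H	8969	8195
3H	8807	8303
4H	8306	7783
5H	8358	7573
6H	7886	6476
7H	7970	6842
0H	8031	6714
non_mtp	21765	20397
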