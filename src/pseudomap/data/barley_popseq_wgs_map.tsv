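chrom	contigs	length_mb
1H	74184	123.7
2H	130436	202.6
3H	119131	187.6
4H	96642	170.6
5H	117314	177.8
6H	121384	168.4
7H	132085	190.2
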