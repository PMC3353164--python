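category	unique	redundant
exon_antisense	121519	301729
exon_sense	211613	616910
intron_antisense	239906	447068
intron_sense	410965	880478
miRNA	1426	1030053
rRNA	97064	1858381
repeat	524801	1094074
siRNA	283866	2927927
snRNA	5704	25039
snoRNA	3790	12647
tRNA	23935	842565
unann	4815596	8865829
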