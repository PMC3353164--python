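family	amur_seq	summer_black_seq
MiR159a/b	CCTTGGAGTGAAGGGAGCT	TTGGAGTGAAGGGAGCTCTC
MiR167a	TGAAGCTGCCAGCATGATCT	TGAAGCTGCCAGCATGATCTG
MiR169e	TAGCCAAGGATGACTTGCCT	TAGCCAAGGATGACTTGCCTGC
MiR169u	TGAGTCAAGGATGACTTGCCG	TGAGTCAAGGATGACTTGCCGT
MiR319b	TTGGACTGAAGGGAGCTCCCT	TTGGACTGAAGGGAGCTCCC
MiR319c/f	TGCTTGGACTGAAGGGAG	TTGGACTGAAGGGAGCTCCC
MiR393a	TCCAAAGGGATCGCATTGAT	TTCCAAAGGGATCGCATTGAT
MiR397a/b	TCATTGAGTGCAGCGTTGATG	CATTGAGTGCAGCGTTGATGA
MiR398a	TTCTCAGGTCACCCCTTTGGG	TGTGTTCTCAGGTCACCCCTT
MiR399a	CAAAGGAGAATTGCCCTGTTA	TGCCAAAGGAGAATTGCC
MiR399b/c	TGCCAAAGGAGAGTTGCCCTG	GCCAAAGGAGAGTTGCCCT
MiR399d	AAAGGAGATTTGCTCGTGAAT	TCTGCCAAAGGAGATTTGCTC
MiR399i	CGCCAAAGGAGAGTTGCCCTG	CGCCAAAGGAGAGTTGCCC
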