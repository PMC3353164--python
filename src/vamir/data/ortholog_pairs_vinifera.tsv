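family	amur_seq	vinifera_seq
MiR156a/i	TTGACAGAAGAGAGGGAGCAC	TGACAGAAGAGAGGGAGCAC
MiR159a/b	CCTTGGAGTGAAGGGAGCT	CTTGGAGTGAAGGGAGCTCTC
MiR166a	TCTCGGACCAGGCTTCATTCC	TCGGACCAGGCTTCATTCCTG
MiR166c/e/h	TCGGACCAGGCTTCATTCCCC	TCGGACCAGGCTTCATTCCCCC
MiR166d/f/g	TCGGACCAGGCTTCATTCCCC	TCGGACCAGGCTTCATTCCCCT
MiR167a	TGAAGCTGCCAGCATGATCT	TGAAGCTGCCAGCATGATCTG
MiR167b/e	TGAAGCTGCCAGCATGATCTAA	TGAAGCTGCCAGCATGATCTA
MiR169b/h	TGAGCCAAGGATGGCTTGCCGT	TGAGCCAAGGATGGCTTGCCG
MiR169e	TAGCCAAGGATGACTTGCCT	TAGCCAAGGATGACTTGCCTG
MiR169i	TGAGCCAAGGATGACTGGCCGT	GAGCCAAGGATGACTGGCCGT
MiR169l	TGAGCCAAGGATGACTTGCCG	GAGCCAAGGATGACTTGCCGT
MiR169m/p	TGAGCCAAGGATGACTTGCCG	GAGCCAAGGATGACTTGCCGG
MiR169n/q	TAGAGCCAAGGATGACTTGCCG	GAGCCAAGGATGACTTGCCGG
MiR169o	TGAGCCAAGGATGACTTGCCG	GAGCCAAGGATGACTTGCCGC
MiR169r	TGAGTCAAGGATGACTTGCCGA	TGAGTCAAGGATGACTTGCCG
MiR169t	CGAGTCAAGGATGACTTGCCGA	CGAGTCAAGGATGACTTGCCG
MiR169x	TAGCCAAGGATGACTTGCCT	TAGCCAAGGATGACTTGCCTA
MiR171a	TGATTGAGCCGTGCCAATATC	TTGAGCCGTGCCAATATCATG
MiR171b	TTGAGCCGCGTCAATATCTCC	TGATTGAGCCGCGTCAATATC
MiR171c/d	TGATTGAGCCGTGCCAATATC	TTGAGCCGTGCCAATATCACG
MiR171e	TTGAGCCGCGCCAATATCACT	TGATTGAGCCGCGCCAATATC
MiR171h	TTGAGCCGCGCCAATATCCCG	TGGTTGAGCCGCGCCAATATC
MiR172d	TGAGAATCTTGATGATGCTGC	AGAATCTTGATGATGCTGCAT
MiR319b	TTGGACTGAAGGGAGCTCCCT	CTTGGACTGAAGGGAGCTCCC
MiR319c/f	TGCTTGGACTGAAGGGAG	CTTGGACTGAAGGGAGCTCCC
MiR319g	TTGGACTGAAGGGAGCTCCC	ATTGGACTGAAGGGAGCTCCC
MiR393a/b	TCCAAAGGGATCGCATTGAT	TCCAAAGGGATCGCATTGATCC
MiR396a	TTCCACAGCTTTCTTGAA	TTCCACAGCTTTCTTGAACTA
MiR396b	TTCCACAGCTTTCTTGAA	TTCCACAGCTTTCTTGAACT
MiR396c/d	TTCCACAGCTTTCTTGAA	TTCCACAGCTTTCTTGAACTG
MiR398a	TTCTCAGGTCACCCCTTTGGG	TGTGTTCTCAGGTCACCCCTT
MiR399a	CAAAGGAGAATTGCCCTGTTA	TGCCAAAGGAGAATTGCCCTG
MiR399d	AAAGGAGATTTGCTCGTGAAT	TGCCAAAGGAGATTTGCTCGT
MiR399h	TGCCAAAGGAGAATTGCC	TGCCAAAGGAGAATTGCCCTG
MiR403a/b/c/d/e/f	TTAGATTCACGCACAAACT	TTAGATTCACGCACAAACTCG
MiR482	TCTTTCCTACTCCTCCCATTCC	CCTACTCCTCCCATTCC
MiR535a/b/c/d/e	TGACAACGAGAGAGAGCACGC	TGACAACGAGAGAGAGCACGCT
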