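locus	fwd_genomic	fwd_converted	rev_genomic	rev_converted
Grb10	GAGAAAAAAGGTTCAGTTACCCCAG(A/G)	GAGAAAAAAGGTTTAGTTATTTTAG(A/G)	CCTCCCGAAATCTGCAATGGTC	CCTCCCAAAATCTACAATAATC
H19	ATTCACAAATGGCAATGCTGTGG	ATTTATAAATGGTAATGTTGTGG	CCTCATGAAGCCCATGACTAT	CCTCATAAAACCCATAACTAT
Igf2r	CAGAGGATTTTAGCACAACTCCAA	TAGAGGATTTTAGTATAATTTTAA	CACTTTTGAGCTTGCCTCTCTTGC	CACTTTTGAGCTTGCCTCTCTTGC
Impact	CTGCATAGTTTTGCTCTCATAAGTG	TTGTATAGTTTTGTTTTTATAAGTG	GGCCTGCTCATGTGACAATGCGGC	AACCTACTCATATAACAATACAAC
Lit1	CAAGGTGAGTGGCCTAGGAC	TAAGGTGAGTGGTTTAGGAT	AATCCCCCACACCTGAATTC	AATCCCCCACACCTAAATTC
Mest	GGGTGTTTTATGTCTTCCAGGG(T/G)	GGGTGTTTTATGTTTTTTAGGG(T/G)	CCCAGATTCTAGTGAAGAAAGCCTTCCCAT	CCCAAATTCTAATAAAAAAAACCTTCCCAT
Peg3	GGTGCATCTTTACTGCCAACTAGCAAAG	GGTGTATTTTTATTGTTAATTAGTAAAG	CAGGTTTGCTGCACAGGCTTATCC	CAAATTTACTACACAAACTTATCC
Peg10	GCAAAGTGACTGGCTCTGCACTCTTAAGTG	GTAAAGTGATTGGTTTTGTATTTTTAAGTG	TTGGTTACTCTCCTGCAGCTTTCCAAATT	TTAATTACTCTCCTACAACTTTCCAAATT
Snrpn	GCAATTATATCCATTATTCCAGATTGACAGTGA(T/G)	GTAATTATATTTATTATTTTAGATTGATAGTGA(T/G)	ATAGGATGCACTTTCACTACTAGAATCC	ATAAAATACACTTTCACTACTAAAATCC
Zac1	GGGTAGGTAAGTAGTGACAA	GGGTAGGTAAGTAGTGATAA	CCTAAAACACCAAAGTAGCA	CCTAAAACACCAAAATAACA
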