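locus	snp_index	allele_b6	allele_cast	sources	identifier	validation_status	note
Grb10	1	A	G	dbSNP		validated	degenerate forward-primer 3' base covers this SNP
Grb10	2	.	.	dbSNP		failed
Grb10	3	.	.	dbSNP		failed
H19	1	G	-	dbSNP		validated	deletion in CAST
H19	2	G	A	dbSNP		validated
H19	3	A	G	dbSNP		validated
H19	4	.	.	dbSNP		failed
Igf2r	1	G	A	dbSNP		validated
Igf2r	2	A	G	dbSNP		validated
Igf2r	3	.	.	dbSNP		failed
Igf2r	4	.	.	dbSNP		failed
Igf2r	5	.	.	dbSNP		failed
Igf2r	6	.	.	dbSNP		failed
Igf2r	7	.	.	dbSNP		failed
Igf2r	8	.	.	dbSNP		failed
Igf2r	9	.	.	dbSNP		failed
Igf2r	10	.	.	dbSNP		failed
Igf2r	11	.	.	dbSNP		failed
Igf2r	12	.	.	dbSNP		failed
Igf2r	13	.	.	dbSNP		failed
Impact	1	T	A	dbSNP		validated
Impact	2	A	G	dbSNP		validated
Impact	3	T	A	dbSNP		validated
Impact	4	.	.	dbSNP		failed
Impact	5	.	.	dbSNP		failed
Impact	6	.	.	dbSNP		failed
Impact	7	.	.	dbSNP		failed
Impact	8	.	.	dbSNP		failed
Impact	9	.	.	dbSNP		failed
Impact	10	.	.	EVA		failed	unnamed record absent from dbSNP
Lit1	1	G	A	dbSNP		validated
Lit1	2	.	.	dbSNP		failed
Lit1	3	.	.	dbSNP		failed
Lit1	4	.	.	dbSNP		failed
Lit1	5	.	.	dbSNP		failed
Lit1	6	.	.	dbSNP		failed
Lit1	7	.	.	dbSNP		failed
Lit1	8	.	.	dbSNP		failed
Lit1	9	.	.	dbSNP		failed
Lit1	10	.	.	dbSNP		failed
Lit1	11	.	.	dbSNP		failed
Lit1	12	.	.	EVA		failed	unnamed record absent from dbSNP
Mest	1	T	G	dbSNP		validated	degenerate forward-primer 3' base covers this SNP
Mest	2	.	.	dbSNP		failed
Peg3	1	T	G	dbSNP		validated
Peg3	2	.	.	dbSNP		failed
Peg3	3	.	.	dbSNP		failed
Peg3	4	.	.	dbSNP		failed
Peg10	1	C	A	dbSNP		validated
Peg10	2	.	.	dbSNP		failed
Peg10	3	.	.	dbSNP		failed
Peg10	4	.	.	dbSNP		failed
Peg10	5	.	.	dbSNP		failed
Peg10	6	.	.	dbSNP		failed
Peg10	7	.	.	dbSNP		failed
Peg10	8	.	.	dbSNP		failed
Peg10	9	.	.	dbSNP		failed
Peg10	10	.	.	dbSNP		failed
Peg10	11	.	.	dbSNP		failed
Peg10	12	.	.	dbSNP		failed
Peg10	13	.	.	dbSNP		failed
Peg10	14	.	.	dbSNP		failed
Peg10	15	.	.	dbSNP		failed
Peg10	16	.	.	dbSNP		failed
Peg10	17	.	.	dbSNP		failed
Peg10	18	.	.	dbSNP		failed
Peg10	19	.	.	dbSNP		failed
Peg10	20	.	.	dbSNP		failed
Peg10	21	.	.	dbSNP		failed
Peg10	22	.	.	dbSNP		failed
Peg10	23	.	.	EVA		failed	unnamed record absent from dbSNP
Snrpn	1	T	G	novel		validated	novel SNP absent from all three databases; degenerate forward-primer 3' base covers it
Snrpn	2	TTT	-	dbSNP		validated	three-base deletion in CAST
Snrpn	3	T	A	dbSNP		validated
Snrpn	4	G	A	dbSNP		validated
Snrpn	5	G	T	dbSNP		validated
Snrpn	6	.	.	dbSNP		failed
Snrpn	7	.	.	dbSNP		failed
Snrpn	8	.	.	dbSNP		failed
Snrpn	9	.	.	dbSNP		failed
Snrpn	10	.	.	dbSNP		failed
Snrpn	11	.	.	dbSNP		failed
Snrpn	12	.	.	dbSNP		failed
Zac1	1	A	G	dbSNP		validated
Zac1	2	.	.	dbSNP		failed
Zac1	3	.	.	dbSNP		failed
Zac1	4	.	.	dbSNP		failed
Zac1	5	.	.	dbSNP		failed
Zac1	6	.	.	dbSNP		failed
Zac1	7	.	.	dbSNP		failed
Zac1	8	.	.	dbSNP		failed
Zac1	9	.	.	dbSNP		failed
Zac1	10	.	.	EVA		failed	unnamed record absent from dbSNP
Zac1	11	.	.	EVA		failed	unnamed record absent from dbSNP
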