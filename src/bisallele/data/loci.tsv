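locus	imprint_direction	strand_note	amplicon_bp	cpg_count	reported_snps	validated_snps
Grb10	maternal_methylated	as_assembly	390	31	3	1
H19	paternal_methylated	reversed	291	9	4	3
Igf2r	maternal_methylated	as_assembly	549	33	13	2
Impact	maternal_methylated	as_assembly	433	17	10	3
Lit1	maternal_methylated	reversed	420	17	12	1
Mest	maternal_methylated	as_assembly	136	4	2	1
Peg3	maternal_methylated	as_assembly	228	11	4	1
Peg10	maternal_methylated	as_assembly	663	54	23	1
Snrpn	maternal_methylated	reversed	356	16	11	4
Zac1	maternal_methylated	as_assembly	578	33	11	1
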