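chrom	pos	rsid	ref	alt	cll_cases	in_compound_het_patient
8	30922465	.	T	G	1	yes
8	30922580	.	G	A	1	no
8	30954292	rs569266355	A	G	1	no
8	31012237	rs78488552	C	G	6	yes
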