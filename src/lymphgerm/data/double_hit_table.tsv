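case_id	zygosity	gene	variant_type	rs_ids
147	germline_double_hit	ARID1B	missense	rs1378351788;rs200808642
1416	germline_double_hit	ATM	missense_and_frameshift_deletion	.
1196	germline_double_hit	CBFA2T3	missense	rs143704547;rs561624190
4167381	germline_double_hit	EPPK1	missense	rs144123426;.
544	germline_double_hit	FAT1	missense	rs377498159;.
1078	germline_double_hit	FAT1	missense	rs201279606;rs201751862
4190784	germline_double_hit	GLI1	missense	rs200306754;.
1260	germline_double_hit	IL6ST	missense	rs191125510;rs199939306
1565	germline_double_hit	MYH9	missense	rs56200894;.
772	germline_double_hit	NCOR1	missense	rs118021690;.
4159421	germline_double_hit	PIM1	missense	.
284	germline_double_hit	RNF213	missense	rs202143169;rs141301945
63	germline_double_hit	WRN	missense	rs78488552;.
757	germline_double_hit	ZFHX3	missense	rs148334947;rs147016640
1191	germline_double_hit	ZFHX3	missense	rs148334947;.
4126692	homozygote	AKAP9	missense	rs61757664
1298	homozygote	ERBB3	missense	rs55699040
1309	homozygote	GLI1	nonsense	.
308	homozygote	MYH9	missense	rs139134727
325	homozygote	MYO5A	missense	rs147898420
4115001	homozygote	NTRK3	missense	.
1568	homozygote	PDZRN3	missense	rs141385664
7	homozygote	SFRP4	missense	rs147145122
1437	homozygote	SYNE1	missense	.
396	homozygote	TSC1	missense	rs118203504
1052;1295	homozygote	ZCCHC8	missense	rs150057798
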