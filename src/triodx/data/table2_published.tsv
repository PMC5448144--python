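assay	n_affected	variant_class	tier	count	printed_percent
WES	127	snv_indel	P	26	20.4
WES	127	snv_indel	LP	12	9.4
WES	127	snv_indel	VUS	14	11.0
WES	127	cnv	P	2	1.6
WES	127	cnv	LP	0	0
WES	127	cnv	VUS	0	0
WGS	244	snv_indel	P	44	18.0
WGS	244	snv_indel	LP	10	4.1
WGS	244	snv_indel	VUS	25	10.2
WGS	244	cnv	P	5	2.0
WGS	244	cnv	LP	1	0.4
WGS	244	cnv	VUS	3	1.2
total	371	snv_indel	P	70	18.9
total	371	snv_indel	LP	22	5.9
total	371	snv_indel	VUS	39	10.5
total	371	cnv	P	7	1.9
total	371	cnv	LP	1	0.3
total	371	cnv	VUS	3	0.8
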