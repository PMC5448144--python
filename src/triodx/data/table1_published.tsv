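section	group	individuals	numerator	denominator	printed_percent
age	2-5	96	26	96	27.1
age	6-12	165	42	165	25.4
age	13-18	61	20	61	32.8
age	19-40	47	15	47	32.0
age	>40	2	0	2	0.00
sex	male	214	52	214	24.3
sex	female	157	51	157	32.5
clinical	intellectual_disability_moderate	298	82	298	27.5
clinical	intellectual_disability_severe	44	11	44	25
clinical	speech_delay	255	69	255	27.1
clinical	seizures	168	52	168	30.9
clinical	facial_dysmorphism	112	33	112	29.5
clinical	autism_spectrum_disorder	95	18	95	18.9
clinical	hypotonia	75	26	75	34.6
clinical	positive_brain_mri	65	18	64	28.1
clinical	macrocephaly	36	9	36	25.0
clinical	microcephaly	34	16	34	47.0
clinical	adhd	27	7	27	25.9
clinical	failure_to_thrive	22	6	22	27.3
clinical	short_stature	18	8	18	44.4
prior_testing	microarray	222	61	222	27.5
prior_testing	single_gene_panel	142	43	142	30.3
prior_testing	karyotype	108	39	108	36.1
prior_testing	fragile_x	101	28	101	27.7
prior_testing	mito_dna_screen	28	7	28	25.0
structure	trio	309	90	309	29.1
structure	duo	42	8	42	19.0
structure	singleton	20	3	20	15.0
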