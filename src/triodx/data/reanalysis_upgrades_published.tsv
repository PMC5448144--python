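gene	individuals	variant	old_tier	new_tier	reason
DDX3X	00075-C	c.745G>T (p.Glu249Ter)	VUS	pathogenic	publication
EBF3	00006-C	c.1101+1G>T	VUS	pathogenic	gene_matching
EBF3	00032-C	c.530C>T (p.Pro177Leu)	VUS	pathogenic	gene_matching
KIAA2022	00082-C	c.2999_3000delCT (p.Ser1000Cysfs)	VUS	pathogenic	publication
TCF20	00078-C	c.5385_5386delTG (p.Cys1795Trpfs)	VUS	pathogenic	publication
ARID2	00026-C	c.1708delT (p.Cys570Valfs)	NR	pathogenic	publication
CDK13	00253-C	c.2525A>G (p.Asn842Ser)	NR	pathogenic	publication
CLPB	00127-C	c.1222A>G (p.Arg408Gly)+c.1249C>T (p.Arg417Ter)	NR	pathogenic	publication
FGF12	00074-C	c.341G>A (p.R114H)	NR	pathogenic	publication
MTOR	00040-C	c.4785G>A (p.Met1595Ile)	NR	pathogenic	publication
MTOR	00028-C,00028-C2	c.5663T>G (p.Phe1888Cys)	NR	pathogenic	filter_relaxation
HDAC8	00001-C	c.737+1G>A	NR	likely_pathogenic	filter_relaxation
LAMA2	00055-C,00055-S	c.715C>T (p.Arg239Cys)	NR	likely_pathogenic	phenotype_clarification
MAST1	00270-C	c.278C>T (p.Ser93Leu)	NR	likely_pathogenic	gene_matching
SUV420H1	00056-C	c.2497G>T (p.Glu833X)	NR	likely_pathogenic	publication
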