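# Day-10 whole-population mutation matrix from pooled-read polymorphism
# calling. Cells hold the fraction of sequencing reads supporting the
# mutation in each surviving population with detectable phage DNA; empty
# cells mean the allele was not detected in that population.
position	bp_change	aa_change	codon_change	impact	gene_no	product	Pop+2	Pop+4	Pop+6	Pop+8
11,048	T→G	R116R	CGT→CGG	Synonymous	33	Portal protein	6.7%	7.6%	6.9%
19,245	T→G	None, intergenic	-	Not applicable	46–47	TMP-TMP protein		9.5%
19,261	A→T	V3V	GTA→GTT	Synonymous	47	Tail tape measure protein	5.6%	5.7%	5.4%
19,272	C→G	A7G	GCT→GGT	Nonpolar to polar	47	Tail tape measure protein		5.0%
28,296	C→A	H1186N	CAT→AAT	Positive to neutral, large to small	52	Tail fiber protein		100%
28,321	C→A	T1194K	ACG→AAG	Neutral to positive, small to large	52	Tail fiber protein		100%
28,380	C→A	Q1214K	CAA→AAA	Neutral to positive, small to large	52	Tail fiber protein		100%	100%	100%
28,381	A→G	Q1214R	CAA→CGA	Neutral to positive, small to large	52	Tail fiber protein	100%
28,383	G→A	A1215T	GCT→ACT	Nonpolar to polar	52	Tail fiber protein				100%
28,446	C→A	L1236I	CTT→ATT	Nonsynonymous conserved	52	Tail fiber protein			100%
28,463	C→G	N1241K	AAC→AAG	Neutral to positive, small to large	52	Tail fiber protein	100%		100%
28,469	C→A	N1243K	AAC→AAA	Neutral to positive, small to large	52	Tail fiber protein	100%
31,700	+82 bp	+82 bp (2281/2373 nt)	-	Frame-shifting insertion	57	Tail fiber protein				77.2%
31,718	+86 bp	+86 bp (2263/2373 nt)	-	Frame-shifting insertion	57	Tail fiber protein			63.6%
31,917	C→A	K688N	AAG→AAT	Positive to neutral, small to large	57	Tail fiber protein			100%	100%
38,211	Δ1 bp	None, intergenic	-	Not applicable	61–62	Endonuclease, hypothetical protein		100%
39,132	T→G	F192V	TTT→GTT	Large to small	63	Methylase		5.0%	5.3%
39,139	C→A	S194Y	TCT→TAT	Polar to nonpolar, small to large	63	Methylase		6.6%	6.9%
48,412	G→T	S15*	TCA→TAA	Early stop codon	85	Hypothetical protein	5.8%	5.1%	5.4%
48,438	G→T	F6L	TTC→TTA	Large to small	85	Hypothetical protein	8.9%	8.6%	8.9%
48,444	T→A	L4F	TTA→TTT	Small to large	85	Hypothetical protein	6.4%	5.5%	5.5%
48,446	A→C	L4V	TTA→GTA	Nonsynonymous conserved	85	Hypothetical protein	10.6%	9.9%
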