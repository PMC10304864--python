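# Day-10 phage isolate mutation matrix (one sequenced isolate per surviving
# population). An x/X marks presence of the mutation in that isolate.
# Starred positions were also detected as polymorphisms in the ancestral
# phage stock (see stock_polymorphisms.tsv).
position	bp_change	aa_change	codon_change	impact	gene_no	product	RB-020	RB-022	RB-024	RB-028	ET013
28,296	C→A	H1186N	CAT→AAT	Positive to neutral, large to small	52	Tail fiber protein		x
28,321	C→A	T1194K	ACG→AAG	Neutral to positive, small to large	52	Tail fiber protein		x
28,380	C→A	Q1214K	CAA→AAA	Neutral to positive and small to large	52	Tail fiber protein		x		x	x
28,381	A→G	Q1214R	CAA→CGA	Neutral to positive and small to large	52	Tail fiber protein	x
28,383	G→A	A1215T	GCT→ACT	Nonpolar to polar	52	Tail fiber protein				x
28,411	G→T	G1224V	GGA→GTA	Polar to nonpolar	52	Tail fiber protein					x
28,463	C→G	N1241K	AAC→AAG	Neutral to positive, small to large	52	Tail fiber protein	x		x
28,469	C→A	N1243K	AAC→AAA	Neutral to positive, small to large	52	Tail fiber protein	x				X
31,917	C→A	K688N	AAG→AAT	Positive to neutral, small to large	57	Tail fiber protein			x	x	X
35,091	(A)8→7	None, intergenic	-	Not applicable	58–59	DNA primase, transcrip. regulator		x
38,215	(T)5→4	None, intergenic	-	Not applicable	61–62	Endonuclease, hyp. protein		x
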