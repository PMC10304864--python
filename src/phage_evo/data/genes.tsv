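# Gene models of the 49,223 bp fixture genome. Spans whose basis is
# "derived" are pinned by the mutation tables (codon numbering and
# coding-strand nucleotide indices of the observed mutations); "assumed"
# spans are minimal plausible stubs consistent with every genic/intergenic
# assignment in the tables.
gene_no	start	end	strand	product	basis
33	10701	11900	+	Portal protein	derived start, assumed end
46	18000	19241	+	Tail tape measure protein	assumed
47	19253	19852	+	Tail tape measure protein	derived start, assumed end
52	24741	28516	+	Tail fiber protein	derived
57	31608	33980	-	Tail fiber protein	derived
58	34200	35000	+	DNA primase	assumed
59	35200	35802	+	Transcriptional regulator	assumed
60	36000	36500	+	Hypothetical protein	assumed
61	37500	38099	+	Endonuclease	assumed
62	38300	38500	+	Hypothetical protein	assumed
63	38559	39458	+	Methylase	derived start, assumed end
85	48306	48455	-	Hypothetical protein	derived end, assumed start
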