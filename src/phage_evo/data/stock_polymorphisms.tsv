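# Polymorphisms detected in the ancestral phage stock by deep resequencing
# (663x mean coverage). Any evolved mutation matching one of these on
# (position, change) is treated as preexisting rather than parallel.
position	bp_change	source_id	frequency
28,380	C→A	ancestral_stock	30.4%
31,648	+86 bp	ancestral_stock	15.9%
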