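# phage-evo

Analysis toolkit for phage experimental-evolution studies: strand-aware
mutation annotation, parallel-evolution statistics, adsorption-rate
estimation, plaque-plate image quantification, and population-dynamics
summaries.

The package targets the common design in which replicate populations of a
lytic phage are serially passaged with their bacterial host, populations
and clonal isolates are resequenced against the ancestral reference, and
the phenotypic consequences are measured by adsorption assays and plaque
morphology. It was built around a TolC-dependent coliphage system (a
49.2 kb siphophage evolving with *E. coli* K-12), but every module takes
ordinary FASTA/TSV/CSV/PNG inputs and works for any comparable experiment.

## What it computes

**Mutation annotation.** Mutation tables (SNVs `C→A`, homopolymer run
changes `(A)8→7`, insertions `+82 bp`, deletions `Δ1 bp`, with optional
read-support frequencies) are mapped onto gene models with full strand
handling. For a reverse-strand gene, the coding nucleotide index of genome
position *p* is `end − p + 1`, codon number `⌈nt/3⌉`, and the reference
codon is read from the reverse complement; alternate alleles (always stated
on the forward strand) are complemented into the coding frame. Effects are
classed synonymous / nonsynonymous / nonsense / frameshift / in-frame
indel / intergenic, and amino-acid substitutions are further classified as
radical or conservative by charge, polarity and volume.

**Parallel evolution.** For a gene of length `L_gene` hit in `k` of the
replicate populations, the conservative same-gene probability under uniform
placement, conditioning on the first hit, is

    P = (L_gene / L_genome)^(k − 1)

reported both exactly and rounded to one significant figure for display.
Two independent nulls accompany it: the closed form
`P = [1 − (1 − L_gene/L_genome)^m]^k` for `m` uniform mutations per
population, and a seeded Monte-Carlo placement simulation (optionally
conditioned on the first population hitting).

**Adsorption kinetics.** From paired titers under the free-phage decay
model `T1/T0 = exp(−δ N t)`, the rate constant is
`δ = −ln(T1/T0) / (t N)` in mL·cell⁻¹·h⁻¹, with plate-count → titer
arithmetic, detection-limit bounds, t-distribution 95% CIs over replicates,
unpaired t tests, and Holm–Bonferroni correction.

**Plaque imaging.** The classic particle-analysis pipeline: scale
calibration from the 86 mm plate diameter, rolling-ball background
subtraction (radius 50 px), dual-intensity thresholding (180–238) inside a
72.24 mm elliptical region, 8-connected components filtered by area
(0.2–64 mm²) and circularity (`4πA/P²`, 0.20–1.00), and per-sample size
statistics.

**Dynamics.** Titer trajectories with a plating detection limit (default
100 PFU/mL), survival/extinction classification (extinct iff below
detection with no later recovery), cross-streak resistance fractions with
their survey detection limit `(1 − 1/n)·100%`, efficiency of plating, and
experiment-wide test accounting.

**Synthetic data.** Seeded generators for every input: a 49,223 bp fixture
genome whose gene models and embedded reference codons are pinned by the
bundled isolate/population mutation tables (and verified on every build by
re-annotation), uniform null mutation tables, Poisson-sampled adsorption
counts, rendered plate images with known plaque diameters, and
titer/resistance trajectories with known fates.

## Worked example

```python
from phage_evo import mutation_annotation as ma, parallelism as par, synthetic_data as sd

fixture = sd.build_fixture_genome(seed=0)

summary = ma.summarize_isolates(fixture.isolate_annotations)
print(summary.n_unique_mutations)               # 11
print(summary.n_unique_aa_changes)              # 9
print(summary.mean_mutations_per_isolate)       # 3.4
print(summary.nonsynonymous_isolates_per_gene)  # {'52': 5, '57': 3}

p52 = par.conservative_parallel_probability(L_gene=3776, L_genome=49223, k_hit=5)
print(p52.value, p52.display)                   # 3.46e-05  0.00003
p57 = par.conservative_parallel_probability(L_gene=2372, L_genome=49223, k_hit=3)
print(p57.value, p57.display)                   # 0.00232   0.002

record = ma.MutationRecord(genome_position=31917, change_kind="snv",
                           ref_base="C", alt_base="A", source_id="RB-024")
ann = ma.annotate_mutation(record, fixture.genome, fixture.annotation)
print(ann.gene_no, ann.ref_codon, ann.alt_codon, ann.aa_label, ann.effect)
# 57 AAG AAT K688N nonsynonymous
```

All five sequenced isolates carry a nonsynonymous change in tail-fiber
gene 52 and three of five in tail-fiber gene 57; the conservative
probabilities of that degree of same-gene parallelism arising without
selection are 0.00003 and 0.002, i.e. the repeated hits are strong evidence
of adaptation. The last lines show the strand handling: a forward-strand
C→A at position 31,917 falls in the third codon position of reverse-strand
gene 57 and reads as AAG→AAT (K688N) in the coding frame.

A CLI mirrors the library (`phage-evo annotate-locus | annotate |
parallelism | adsorption | plaques | dynamics | synth ...`); run
`phage-evo --help`.

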