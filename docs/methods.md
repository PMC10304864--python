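# Methods notes

This note records the models behind each module, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
places where the design was genuinely open.

## Coordinate model

All genome coordinates are 1-based and inclusive. Gene models are spans on
the forward strand with an orientation; codon numbering runs from the
gene's own 5′ end. For a reverse-strand gene the coding nucleotide index of
genome position *p* is `end − p + 1`, so codon *c* occupies forward-strand
positions `end − 3c + 1 … end − 3c + 3` and its reference codon is the
reverse complement of that slice. Mutation records always state alleles on
the forward strand; complementation into the coding frame happens during
annotation, never in the input.

Gene spans whose length is not a multiple of 3 are translated over complete
codons only; positions in the trailing 1–2 nt get no codon context (with a
warning). This accommodates annotations whose printed ORF lengths include
ambiguity about the stop codon — tail-fiber gene 52 in the bundled fixture
is 3,776 bp, deliberately kept off-frame because that is the length the
source annotation reports. The bundled gene 57 span is 2,373 nt
(31,608..33,980, reverse), the value consistent with the coding-strand
insertion indices in the population table (2281/2373 and 2263/2373); the
source annotation elsewhere reports other lengths for this ORF (3,372 and
2,372 bp), and the parallelism computation for gene 57 keeps 2,372 as its
numerator because that is the figure the probability was historically
computed with. The two are not reconciled further.

Overlapping gene models (e.g. tape-measure ORFs sharing a frame through
ribosomal slippage) are out of scope: the locator assigns the first
containing gene and warns.

## Amino-acid property classes

Substitutions are classified by charge (positive {K,R,H}, negative {D,E},
neutral otherwise), polarity (polar {C,D,E,G,H,K,N,Q,R,S,T,W,Y} vs
nonpolar {A,F,I,L,M,P,V}) and volume (small {A,C,D,G,I,L,N,P,S,T,V} vs
large {E,F,H,K,M,Q,R,W,Y}); a substitution changing no class is
"conserved". Binary volume splits differ between published schemes mainly
in where the mid-sized branched residues sit; this package's default places
L and I in the small class, the assignment that maximises agreement with
the impact labels in the bundled tables (12 of 16 reproduce exactly; the
four exceptions — Q1214K/Q1214R, K688N, S194Y — are mutually inconsistent
under *any* single three-way table and are flagged in
`synthetic_data.DISCREPANT_IMPACT_LABELS`). The table is user-overridable
via YAML/JSON for analyses that prefer a different convention.

## Parallelism statistics

The conservative same-gene probability uses exponent `k_hit − 1`,
interpreted as conditioning on the first observed hit: having seen one
population hit the gene, the probability that the remaining `k − 1`
independently place a uniform mutation inside it is
`(L_gene/L_genome)^(k−1)`. Display rounding is one significant figure in
plain decimal (3.46×10⁻⁵ → "0.00003").

The exact null `[1 − (1 − L/G)^m]^k` treats each population as placing
`m` uniform, independent mutations. Note it is *not* always larger than
the conservative value: at `m = 1` it equals `(L/G)^k`, one factor of
`L/G` smaller. It exceeds the conservative value whenever the
per-population hit probability `h = 1 − (1 − L/G)^m` satisfies
`h ≥ (L/G)^((k−1)/k)` — on realistic settings, whenever `m ≥ 2`. The
Monte-Carlo estimator draws integer positions uniformly on `1..L_genome`
with the gene at `1..L_gene` (without loss of generality), in memory-bounded
chunks, and is deterministic under a fixed seed; its conditional mode with
`m = 1` converges on the conservative formula, which is the package's
internal consistency check between the two routes.

The uniform-placement null ignores mutational-spectrum bias (e.g. the
C→A enrichment visible in the bundled tables) and local rate
heterogeneity; its probabilities are therefore anti-conservative for
spectra concentrated on few sites. This is a documented limitation, not a
correction the package attempts.

## Adsorption

Rates follow `δ = −ln(T1/T0)/(t·N)` with `t` in hours and `N` in
cells/mL, giving mL·cell⁻¹·h⁻¹ (a `--per-minute` display option divides
by 60 for comparison with classical adsorption constants). Confidence
intervals are t-distribution intervals over replicate rate estimates, not
error propagation from counts, matching the replicate-level design of the
assays (n = 9). Group comparisons are Student (equal-variance) unpaired
t tests; one-tailed tests halve the two-sided p when the observed
direction matches the hypothesis. Holm–Bonferroni is delegated to
statsmodels, with the hand-stepped procedure kept as the test oracle. A
no-cell control series, when supplied, replaces T0 with the control's T1
as the no-adsorption baseline (off by default: the quantitative role of
the control is a protocol choice, not a fixed convention).

## Plaque imaging

The pipeline mirrors the standard particle-analysis protocol: convert to
8-bit grayscale, subtract a rolling-ball background (radius 50 px),
threshold an intensity window inside a centred 72.24 mm elliptical region,
extract 8-connected components, and filter by area 0.2–64 mm² and
circularity 0.20–1.00. Circularity is `4πA/P²` with the contour-traced
perimeter, capped at 1.0 to absorb discretisation overshoot at small
radii. Components touching the ROI boundary or image border are discarded
as truncated. Plaques are assumed brighter than the lawn (bright-field
transillumination of clearings); no watershed splitting of merged plaques
is attempted.

The printed 180–238 intensity window is a property of the original
camera/lightbox contrast. The synthetic renderer's nominal contrast is
150 (plaques 210 on lawn 60), so after background subtraction a lower
bound of 180 would select nothing on any render; recovery studies
therefore run the same pipeline with the lower bound recalibrated to 100
(two-thirds of the nominal contrast, keeping the anti-aliased edge ramp
mostly inside the window), set from the renderer's parameters — the
printed values remain the config defaults for real photographs.
Equivalent-circle diameter `2√(A/π)` is the reported plaque diameter.

## Dynamics

Extinction is defined as falling below the plating detection limit
(default 100 PFU/mL) with no later recovery through the final day; the
extinction day is the first day of that terminal run, with no smoothing.
Trace recovery below the standard detection limit (phages retrievable only
by enrichment) is representable as a post-hoc flag on the population, not
by the classifier. The cross-streak detection limit is `(1 − 1/n)·100%`
(95% at n = 20, 97.5% at n = 40): with zero sensitive isolates observed,
complete resistance is indistinguishable from any fraction at or above
that limit.

## Synthetic generators: what they emulate, and what they do not

All generators are deterministic under a fixed seed and expose their
ground truth (sidecar JSON when writing files, in-memory objects
otherwise).

- **Fixture genome.** Random uniform background with the table-pinned
  bases overwritten: every reference codon (reverse-complemented for
  reverse-strand genes), intergenic SNV reference bases, and homopolymer
  runs with non-matching flanks, plus cosmetic start codons. Every build
  re-annotates both bundled tables and aborts on any disagreement. Gene
  spans not pinned by the tables are minimal plausible stubs and marked
  "assumed" in `genes.tsv`. The background has uniform composition —
  no codon-usage, GC-skew or mutational-spectrum realism — so passing
  round-trip tests demonstrates coordinate/strand correctness, not
  robustness to compositional pathologies.
- **Adsorption counts.** Exponential decay of free phage with Poisson
  plate counts at the plated expectation. Defaults mirror the assay
  design: T0 = 10⁶ PFU/mL, 0.5 h incubation, 2×10⁹ cells/mL, n = 9
  replicates, 0.1 mL plated at 10³-fold dilution (about 50–100 plaques
  per plate); the default true rate 7×10⁻¹⁰ mL·cell⁻¹·h⁻¹ is chosen so
  the assay retains a measurable (~2-fold) titer drop. Pipetting and
  dilution errors beyond Poisson noise are not modelled, so recovery
  tests bound estimator bias under counting noise only.
- **Plates.** Anti-aliased bright disks on a darker lawn inside an 86 mm
  plate, with a linear illumination gradient (default 30 units
  peak-to-peak) and Gaussian pixel noise (sd 2); placement is rejection
  sampling, largest first, fully inside the ROI with a 0.5 mm minimum
  edge gap. Overlapping plaques, condensation, bubbles and lawn
  aberrations are deliberately absent, so detection-rate results are
  upper bounds on real-photo performance.
- **Dynamics.** Log-space rise by day 1 to ~10⁹ PFU/mL, then log-linear
  decline for extinction-bound populations (crossing the limit around
  day 5) or fluctuation at high titer for survivors; resistance counts
  are binomial with probability rising past the survey detection limit by
  day 5. Shapes are phenomenological, not a mechanistic host-phage model.

## Problem sizes used in the checked studies

Estimator recovery uses 1,000 seeded nine-replicate assays; plaque
recovery uses 20 plates at 0.15 mm/px with 50–120 plaques per plate,
diameters uniform on 0.6–6 mm (detection ≥ 95%, per-plaque diameter error
within 5% + 2 px); Monte-Carlo nulls use 10⁶ replicates (2×10⁶ for the
conditional mode, whose conditioning event retains ~8% of draws); fate
recovery uses 10 populations at extinction fraction 0.5. These sizes are
the package's own choices for tight, stable bounds at interactive
runtimes.

## Known limitations

- No dual gene assignment for overlapping ORFs; no GenomeDiff input.
- The uniform null ignores mutational spectrum and site heterogeneity.
- Absolute circularity values at very small radii depend on the perimeter
  estimator and may differ between particle-analysis implementations.
- The plaque pipeline does not split merged plaques; crowded plates bias
  sizes upward and counts downward.
- The renderer's intensity scale is nominal; threshold windows must be
  calibrated per imaging setup (see above).
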