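"""Reference genome and strand-aware gene-coordinate arithmetic.

All genome coordinates are 1-based and inclusive. A gene model carries a
span on the forward strand plus an orientation; codon numbering always runs
from the gene's own 5' end, so for reverse-strand genes the first codon sits
at the *end* of the forward-strand span and reference codons are read from
the reverse complement.

The locator maps a genome position to either a :class:`CodonContext`
(gene, codon number, within-codon offset, reference codon on the coding
strand) or an intergenic context naming the flanking genes.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq

FORWARD = "+"
REVERSE = "-"

_VALID_BASES = frozenset("ACGT")


class GenomeError(ValueError):
    """Raised for malformed genome or annotation inputs."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GenomeSequence:
    """A single reference nucleotide sequence over {A, C, G, T}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        for i, base in enumerate(self.sequence):
            if base not in _VALID_BASES:
                raise GenomeError(
                    f"invalid character {base!r} at position {i + 1} of "
                    f"record {self.id!r}: alphabet is restricted to A/C/G/T"
                )
        if not self.sequence:
            raise GenomeError(f"record {self.id!r} is empty")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Forward-strand base at a 1-based position."""
        self._check_bounds(position)
        return self.sequence[position - 1]

    def slice(self, start: int, end: int) -> str:
        """Forward-strand subsequence over the 1-based inclusive span."""
        self._check_bounds(start)
        self._check_bounds(end)
        return self.sequence[start - 1 : end]

    def _check_bounds(self, position: int) -> None:
        if not 1 <= position <= self.length_bp:
            raise GenomeError(
                f"position {position} outside genome [1, {self.length_bp}]"
            )


@dataclass(frozen=True)
class GeneModel:
    """One gene span: 1-based inclusive coordinates plus orientation."""

    gene_no: str
    start_bp: int
    end_bp: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in (FORWARD, REVERSE):
            raise GenomeError(
                f"gene {self.gene_no}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.end_bp < self.start_bp:
            raise GenomeError(
                f"gene {self.gene_no}: end {self.end_bp} < start {self.start_bp}"
            )
        if self.length_bp < 3:
            raise GenomeError(f"gene {self.gene_no}: span shorter than one codon")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def codon_count(self) -> int:
        """Number of complete codons (trailing 1-2 nt of off-frame spans ignored)."""
        return self.length_bp // 3

    def contains(self, position: int) -> bool:
        return self.start_bp <= position <= self.end_bp


@dataclass
class GenomeAnnotation:
    """Ordered, non-overlapping (by assumption) gene models for one genome."""

    genome_id: str
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: g.start_bp)
        seen: set[str] = set()
        for gene in self.genes:
            if gene.gene_no in seen:
                raise GenomeError(f"duplicate gene_no {gene.gene_no!r}")
            seen.add(gene.gene_no)
        for a, b in zip(self.genes, self.genes[1:]):
            if b.start_bp <= a.end_bp:
                warnings.warn(
                    f"genes {a.gene_no} and {b.gene_no} overlap; positions in "
                    "the overlap are assigned to the first gene",
                    stacklevel=2,
                )

    def gene(self, gene_no: str) -> GeneModel:
        for g in self.genes:
            if g.gene_no == gene_no:
                return g
        raise KeyError(gene_no)

    def genes_at(self, position: int) -> list[GeneModel]:
        return [g for g in self.genes if g.contains(position)]


@dataclass(frozen=True)
class CodonContext:
    gene_no: str
    codon_number: int
    within_codon_offset: int  # 1, 2 or 3 from the codon's 5' base on the coding strand
    ref_codon: str


@dataclass(frozen=True)
class LocusContext:
    kind: str  # "genic" | "intergenic"
    codon: Optional[CodonContext] = None
    upstream_gene: Optional[str] = None
    downstream_gene: Optional[str] = None

    @property
    def is_genic(self) -> bool:
        return self.kind == "genic"


def load_genome(path: str | Path) -> GenomeSequence:
    """Read a single-record FASTA into a :class:`GenomeSequence`.

    Rejects multi-record files and any non-ACGT character (reported with its
    1-based offset).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise GenomeError(
            f"expected exactly one FASTA record in {path}, found {len(records)}"
        )
    rec = records[0]
    return GenomeSequence(id=rec.id, sequence=str(rec.seq).upper())


def load_annotation(path: str | Path, genome_id: str = "") -> GenomeAnnotation:
    """Read the native TSV annotation (gene_no, start, end, strand, product)."""
    genes = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        required = {"gene_no", "start", "end", "strand"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise GenomeError(
                f"annotation {path} must carry a header with columns "
                "gene_no, start, end, strand[, product]"
            )
        for row in reader:
            strand = row["strand"].strip()
            # tolerate unicode minus from hand-written tables
            strand = {"−": REVERSE}.get(strand, strand)
            genes.append(
                GeneModel(
                    gene_no=row["gene_no"].strip(),
                    start_bp=int(row["start"]),
                    end_bp=int(row["end"]),
                    strand=strand,
                    product=(row.get("product") or "").strip(),
                )
            )
    return GenomeAnnotation(genome_id=genome_id, genes=genes)


def load_annotation_gff3(path: str | Path, genome_id: str = "") -> GenomeAnnotation:
    """Map a GFF3 gene/CDS file onto the same :class:`GenomeAnnotation` type.

    Uses the ``locus_tag`` or ``ID`` attribute as the gene number and
    ``product`` as the product description; rows other than gene/CDS are
    ignored.
    """
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] not in ("gene", "CDS"):
                continue
            attrs = {}
            for item in fields[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = v.strip()
            gene_no = attrs.get("locus_tag") or attrs.get("ID") or attrs.get("Name")
            if gene_no is None:
                raise GenomeError(f"GFF3 feature without locus_tag/ID in {path}")
            genes.append(
                GeneModel(
                    gene_no=gene_no,
                    start_bp=int(fields[3]),
                    end_bp=int(fields[4]),
                    strand=fields[6],
                    product=attrs.get("product", ""),
                )
            )
    # gene + CDS rows for the same locus collapse to one model
    unique = {g.gene_no: g for g in genes}
    return GenomeAnnotation(genome_id=genome_id, genes=list(unique.values()))


def nt_index_in_gene(gene: GeneModel, position: int) -> int:
    """1-based coding-strand nucleotide index of a genome position.

    Forward genes count from ``start_bp``; reverse genes count from
    ``end_bp`` (the coding 5' end). Bijective over the gene span.
    """
    if not gene.contains(position):
        raise GenomeError(
            f"position {position} outside gene {gene.gene_no} "
            f"[{gene.start_bp}, {gene.end_bp}]"
        )
    if gene.strand == FORWARD:
        return position - gene.start_bp + 1
    return gene.end_bp - position + 1


def ref_codon(gene: GeneModel, genome: GenomeSequence, codon_number: int) -> str:
    """Reference codon on the coding strand for a 1-based codon number."""
    if not 1 <= codon_number <= gene.codon_count:
        raise GenomeError(
            f"codon {codon_number} outside gene {gene.gene_no} "
            f"(holds {gene.codon_count} complete codons)"
        )
    if gene.strand == FORWARD:
        first = gene.start_bp + 3 * (codon_number - 1)
        return genome.slice(first, first + 2)
    # coding nt indices 3c-2..3c map to descending forward positions
    low = gene.end_bp - 3 * codon_number + 1
    return reverse_complement(genome.slice(low, low + 2))


def codon_context(gene: GeneModel, genome: GenomeSequence, position: int) -> Optional[CodonContext]:
    """Codon number, within-codon offset and reference codon at a genic position.

    Returns ``None`` (with a warning) for positions in the trailing 1-2 nt of
    a span whose length is not a codon multiple: only complete codons are
    translated.
    """
    nt = nt_index_in_gene(gene, position)
    codon_number = (nt - 1) // 3 + 1
    offset = (nt - 1) % 3 + 1
    if codon_number > gene.codon_count:
        warnings.warn(
            f"position {position} falls in the trailing partial codon of gene "
            f"{gene.gene_no} (length {gene.length_bp} bp is not a codon "
            "multiple); no codon context assigned",
            stacklevel=2,
        )
        return None
    return CodonContext(
        gene_no=gene.gene_no,
        codon_number=codon_number,
        within_codon_offset=offset,
        ref_codon=ref_codon(gene, genome, codon_number),
    )


def locate_position(
    annotation: GenomeAnnotation, genome: GenomeSequence, position: int
) -> LocusContext:
    """Classify a 1-based genome position as genic or intergenic.

    Genic positions get a strand-aware :class:`CodonContext`; intergenic
    positions name the flanking genes (``None`` at the genome ends).
    """
    genome._check_bounds(position)
    containing = annotation.genes_at(position)
    if containing:
        if len(containing) > 1:
            warnings.warn(
                f"position {position} lies in {len(containing)} overlapping "
                f"genes; assigned to gene {containing[0].gene_no}",
                stacklevel=2,
            )
        gene = containing[0]
        return LocusContext(kind="genic", codon=codon_context(gene, genome, position))
    upstream = None
    downstream = None
    for g in annotation.genes:
        if g.end_bp < position:
            upstream = g.gene_no
        elif g.start_bp > position and downstream is None:
            downstream = g.gene_no
    return LocusContext(kind="intergenic", upstream_gene=upstream, downstream_gene=downstream)
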