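"""Mutation-table parsing, codon/amino-acid annotation and summaries.

Input tables use one row per (mutation, source) with a ``bp_change`` column
in the resequencing-report dialect: ``C→A`` for SNVs, ``(A)8→7`` for
homopolymer run changes, ``+82 bp`` for insertions and ``Δ1 bp`` for
deletions (ASCII spellings ``C->A``, ``(A)8->7`` and ``del 1 bp`` are
accepted). SNV alleles are always stated on the forward genome strand;
complementation into the coding frame of reverse-strand genes happens here,
during annotation.

Amino-acid property changes are classified against a charge / polarity /
volume table; a substitution leaving all three classes unchanged is called
conserved (the classical "conservative" substitution).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml
from Bio.Data.CodonTable import standard_dna_table

from .genome_model import (
    FORWARD,
    GenomeAnnotation,
    GenomeSequence,
    LocusContext,
    locate_position,
)

SNV = "snv"
INSERTION = "insertion"
DELETION = "deletion"
HOMOPOLYMER_CONTRACTION = "homopolymer_contraction"

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONSENSE = "nonsense"
FRAMESHIFT = "frameshift"
IN_FRAME_INDEL = "in_frame_indel"
INTERGENIC = "intergenic"

STOP = "*"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class MutationParseError(ValueError):
    pass


class ReferenceMismatchError(ValueError):
    """Record's stated reference allele disagrees with the genome."""


@dataclass(frozen=True)
class MutationRecord:
    """One observed change at a genome position in one isolate/population."""

    genome_position: int
    change_kind: str
    ref_base: Optional[str] = None
    alt_base: Optional[str] = None
    length_bp: Optional[int] = None  # inserted/deleted length for indels
    homopolymer: Optional[tuple[str, int, int]] = None  # (base, run_from, run_to)
    source_id: str = ""
    read_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.change_kind == SNV:
            if self.ref_base == self.alt_base or None in (self.ref_base, self.alt_base):
                raise MutationParseError(
                    f"SNV at {self.genome_position} needs distinct ref/alt bases"
                )
        elif self.length_bp is not None and self.length_bp <= 0:
            raise MutationParseError(
                f"indel at {self.genome_position} needs positive length"
            )

    @property
    def change_key(self) -> str:
        """Canonical change descriptor used for (position, change) identity."""
        if self.change_kind == SNV:
            return f"{self.ref_base}>{self.alt_base}"
        if self.change_kind == INSERTION:
            return f"+{self.length_bp}bp"
        return f"-{self.length_bp}bp"

    @property
    def key(self) -> tuple[int, str]:
        return (self.genome_position, self.change_key)

    @property
    def net_length_change(self) -> int:
        if self.change_kind == SNV:
            return 0
        sign = 1 if self.change_kind == INSERTION else -1
        return sign * int(self.length_bp or 0)


_SNV_RE = re.compile(r"^([ACGT])\s*(?:→|->)\s*([ACGT])$")
_HOMOPOLYMER_RE = re.compile(r"^\((\w)\)\s*_?(\d+)\s*(?:→|->)\s*(\d+)_?$")
_INSERTION_RE = re.compile(r"^\+\s*(\d+)\s*bp$", re.IGNORECASE)
_DELETION_RE = re.compile(r"^(?:Δ|del\s*)\s*(\d+)\s*bp$", re.IGNORECASE)


def parse_bp_change(text: str) -> dict:
    """Parse one ``bp_change`` string into record fields."""
    s = text.strip()
    if m := _SNV_RE.match(s):
        if m.group(1) == m.group(2):
            raise MutationParseError(f"SNV {text!r} has identical ref and alt bases")
        return {"change_kind": SNV, "ref_base": m.group(1), "alt_base": m.group(2)}
    if m := _HOMOPOLYMER_RE.match(s):
        base, run_from, run_to = m.group(1), int(m.group(2)), int(m.group(3))
        if run_from == run_to:
            raise MutationParseError(f"homopolymer change {text!r} has no net change")
        kind = HOMOPOLYMER_CONTRACTION if run_to < run_from else INSERTION
        return {
            "change_kind": kind,
            "length_bp": abs(run_from - run_to),
            "homopolymer": (base, run_from, run_to),
        }
    if m := _INSERTION_RE.match(s):
        return {"change_kind": INSERTION, "length_bp": int(m.group(1))}
    if m := _DELETION_RE.match(s):
        return {"change_kind": DELETION, "length_bp": int(m.group(1))}
    raise MutationParseError(f"unparseable bp_change string: {text!r}")


def _parse_frequency(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
        if value.endswith("%"):
            pct = float(value[:-1])
            if not 0 <= pct <= 100:
                raise MutationParseError(f"frequency {value!r} outside [0, 100]%")
            return pct / 100.0
        value = float(value)
    value = float(value)
    # bare numbers > 1 are read as percentages (tables print "77.2")
    if value > 1.0:
        if value > 100:
            raise MutationParseError(f"frequency {value} outside [0, 100]%")
        return value / 100.0
    if value < 0:
        raise MutationParseError(f"negative frequency {value}")
    return value


def parse_mutation_table(
    path: str | Path, population_mode: bool = False
) -> list[MutationRecord]:
    """Read a TSV with columns position, bp_change, source_id[, frequency].

    Thousands separators in positions are tolerated. In population mode every
    row must carry a read frequency.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"position", "bp_change", "source_id"}
    if not required.issubset(df.columns):
        raise MutationParseError(
            f"mutation table {path} must have columns {sorted(required)}"
        )
    records = []
    for i, row in df.iterrows():
        try:
            fields = parse_bp_change(row["bp_change"])
            freq = (
                _parse_frequency(row["frequency"]) if "frequency" in df.columns else None
            )
        except MutationParseError as err:
            raise MutationParseError(f"{path} row {i + 2}: {err}") from err
        if population_mode and freq is None:
            raise MutationParseError(
                f"{path} row {i + 2}: population mode requires a read frequency"
            )
        # homopolymer contractions normalise to deletions of |n-m| bases
        kind = fields["change_kind"]
        if kind == HOMOPOLYMER_CONTRACTION:
            kind = DELETION
        records.append(
            MutationRecord(
                genome_position=int(str(row["position"]).replace(",", "")),
                change_kind=kind,
                ref_base=fields.get("ref_base"),
                alt_base=fields.get("alt_base"),
                length_bp=fields.get("length_bp"),
                homopolymer=fields.get("homopolymer"),
                source_id=str(row["source_id"]).strip(),
                read_frequency=freq,
            )
        )
    return records


# ---------------------------------------------------------------------------
# amino-acid property classification


@dataclass(frozen=True)
class PropertyTable:
    """Charge / polarity / volume classes for the 20 residues.

    The default split reproduces the classical radical/conservative scheme
    used for these substitutions: charge positive {K,R,H} and negative {D,E};
    polar {C,D,E,G,H,K,N,Q,R,S,T,W,Y} vs nonpolar {A,F,I,L,M,P,V}; volume
    small {A,C,D,G,I,L,N,P,S,T,V} vs large {E,F,H,K,M,Q,R,W,Y}. Override any
    class via :func:`PropertyTable.from_mapping` or a YAML/JSON config.
    """

    charge: dict[str, str] = field(default_factory=dict)
    polarity: dict[str, str] = field(default_factory=dict)
    volume: dict[str, str] = field(default_factory=dict)

    AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

    def __post_init__(self) -> None:
        for name, table in (
            ("charge", self.charge),
            ("polarity", self.polarity),
            ("volume", self.volume),
        ):
            missing = set(self.AMINO_ACIDS) - set(table)
            if missing:
                raise ValueError(f"{name} table missing residues {sorted(missing)}")

    @classmethod
    def default(cls) -> "PropertyTable":
        positive, negative = set("KRH"), set("DE")
        polar = set("CDEGHKNQRSTWY")
        small = set("ACDGILNPSTV")
        return cls(
            charge={
                aa: "positive" if aa in positive else "negative" if aa in negative else "neutral"
                for aa in cls.AMINO_ACIDS
            },
            polarity={aa: "polar" if aa in polar else "nonpolar" for aa in cls.AMINO_ACIDS},
            volume={aa: "small" if aa in small else "large" for aa in cls.AMINO_ACIDS},
        )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PropertyTable":
        """Build from ``{"charge": {...}, "polarity": {...}, "volume": {...}}``,
        filling unspecified residues from the default table."""
        base = cls.default()
        return cls(
            charge={**base.charge, **mapping.get("charge", {})},
            polarity={**base.polarity, **mapping.get("polarity", {})},
            volume={**base.volume, **mapping.get("volume", {})},
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PropertyTable":
        text = Path(path).read_text()
        mapping = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        )
        return cls.from_mapping(mapping)


@dataclass(frozen=True)
class PropertyChange:
    """Per-class transitions of one amino-acid substitution."""

    charge_change: Optional[tuple[str, str]] = None
    polarity_change: Optional[tuple[str, str]] = None
    volume_change: Optional[tuple[str, str]] = None

    @property
    def conserved(self) -> bool:
        return (
            self.charge_change is None
            and self.polarity_change is None
            and self.volume_change is None
        )

    def describe(self) -> str:
        parts = []
        for change in (self.charge_change, self.polarity_change, self.volume_change):
            if change is not None:
                parts.append(f"{change[0]} to {change[1]}")
        return ", ".join(parts).capitalize() if parts else "Nonsynonymous conserved"


def classify_property_change(
    aa_from: str, aa_to: str, table: Optional[PropertyTable] = None
) -> PropertyChange:
    """Classify a residue substitution by charge, polarity and volume.

    Stop codons are not classified (a gain of stop is already a nonsense
    call); unknown residues raise.
    """
    table = table or PropertyTable.default()
    for aa in (aa_from, aa_to):
        if aa not in table.charge:
            raise ValueError(f"residue {aa!r} not in property table")

    def transition(mapping: dict[str, str]) -> Optional[tuple[str, str]]:
        a, b = mapping[aa_from], mapping[aa_to]
        return None if a == b else (a, b)

    return PropertyChange(
        charge_change=transition(table.charge),
        polarity_change=transition(table.polarity),
        volume_change=transition(table.volume),
    )


# ---------------------------------------------------------------------------
# annotation


_CODON_TABLE = {
    codon: aa for codon, aa in standard_dna_table.forward_table.items()
}
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = STOP


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon.upper()]


@dataclass(frozen=True)
class MutationAnnotation:
    record: MutationRecord
    locus: LocusContext
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None
    aa_from: Optional[str] = None
    aa_to: Optional[str] = None
    effect: str = INTERGENIC
    property_change: Optional[PropertyChange] = None

    @property
    def gene_no(self) -> Optional[str]:
        return self.locus.codon.gene_no if self.locus.codon else None

    @property
    def aa_label(self) -> Optional[str]:
        if self.aa_from is None:
            return None
        return f"{self.aa_from}{self.locus.codon.codon_number}{self.aa_to}"

    @property
    def is_aa_changing(self) -> bool:
        return self.effect in (NONSYNONYMOUS, NONSENSE)


def annotate_mutation(
    record: MutationRecord,
    genome: GenomeSequence,
    annotation: GenomeAnnotation,
    property_table: Optional[PropertyTable] = None,
) -> MutationAnnotation:
    """Derive locus, codon change, effect class and property change.

    SNVs inside an ORF are substituted into the coding-strand reference codon
    (reverse-strand genes take the complemented alternate base); indels
    become frameshifts unless their length is a codon multiple; anything
    between genes is intergenic.
    """
    locus = locate_position(annotation, genome, record.genome_position)

    if record.change_kind == SNV:
        observed = genome.base(record.genome_position)
        if observed != record.ref_base:
            raise ReferenceMismatchError(
                f"record at {record.genome_position} states forward-strand "
                f"reference {record.ref_base} but the genome has {observed}"
            )

    if not locus.is_genic:
        return MutationAnnotation(record=record, locus=locus, effect=INTERGENIC)

    if record.change_kind != SNV:
        effect = (
            IN_FRAME_INDEL if (record.length_bp or 0) % 3 == 0 else FRAMESHIFT
        )
        return MutationAnnotation(record=record, locus=locus, effect=effect)

    ctx = locus.codon
    if ctx is None:
        # trailing partial codon: no translation possible
        return MutationAnnotation(record=record, locus=locus, effect=NONSYNONYMOUS)

    gene = annotation.gene(ctx.gene_no)
    alt = record.alt_base
    if gene.strand != FORWARD:
        alt = alt.translate(_COMPLEMENT)
    offset = ctx.within_codon_offset
    alt_codon = ctx.ref_codon[: offset - 1] + alt + ctx.ref_codon[offset:]

    aa_from = translate_codon(ctx.ref_codon)
    aa_to = translate_codon(alt_codon)
    if aa_from == aa_to:
        effect = SYNONYMOUS
    elif aa_to == STOP:
        effect = NONSENSE
    else:
        effect = NONSYNONYMOUS

    prop = None
    if effect == NONSYNONYMOUS and aa_from != STOP:
        prop = classify_property_change(aa_from, aa_to, property_table)

    return MutationAnnotation(
        record=record,
        locus=locus,
        ref_codon=ctx.ref_codon,
        alt_codon=alt_codon,
        aa_from=aa_from,
        aa_to=aa_to,
        effect=effect,
        property_change=prop,
    )


def annotate_all(
    records: Iterable[MutationRecord],
    genome: GenomeSequence,
    annotation: GenomeAnnotation,
    property_table: Optional[PropertyTable] = None,
) -> list[MutationAnnotation]:
    return [annotate_mutation(r, genome, annotation, property_table) for r in records]


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class IsolateSummary:
    n_isolates: int
    n_unique_mutations: int
    n_unique_aa_changes: int
    mean_mutations_per_isolate: float
    nonsynonymous_isolates_per_gene: dict[str, int]


def summarize_isolates(annotations: Sequence[MutationAnnotation]) -> IsolateSummary:
    """Cross-isolate summary of an annotated mutation set.

    Mutation uniqueness is keyed on (position, change) so a substitution seen
    in several isolates counts once among unique mutations but each
    occurrence contributes to the per-isolate mean. Amino-acid uniqueness is
    keyed on the substitution label (intergenic/synonymous rows contribute
    none).
    """
    isolates = sorted({a.record.source_id for a in annotations})
    unique_mutations = {a.record.key for a in annotations}
    unique_aa = {a.aa_label for a in annotations if a.is_aa_changing}
    per_gene: dict[str, set[str]] = {}
    for a in annotations:
        if a.is_aa_changing and a.gene_no is not None:
            per_gene.setdefault(a.gene_no, set()).add(a.record.source_id)
    return IsolateSummary(
        n_isolates=len(isolates),
        n_unique_mutations=len(unique_mutations),
        n_unique_aa_changes=len(unique_aa),
        mean_mutations_per_isolate=len(annotations) / len(isolates) if isolates else 0.0,
        nonsynonymous_isolates_per_gene={g: len(s) for g, s in per_gene.items()},
    )


@dataclass(frozen=True)
class ConcordanceMismatch:
    population: str
    position: int
    change: str
    aa_label: Optional[str]


def compare_isolate_to_population(
    isolate_annotations: Sequence[MutationAnnotation],
    population_annotations: Sequence[MutationAnnotation],
    fixed_threshold: float = 1.0,
) -> list[ConcordanceMismatch]:
    """Loci at or above a fixation threshold in population reads but absent
    from the isolate, keyed on (position, change)."""
    if any(a.record.read_frequency is None for a in population_annotations):
        raise ValueError("population annotations must carry read frequencies")
    isolate_keys = {a.record.key for a in isolate_annotations}
    mismatches = []
    for a in population_annotations:
        if a.record.read_frequency >= fixed_threshold and a.record.key not in isolate_keys:
            mismatches.append(
                ConcordanceMismatch(
                    population=a.record.source_id,
                    position=a.record.genome_position,
                    change=a.record.change_key,
                    aa_label=a.aa_label,
                )
            )
    return mismatches


def concordance_report(
    pairs: dict[str, tuple[Sequence[MutationAnnotation], Sequence[MutationAnnotation]]],
    fixed_threshold: float = 1.0,
) -> tuple[dict[str, list[ConcordanceMismatch]], int]:
    """Per-population isolate-vs-population mismatches and their union count."""
    per_pop = {
        label: compare_isolate_to_population(iso, pop, fixed_threshold)
        for label, (iso, pop) in pairs.items()
    }
    union = {(m.position, m.change) for ms in per_pop.values() for m in ms}
    return per_pop, len(union)


def filter_preexisting(
    annotations: Sequence[MutationAnnotation],
    stock_polymorphisms: Iterable[tuple[int, str, float]],
) -> tuple[list[MutationAnnotation], list[MutationAnnotation], list[tuple[int, str, float]]]:
    """Partition annotations into (evolved, preexisting) against stock variants.

    A mutation matching a stock polymorphism on (position, change) is called
    preexisting regardless of its stock frequency; stock entries matching
    nothing are returned as unused.
    """
    stock = list(stock_polymorphisms)
    for pos, change, freq in stock:
        if not 0 <= freq <= 1:
            raise ValueError(f"stock frequency {freq} for {pos} {change} outside [0, 1]")
    stock_keys = {(pos, change) for pos, change, _ in stock}
    evolved = [a for a in annotations if a.record.key not in stock_keys]
    preexisting = [a for a in annotations if a.record.key in stock_keys]
    matched = {a.record.key for a in preexisting}
    unused = [(p, c, f) for p, c, f in stock if (p, c) not in matched]
    return evolved, preexisting, unused


def load_stock_polymorphisms(path: str | Path) -> list[tuple[int, str, float]]:
    """Read stock variants as (position, change_key, frequency) triples."""
    records = parse_mutation_table(path, population_mode=True)
    return [(r.genome_position, r.change_key, r.read_frequency) for r in records]
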