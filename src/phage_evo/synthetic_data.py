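"""Generators for every input the analysis modules consume.

The centrepiece is the fixture genome: a 49,223 bp annotated phage genome
whose gene models and embedded reference codons are pinned by the bundled
isolate/population mutation matrices, so that re-annotating those tables
reproduces every printed codon pair, amino-acid label and effect class. The
background sequence is random (seeded); only the bases the tables constrain
are fixed, and an internal consistency oracle re-derives every annotation
and aborts the build if any row disagrees.

Also here: uniform null mutation tables for parallelism statistics,
Poisson-sampled adsorption assay counts under exponential titer decay,
rendered plate images with known plaque diameters, and titer/resistance
trajectories with known survival/extinction fates. Every generator is
deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_model import (
    FORWARD,
    GenomeAnnotation,
    GenomeSequence,
    load_annotation,
    nt_index_in_gene,
    reverse_complement,
)
from .mutation_annotation import (
    FRAMESHIFT,
    INTERGENIC,
    NONSENSE,
    NONSYNONYMOUS,
    SNV,
    SYNONYMOUS,
    MutationAnnotation,
    MutationRecord,
    PropertyChange,
    annotate_all,
    parse_bp_change,
)

GENOME_LENGTH = 49223

#: day-10 sequenced isolate -> source population
ISOLATE_POPULATIONS = {
    "RB-020": "Pop+2",
    "RB-022": "Pop+4",
    "RB-024": "Pop+6",
    "RB-028": "Pop+8",
    "ET013": "Pop+9",
}

#: substitutions whose printed property-impact labels are internally
#: inconsistent with any single charge/polarity/volume table; they are
#: excluded from property-label round-trip checks (codon and effect checks
#: still apply).
DISCREPANT_IMPACT_LABELS = frozenset({"Q1214K", "Q1214R", "K688N", "S194Y"})


class FixtureConsistencyError(RuntimeError):
    """The built genome fails to reproduce a bundled table row."""


def data_path(name: str) -> Path:
    return Path(resources.files("phage_evo.data") / name)


def load_fixture_gene_models() -> GenomeAnnotation:
    return load_annotation(data_path("genes.tsv"), genome_id="fixture_phage")


def load_table_matrix(name: str) -> pd.DataFrame:
    """Read a bundled wide-format mutation matrix (one row per mutation)."""
    df = pd.read_csv(data_path(name), sep="\t", comment="#", dtype=str)
    df["position"] = df["position"].str.replace(",", "").astype(int)
    return df


def matrix_to_records(
    df: pd.DataFrame, sample_columns: Sequence[str], population_mode: bool = False
) -> list[MutationRecord]:
    """Expand a wide matrix into per-sample :class:`MutationRecord` rows."""
    records = []
    for _, row in df.iterrows():
        fields = parse_bp_change(row["bp_change"])
        kind = fields["change_kind"]
        if kind == "homopolymer_contraction":
            kind = "deletion"
        for sample in sample_columns:
            cell = row.get(sample)
            if cell is None or pd.isna(cell) or not str(cell).strip():
                continue
            freq = None
            if population_mode:
                freq = float(str(cell).rstrip("%")) / 100.0
            records.append(
                MutationRecord(
                    genome_position=int(row["position"]),
                    change_kind=kind,
                    ref_base=fields.get("ref_base"),
                    alt_base=fields.get("alt_base"),
                    length_bp=fields.get("length_bp"),
                    homopolymer=fields.get("homopolymer"),
                    source_id=sample,
                    read_frequency=freq,
                )
            )
    return records


def load_table2_records() -> list[MutationRecord]:
    df = load_table_matrix("table2_isolates.tsv")
    return matrix_to_records(df, list(ISOLATE_POPULATIONS))


def load_table3_records() -> list[MutationRecord]:
    df = load_table_matrix("table3_populations.tsv")
    pops = [c for c in df.columns if c.startswith("Pop")]
    return matrix_to_records(df, pops, population_mode=True)


def load_stock_records() -> list[tuple[int, str, float]]:
    df = pd.read_csv(data_path("stock_polymorphisms.tsv"), sep="\t", comment="#", dtype=str)
    out = []
    for _, row in df.iterrows():
        fields = parse_bp_change(row["bp_change"])
        if fields["change_kind"] == SNV:
            change = f"{fields['ref_base']}>{fields['alt_base']}"
        elif fields["change_kind"] == "insertion":
            change = f"+{fields['length_bp']}bp"
        else:
            change = f"-{fields['length_bp']}bp"
        freq = float(row["frequency"].rstrip("%")) / 100.0
        out.append((int(row["position"].replace(",", "")), change, freq))
    return out


# ---------------------------------------------------------------------------
# expected-annotation parsing (the tables are the oracle for round trips)


@dataclass(frozen=True)
class ExpectedAnnotation:
    position: int
    bp_change: str
    aa_label: Optional[str]
    ref_codon: Optional[str]
    alt_codon: Optional[str]
    effect: str
    impact_text: str
    gene_no: str

    @property
    def property_label_checked(self) -> bool:
        return (
            self.effect == NONSYNONYMOUS
            and self.aa_label not in DISCREPANT_IMPACT_LABELS
        )


_TRANSITION_PHRASES = {
    "positive to neutral": ("charge", ("positive", "neutral")),
    "neutral to positive": ("charge", ("neutral", "positive")),
    "negative to neutral": ("charge", ("negative", "neutral")),
    "neutral to negative": ("charge", ("neutral", "negative")),
    "polar to nonpolar": ("polarity", ("polar", "nonpolar")),
    "nonpolar to polar": ("polarity", ("nonpolar", "polar")),
    "large to small": ("volume", ("large", "small")),
    "small to large": ("volume", ("small", "large")),
}


def parse_impact_label(text: str) -> Optional[PropertyChange]:
    """Parse a printed impact label into structured property transitions.

    Returns ``None`` for labels that carry no property classification
    (synonymous, intergenic, stop, frameshift); "nonsynonymous conserved"
    parses to the empty (conserved) change.
    """
    s = text.strip().lower()
    if s in {"synonymous", "not applicable", "early stop codon", "frame-shifting insertion"}:
        return None
    if s == "nonsynonymous conserved":
        return PropertyChange()
    kwargs: dict = {}
    for part in re.split(r",| and ", s):
        part = part.strip()
        if not part:
            continue
        if part not in _TRANSITION_PHRASES:
            raise ValueError(f"unrecognised impact phrase {part!r} in {text!r}")
        dim, pair = _TRANSITION_PHRASES[part]
        kwargs[f"{dim}_change"] = pair
    return PropertyChange(**kwargs)


def _expected_effect(impact: str, bp_change: str, aa_label: str) -> str:
    s = impact.strip().lower()
    if s == "synonymous":
        return SYNONYMOUS
    if s == "not applicable":
        return INTERGENIC
    if s == "early stop codon":
        return NONSENSE
    if s == "frame-shifting insertion":
        return FRAMESHIFT
    return NONSYNONYMOUS


def expected_annotations(df: pd.DataFrame) -> list[ExpectedAnnotation]:
    out = []
    for _, row in df.iterrows():
        aa = str(row["aa_change"]).strip()
        codons = str(row["codon_change"]).strip()
        genic_snv = "→" in codons
        ref_codon = alt_codon = None
        if genic_snv:
            ref_codon, alt_codon = codons.split("→")
        out.append(
            ExpectedAnnotation(
                position=int(row["position"]),
                bp_change=row["bp_change"],
                aa_label=aa if genic_snv else None,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                effect=_expected_effect(row["impact"], row["bp_change"], aa),
                impact_text=row["impact"],
                gene_no=str(row["gene_no"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# fixture genome construction


@dataclass
class FixtureGenome:
    genome: GenomeSequence
    annotation: GenomeAnnotation
    isolate_records: list[MutationRecord]
    population_records: list[MutationRecord]
    stock_polymorphisms: list[tuple[int, str, float]]
    seed: int
    constrained_positions: dict[int, str] = field(default_factory=dict)

    @property
    def isolate_annotations(self) -> list[MutationAnnotation]:
        return annotate_all(self.isolate_records, self.genome, self.annotation)

    @property
    def population_annotations(self) -> list[MutationAnnotation]:
        return annotate_all(self.population_records, self.genome, self.annotation)


def _codon_forward_span(gene, codon_number: int) -> tuple[int, str]:
    """Forward-strand start of the codon and a note of orientation."""
    if gene.strand == FORWARD:
        return gene.start_bp + 3 * (codon_number - 1), FORWARD
    return gene.end_bp - 3 * codon_number + 1, "-"


def _place(constraints: dict[int, str], position: int, bases: str, context: str) -> None:
    for i, b in enumerate(bases):
        pos = position + i
        prior = constraints.get(pos)
        if prior is not None and prior != b:
            raise FixtureConsistencyError(
                f"conflicting base constraints at {pos}: {prior} vs {b} ({context})"
            )
        constraints[pos] = b


def _collect_constraints(annotation: GenomeAnnotation) -> dict[int, str]:
    """Forward-strand base constraints implied by the bundled tables."""
    constraints: dict[int, str] = {}
    seen: set[tuple[int, str]] = set()
    for name in ("table2_isolates.tsv", "table3_populations.tsv"):
        df = load_table_matrix(name)
        for exp in expected_annotations(df):
            key = (exp.position, exp.bp_change)
            if key in seen:
                continue
            seen.add(key)
            fields = parse_bp_change(exp.bp_change)
            if fields["change_kind"] == SNV and exp.ref_codon is not None:
                gene = annotation.gene(exp.gene_no)
                nt = nt_index_in_gene(gene, exp.position)
                codon_number = (nt - 1) // 3 + 1
                low, strand = _codon_forward_span(gene, codon_number)
                bases = (
                    exp.ref_codon
                    if strand == FORWARD
                    else reverse_complement(exp.ref_codon)
                )
                _place(constraints, low, bases, f"codon of {exp.aa_label}")
            elif fields["change_kind"] == SNV:
                # intergenic SNV: pin the stated forward-strand reference base
                _place(constraints, exp.position, fields["ref_base"], exp.bp_change)
            elif fields.get("homopolymer") is not None:
                base, run_from, _ = fields["homopolymer"]
                _place(
                    constraints,
                    exp.position,
                    base * run_from,
                    f"homopolymer at {exp.position}",
                )
                flank = "C" if base != "C" else "G"
                _place(constraints, exp.position - 1, flank, "homopolymer 5' flank")
                _place(constraints, exp.position + run_from, flank, "homopolymer 3' flank")
    # cosmetic start codons where they do not collide with table constraints
    for gene in annotation.genes:
        if gene.strand == FORWARD:
            low, bases = gene.start_bp, "ATG"
        else:
            low, bases = gene.end_bp - 2, reverse_complement("ATG")
        if all(constraints.get(low + i, b) == b for i, b in enumerate(bases)):
            _place(constraints, low, bases, f"start codon of gene {gene.gene_no}")
    return constraints


def build_fixture_genome(
    seed: int = 0, outdir: Optional[str | Path] = None
) -> FixtureGenome:
    """Build the annotated fixture genome and (optionally) write all inputs.

    The background is seeded-random; every base the mutation tables pin is
    overwritten with its required value, then the whole construction is
    verified by re-annotating both tables and comparing codon pairs,
    amino-acid labels and effect classes row by row.
    """
    annotation = load_fixture_gene_models()
    constraints = _collect_constraints(annotation)

    rng = np.random.default_rng(seed)
    arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=GENOME_LENGTH)
    seq = bytearray(b"".join(arr))
    for pos, base in constraints.items():
        seq[pos - 1] = ord(base)
    genome = GenomeSequence(id="fixture_phage", sequence=seq.decode())

    fixture = FixtureGenome(
        genome=genome,
        annotation=annotation,
        isolate_records=load_table2_records(),
        population_records=load_table3_records(),
        stock_polymorphisms=load_stock_records(),
        seed=seed,
        constrained_positions=constraints,
    )
    _verify_fixture(fixture)

    if outdir is not None:
        _write_fixture(fixture, Path(outdir))
    return fixture


def _verify_fixture(fixture: FixtureGenome) -> None:
    """Oracle: every table row must re-annotate to its printed call."""
    failures = []
    for name, records in (
        ("table2_isolates.tsv", fixture.isolate_records),
        ("table3_populations.tsv", fixture.population_records),
    ):
        df = load_table_matrix(name)
        # positions are unique within each table
        expected = {e.position: e for e in expected_annotations(df)}
        seen: set[int] = set()
        for record, ann in zip(
            records, annotate_all(records, fixture.genome, fixture.annotation)
        ):
            exp = expected[record.genome_position]
            if exp.position in seen:
                continue
            seen.add(exp.position)
            problems = []
            if ann.effect != exp.effect:
                problems.append(f"effect {ann.effect} != {exp.effect}")
            if exp.ref_codon is not None and (
                ann.ref_codon != exp.ref_codon or ann.alt_codon != exp.alt_codon
            ):
                problems.append(
                    f"codons {ann.ref_codon}→{ann.alt_codon} != "
                    f"{exp.ref_codon}→{exp.alt_codon}"
                )
            if exp.aa_label is not None and ann.aa_label != exp.aa_label:
                problems.append(f"aa {ann.aa_label} != {exp.aa_label}")
            if problems:
                failures.append(f"{name} position {exp.position}: " + "; ".join(problems))
    if failures:
        raise FixtureConsistencyError(
            "fixture genome fails table round-trip:\n" + "\n".join(failures)
        )


def record_change_text(record: MutationRecord) -> str:
    """Normalised spelling variants of a record's change, for row matching."""
    if record.change_kind == SNV:
        return f"{record.ref_base}→{record.alt_base}"
    if record.homopolymer is not None:
        b, n, m = record.homopolymer
        return f"({b}){n}→{m}"
    if record.change_kind == "insertion":
        return f"+{record.length_bp}bp"
    return f"Δ{record.length_bp}bp"


def _write_fixture(fixture: FixtureGenome, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    SeqIO.write(
        [SeqRecord(Seq(fixture.genome.sequence), id=fixture.genome.id, description="")],
        str(outdir / "genome.fa"),
        "fasta",
    )
    for name in ("genes.tsv", "stock_polymorphisms.tsv"):
        (outdir / name).write_text(data_path(name).read_text())

    def records_frame(records: list[MutationRecord], with_freq: bool) -> pd.DataFrame:
        rows = []
        for r in records:
            row = {
                "position": r.genome_position,
                "bp_change": record_change_text(r).replace("bp", " bp"),
                "source_id": r.source_id,
            }
            if with_freq:
                row["frequency"] = f"{r.read_frequency * 100:g}%"
            rows.append(row)
        return pd.DataFrame(rows)

    records_frame(fixture.isolate_records, False).to_csv(
        outdir / "isolate_mutations.tsv", sep="\t", index=False
    )
    records_frame(fixture.population_records, True).to_csv(
        outdir / "population_mutations.tsv", sep="\t", index=False
    )
    (outdir / "ground_truth.json").write_text(
        json.dumps(
            {
                "seed": fixture.seed,
                "genome_length": fixture.genome.length_bp,
                "n_constrained_positions": len(fixture.constrained_positions),
                "genes": [
                    {
                        "gene_no": g.gene_no,
                        "start": g.start_bp,
                        "end": g.end_bp,
                        "strand": g.strand,
                        "product": g.product,
                    }
                    for g in fixture.annotation.genes
                ],
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# null mutation tables


def generate_null_mutations(
    n_populations: int,
    m_per_population: int,
    genome_length: int = GENOME_LENGTH,
    seed: int = 0,
    genome: Optional[GenomeSequence] = None,
) -> dict[str, pd.DataFrame]:
    """Uniform, independent mutation placements per population.

    SNV alternate alleles are drawn uniformly from the three non-reference
    bases; without a genome the reference base itself is drawn uniformly.
    """
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    tables = {}
    for i in range(1, n_populations + 1):
        rows = []
        positions = rng.integers(1, genome_length + 1, size=m_per_population)
        for pos in positions:
            ref = (
                genome.base(int(pos))
                if genome is not None
                else bases[rng.integers(4)]
            )
            alt = rng.choice([b for b in bases if b != ref])
            rows.append(
                {"position": int(pos), "bp_change": f"{ref}→{alt}", "source_id": f"null_pop_{i}"}
            )
        tables[f"null_pop_{i}"] = pd.DataFrame(
            rows, columns=["position", "bp_change", "source_id"]
        )
    return tables


# ---------------------------------------------------------------------------
# adsorption assay counts


def generate_adsorption_counts(
    true_rate: float = 7e-10,
    time_h: float = 0.5,
    cell_density: float = 2e9,
    t0_titer: float = 1e6,
    n_replicates: int = 9,
    plated_volume_ml: float = 0.1,
    dilution_t0: float = 1e3,
    dilution_t1: float = 1e3,
    seed: int = 0,
    host: str = "BW25113",
    phage: str = "U136B",
) -> pd.DataFrame:
    """Poisson-sampled plaque counts under exponential free-phage decay.

    Expected final titer is ``t0 * exp(-rate * density * time)``; each
    replicate's plated counts are Poisson at the plated expectation
    ``titer * volume / dilution``.
    """
    import warnings as _warnings

    if min(true_rate, 0) < 0 or time_h <= 0 or cell_density <= 0 or t0_titer <= 0:
        raise ValueError("rate must be >= 0 and time, density, titer positive")
    rng = np.random.default_rng(seed)
    t1_titer = t0_titer * np.exp(-true_rate * cell_density * time_h)
    lam0 = t0_titer * plated_volume_ml / dilution_t0
    lam1 = t1_titer * plated_volume_ml / dilution_t1
    if min(lam0, lam1) < 1:
        _warnings.warn(
            f"expected plate counts below 1 (T0 {lam0:.2g}, T1 {lam1:.2g}); "
            "estimates will be unstable",
            stacklevel=2,
        )
    rows = []
    for rep in range(1, n_replicates + 1):
        rows.append(
            {
                "replicate_id": rep,
                "host": host,
                "phage": phage,
                "t0_count": int(rng.poisson(lam0)),
                "t1_count": int(rng.poisson(lam1)),
                "dilution_t0": dilution_t0,
                "dilution_t1": dilution_t1,
                "volume_mL": plated_volume_ml,
                "time_h": time_h,
                "cell_density": cell_density,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plate images


class PlatePlacementError(RuntimeError):
    pass


def generate_plate_image(
    plaque_diameters_mm: Sequence[float],
    mm_per_px: float = 0.15,
    lawn_intensity: float = 60.0,
    plaque_intensity: float = 210.0,
    illumination_gradient: float = 30.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    plate_diameter_mm: float = 86.0,
    roi_diameter_mm: float = 72.24,
    min_gap_mm: float = 0.5,
    max_tries_per_disk: int = 5000,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render an 8-bit plate photo with bright anti-aliased plaque disks.

    Disks are placed by rejection sampling, largest first, fully inside the
    elliptical analysis region with a minimum edge-to-edge gap; a linear
    illumination gradient (peak-to-peak ``illumination_gradient``) and
    Gaussian pixel noise are superimposed. Returns the image and a ground
    truth table (center coordinates in mm, true diameter).
    """
    rng = np.random.default_rng(seed)
    size = int(round(plate_diameter_mm / mm_per_px))
    center = plate_diameter_mm / 2.0

    diameters = sorted((float(d) for d in plaque_diameters_mm), reverse=True)
    placed: list[tuple[float, float, float]] = []  # (x_mm, y_mm, radius_mm)
    roi_radius = roi_diameter_mm / 2.0
    for d in diameters:
        r = d / 2.0
        limit = roi_radius - r - min_gap_mm
        if limit <= 0:
            raise PlatePlacementError(f"disk of diameter {d} mm cannot fit in the ROI")
        for _ in range(max_tries_per_disk):
            x = center + rng.uniform(-limit, limit)
            y = center + rng.uniform(-limit, limit)
            if (x - center) ** 2 + (y - center) ** 2 > limit**2:
                continue
            if all(
                (x - px) ** 2 + (y - py) ** 2 >= (r + pr + min_gap_mm) ** 2
                for px, py, pr in placed
            ):
                placed.append((x, y, r))
                break
        else:
            raise PlatePlacementError(
                f"could not place disk of diameter {d} mm after "
                f"{max_tries_per_disk} tries ({len(placed)} placed)"
            )

    yy, xx = np.mgrid[0:size, 0:size]
    xmm = (xx + 0.5) * mm_per_px
    ymm = (yy + 0.5) * mm_per_px

    img = np.full((size, size), float(lawn_intensity))
    in_plate = (xmm - center) ** 2 + (ymm - center) ** 2 <= (plate_diameter_mm / 2) ** 2
    img[~in_plate] = 20.0  # bench around the plate
    if illumination_gradient:
        img += illumination_gradient * (xmm / plate_diameter_mm - 0.5)

    contrast = plaque_intensity - lawn_intensity
    for x, y, r in placed:
        r_px = r / mm_per_px
        cx, cy = x / mm_per_px - 0.5, y / mm_per_px - 0.5
        lo_x = max(0, int(cx - r_px - 2))
        hi_x = min(size, int(cx + r_px + 3))
        lo_y = max(0, int(cy - r_px - 2))
        hi_y = min(size, int(cy + r_px + 3))
        wy, wx = np.mgrid[lo_y:hi_y, lo_x:hi_x]
        dist = np.hypot(wx - cx, wy - cy)
        coverage = np.clip(r_px - dist + 0.5, 0.0, 1.0)  # anti-aliased edge
        img[lo_y:hi_y, lo_x:hi_x] += contrast * coverage

    if noise_sd:
        img += rng.normal(0.0, noise_sd, img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = pd.DataFrame(
        [{"x_mm": x, "y_mm": y, "diameter_mm": 2 * r} for x, y, r in placed]
    )
    return image, truth


# ---------------------------------------------------------------------------
# population dynamics


@dataclass(frozen=True)
class DynamicsTruth:
    fates: dict[str, str]  # population -> "survival_bound" | "extinction_bound"
    extinction_days: dict[str, int]


def generate_dynamics(
    n_populations: int = 10,
    extinction_fraction: float = 0.5,
    seed: int = 0,
    n_days: int = 10,
    detection_limit: float = 100.0,
) -> tuple[pd.DataFrame, pd.DataFrame, DynamicsTruth]:
    """Titer trajectories and cross-streak resistance counts.

    All populations rise sharply by day 1; extinction-bound populations then
    decline log-linearly, crossing the detection limit around day 5 and
    staying undetected; survivors fluctuate at high titer. Resistance counts
    are binomial draws against a resistance probability that rises past the
    cross-streak detection limit. Below-detection titers are recorded as 0.
    """
    if not 0 <= extinction_fraction <= 1:
        raise ValueError("extinction_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_extinct = int(round(extinction_fraction * n_populations))
    fates, extinction_days = {}, {}
    titer_rows, resist_rows = [], []
    streak_days = {1: 20, 5: 40, 10: 20}

    for i in range(1, n_populations + 1):
        pop = f"Pop+{i}"
        extinct = i <= n_extinct
        fates[pop] = "extinction_bound" if extinct else "survival_bound"
        peak = 10 ** rng.uniform(8.5, 9.5)
        slope = rng.uniform(1.5, 2.2)  # log10 decline per day
        ext_day = None
        for day in range(0, n_days + 1):
            if day == 0:
                titer = 1e4
            elif extinct:
                log_t = np.log10(peak) - slope * (day - 1) + rng.normal(0, 0.15)
                titer = 10**log_t
                if titer < detection_limit:
                    titer = 0.0
                    if ext_day is None:
                        ext_day = day
            else:
                titer = 10 ** (np.log10(peak) + rng.normal(-0.5, 0.4))
                titer = max(titer, 10 * detection_limit)  # survivors stay detectable
            titer_rows.append({"population": pop, "day": day, "titer": titer})
        if extinct and ext_day is None:  # guarantee the fate by construction
            ext_day = n_days
            titer_rows[-1]["titer"] = 0.0
        extinction_days[pop] = ext_day

        for day, n_tested in streak_days.items():
            if day > n_days:
                continue
            p_resist = {1: rng.uniform(0.55, 0.8), 5: rng.uniform(0.9, 1.0), 10: 1.0}[day]
            n_resistant = rng.binomial(n_tested, p_resist)
            resist_rows.append(
                {
                    "population": pop,
                    "day": day,
                    "n_tested": n_tested,
                    "n_sensitive": n_tested - n_resistant,
                }
            )

    truth = DynamicsTruth(fates=fates, extinction_days=extinction_days)
    return pd.DataFrame(titer_rows), pd.DataFrame(resist_rows), truth
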