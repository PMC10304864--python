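"""Mutation parsing, codon/effect annotation and cross-isolate summaries."""

import pytest

from phage_evo import genome_model as gm, mutation_annotation as ma, synthetic_data as sd


class TestParseBpChange:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C→A", {"change_kind": ma.SNV, "ref_base": "C", "alt_base": "A"}),
            ("C->A", {"change_kind": ma.SNV, "ref_base": "C", "alt_base": "A"}),
            (
                "(A)_8→7_",
                {
                    "change_kind": ma.HOMOPOLYMER_CONTRACTION,
                    "length_bp": 1,
                    "homopolymer": ("A", 8, 7),
                },
            ),
            (
                "(A)8->7",
                {
                    "change_kind": ma.HOMOPOLYMER_CONTRACTION,
                    "length_bp": 1,
                    "homopolymer": ("A", 8, 7),
                },
            ),
            ("+82 bp", {"change_kind": ma.INSERTION, "length_bp": 82}),
            ("Δ1 bp", {"change_kind": ma.DELETION, "length_bp": 1}),
            ("del 1 bp", {"change_kind": ma.DELETION, "length_bp": 1}),
        ],
    )
    def test_dialect(self, text, expected):
        assert ma.parse_bp_change(text) == expected

    @pytest.mark.parametrize("text", ["C→C", "Q→A", "82 bp", "(A)8→8"])
    def test_unparseable(self, text):
        with pytest.raises(ma.MutationParseError):
            ma.parse_bp_change(text)

    @pytest.mark.parametrize(
        "raw,expected", [("77.2%", 0.772), ("100%", 1.0), ("5.0", 0.05), (0.5, 0.5)]
    )
    def test_frequencies(self, raw, expected):
        assert ma._parse_frequency(raw) == pytest.approx(expected)

    def test_frequency_out_of_range(self):
        with pytest.raises(ma.MutationParseError):
            ma._parse_frequency("120%")


class TestParseTable:
    def test_round_trip_table(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "position\tbp_change\tsource_id\tfrequency\n"
            "28,296\tC→A\tPopX\t77.2%\n"
            "35,091\t(A)_8→7_\tPopX\t100%\n"
            "31,700\t+82 bp\tPopX\t100%\n"
        )
        records = ma.parse_mutation_table(path, population_mode=True)
        assert [r.genome_position for r in records] == [28296, 35091, 31700]
        assert records[0].change_kind == ma.SNV
        assert records[0].read_frequency == pytest.approx(0.772)
        # homopolymer contraction normalises to a 1 bp deletion
        assert records[1].change_kind == ma.DELETION
        assert records[1].net_length_change == -1
        assert records[2].change_kind == ma.INSERTION
        assert records[2].length_bp == 82

    def test_population_mode_requires_frequency(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("position\tbp_change\tsource_id\n100\tC→A\tPopX\n")
        with pytest.raises(ma.MutationParseError, match="frequency"):
            ma.parse_mutation_table(path, population_mode=True)

    def test_bad_row_cited(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("position\tbp_change\tsource_id\n100\tC=>A\tPopX\n")
        with pytest.raises(ma.MutationParseError, match="row 2"):
            ma.parse_mutation_table(path)


def snv(position, ref, alt, source="iso", freq=None):
    return ma.MutationRecord(
        genome_position=position,
        change_kind=ma.SNV,
        ref_base=ref,
        alt_base=alt,
        source_id=source,
        read_frequency=freq,
    )


class TestAnnotate:
    @pytest.mark.parametrize(
        "position,ref,alt,codons,aa_label,effect",
        [
            (28380, "C", "A", ("CAA", "AAA"), "Q1214K", ma.NONSYNONYMOUS),
            (31917, "C", "A", ("AAG", "AAT"), "K688N", ma.NONSYNONYMOUS),
            (11048, "T", "G", ("CGT", "CGG"), "R116R", ma.SYNONYMOUS),
            (48412, "G", "T", ("TCA", "TAA"), "S15*", ma.NONSENSE),
        ],
    )
    def test_snv_examples(self, fixture_genome, position, ref, alt, codons, aa_label, effect):
        ann = ma.annotate_mutation(
            snv(position, ref, alt), fixture_genome.genome, fixture_genome.annotation
        )
        assert (ann.ref_codon, ann.alt_codon) == codons
        assert ann.aa_label == aa_label
        assert ann.effect == effect

    def test_alt_codon_differs_only_at_offset(self, fixture_genome):
        ann = ma.annotate_mutation(
            snv(31917, "C", "A"), fixture_genome.genome, fixture_genome.annotation
        )
        offset = ann.locus.codon.within_codon_offset
        diffs = [i for i in range(3) if ann.ref_codon[i] != ann.alt_codon[i]]
        assert diffs == [offset - 1]

    @pytest.mark.parametrize(
        "length,effect",
        [(82, ma.FRAMESHIFT), (86, ma.FRAMESHIFT), (1, ma.FRAMESHIFT), (3, ma.IN_FRAME_INDEL)],
    )
    def test_indel_effect_by_length_mod3(self, fixture_genome, length, effect):
        record = ma.MutationRecord(
            genome_position=31700,
            change_kind=ma.INSERTION,
            length_bp=length,
            source_id="pop",
        )
        ann = ma.annotate_mutation(
            record, fixture_genome.genome, fixture_genome.annotation
        )
        assert ann.effect == effect

    def test_intergenic_change(self, fixture_genome):
        record = ma.MutationRecord(
            genome_position=38211,
            change_kind=ma.DELETION,
            length_bp=1,
            source_id="pop",
        )
        ann = ma.annotate_mutation(
            record, fixture_genome.genome, fixture_genome.annotation
        )
        assert ann.effect == ma.INTERGENIC
        assert ann.gene_no is None

    def test_reference_mismatch(self, fixture_genome):
        actual = fixture_genome.genome.base(28380)
        wrong = "G" if actual != "G" else "T"
        with pytest.raises(ma.ReferenceMismatchError):
            ma.annotate_mutation(
                snv(28380, wrong, "A"),
                fixture_genome.genome,
                fixture_genome.annotation,
            )


class TestPropertyClassification:
    @pytest.mark.parametrize(
        "aa_from,aa_to,charge,volume",
        [
            ("H", "N", ("positive", "neutral"), ("large", "small")),
            ("T", "K", ("neutral", "positive"), ("small", "large")),
        ],
    )
    def test_radical_changes(self, aa_from, aa_to, charge, volume):
        change = ma.classify_property_change(aa_from, aa_to)
        assert change.charge_change == charge
        assert change.volume_change == volume
        assert not change.conserved

    @pytest.mark.parametrize("aa_from,aa_to", [("L", "I"), ("A", "A")])
    def test_conserved(self, aa_from, aa_to):
        assert ma.classify_property_change(aa_from, aa_to).conserved

    def test_unknown_residue(self):
        with pytest.raises(ValueError):
            ma.classify_property_change("B", "A")

    def test_override_table(self):
        table = ma.PropertyTable.from_mapping({"volume": {"L": "large"}})
        assert not ma.classify_property_change("L", "V", table).conserved

    def test_covers_all_twenty_residues(self):
        table = ma.PropertyTable.default()
        assert set(table.charge) == set(ma.PropertyTable.AMINO_ACIDS)


class TestTableRoundTrip:
    """Re-annotating the bundled tables reproduces every printed call."""

    @pytest.mark.parametrize(
        "table_name,records_attr",
        [
            ("table2_isolates.tsv", "isolate_records"),
            ("table3_populations.tsv", "population_records"),
        ],
    )
    def test_codons_labels_effects(self, fixture_genome, table_name, records_attr):
        expected = {
            e.position: e
            for e in sd.expected_annotations(sd.load_table_matrix(table_name))
        }
        records = getattr(fixture_genome, records_attr)
        annotations = ma.annotate_all(
            records, fixture_genome.genome, fixture_genome.annotation
        )
        checked = set()
        for ann in annotations:
            exp = expected[ann.record.genome_position]
            checked.add(exp.position)
            assert ann.effect == exp.effect, exp.position
            if exp.ref_codon is not None:
                assert (ann.ref_codon, ann.alt_codon) == (exp.ref_codon, exp.alt_codon)
                assert ann.aa_label == exp.aa_label
            if exp.property_label_checked:
                assert ann.property_change == sd.parse_impact_label(exp.impact_text), (
                    exp.position
                )
        assert checked == set(expected)

    def test_synonymous_changes_carry_no_property_change(self, fixture_genome):
        for ann in fixture_genome.population_annotations:
            if ann.effect == ma.SYNONYMOUS:
                assert ann.property_change is None


class TestSummaries:
    def test_single_isolate_single_mutation(self, fixture_genome):
        ann = ma.annotate_mutation(
            snv(28296, "C", "A"), fixture_genome.genome, fixture_genome.annotation
        )
        summary = ma.summarize_isolates([ann])
        assert summary.n_unique_mutations == 1
        assert summary.n_unique_aa_changes == 1
        assert summary.mean_mutations_per_isolate == 1.0

    def test_shared_mutation_counts_once_unique_twice_in_mean(self, fixture_genome):
        anns = [
            ma.annotate_mutation(
                snv(28296, "C", "A", source=s),
                fixture_genome.genome,
                fixture_genome.annotation,
            )
            for s in ("iso1", "iso2")
        ]
        summary = ma.summarize_isolates(anns)
        assert summary.n_unique_mutations == 1
        assert summary.mean_mutations_per_isolate == 1.0
        assert summary.n_isolates == 2


class TestConcordance:
    def test_identical_sets_no_mismatch(self, fixture_genome):
        iso = [
            ma.annotate_mutation(
                snv(28296, "C", "A"), fixture_genome.genome, fixture_genome.annotation
            )
        ]
        pop = [
            ma.annotate_mutation(
                snv(28296, "C", "A", source="Pop", freq=1.0),
                fixture_genome.genome,
                fixture_genome.annotation,
            )
        ]
        assert ma.compare_isolate_to_population(iso, pop) == []

    def test_population_requires_frequencies(self, fixture_genome):
        pop = [
            ma.annotate_mutation(
                snv(28296, "C", "A"), fixture_genome.genome, fixture_genome.annotation
            )
        ]
        with pytest.raises(ValueError, match="frequencies"):
            ma.compare_isolate_to_population([], pop)

    def test_sub_fixation_alleles_ignored(self, fixture_genome):
        pop = [
            ma.annotate_mutation(
                snv(11048, "T", "G", source="Pop", freq=0.067),
                fixture_genome.genome,
                fixture_genome.annotation,
            )
        ]
        assert ma.compare_isolate_to_population([], pop) == []


class TestPreexistingFilter:
    def test_stock_match_partitions(self, fixture_genome):
        anns = fixture_genome.isolate_annotations
        evolved, preexisting, unused = ma.filter_preexisting(
            anns, fixture_genome.stock_polymorphisms
        )
        assert len(evolved) + len(preexisting) == len(anns)
        # the stock substitution appears in three isolates
        assert sorted(a.record.source_id for a in preexisting) == [
            "ET013",
            "RB-022",
            "RB-028",
        ]
        assert all(a.aa_label == "Q1214K" for a in preexisting)
        # the stock duplication was never observed in evolved isolates
        assert [(p, c) for p, c, _ in unused] == [(31648, "+86bp")]

    def test_empty_stock_all_evolved(self, fixture_genome):
        anns = fixture_genome.isolate_annotations
        evolved, preexisting, unused = ma.filter_preexisting(anns, [])
        assert len(evolved) == len(anns)
        assert preexisting == [] and unused == []

    def test_bad_stock_frequency(self, fixture_genome):
        with pytest.raises(ValueError):
            ma.filter_preexisting(fixture_genome.isolate_annotations, [(1, "C>A", 1.5)])
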