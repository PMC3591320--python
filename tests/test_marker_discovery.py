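"""Diagnostic indel discovery, assay evaluation and enzyme ranking."""

import pytest

from rflp.errors import ConfigError, DataError
from rflp.marker_discovery import (
    discover_diagnostic_indels,
    evaluate_assay,
    patterns_equivalent,
    select_enzyme,
)
from rflp.seq_core import PDAM_F, PDAM_R, AlignmentRow, GappedAlignment
from rflp.virtual_digest import ALU_I, Enzyme

NO_SITE_ENZYME = Enzyme("NarI", "GGCGCC", 2)  # absent from all fixture amplicons


def aln(*rows):
    return GappedAlignment(
        rows=tuple(AlignmentRow(f"r{i}", seq, label) for i, (seq, label) in enumerate(rows))
    )


class TestDiscoverDiagnosticIndels:
    def test_toy_two_bp_deletion(self):
        alignment = aln(
            ("ACGT--ACGT", "X"), ("ACGTTTACGT", "Y"), ("ACGTTTACGT", "Y")
        )
        (indel,) = discover_diagnostic_indels(alignment)
        assert (indel.lineage, indel.kind, indel.length) == ("X", "deletion", 2)
        assert indel.columns == (4, 6)
        assert indel.support == 1.0

    def test_fixture_alignment_recovers_8_and_6(self, alignment):
        indels = discover_diagnostic_indels(alignment, min_length=2)
        assert [(d.lineage, d.kind, d.length) for d in indels] == [
            ("alpha", "deletion", 8),
            ("beta", "deletion", 6),
        ]

    def test_no_gap_columns_gives_empty(self):
        alignment = aln(("ACGT", "X"), ("ACGT", "Y"))
        assert discover_diagnostic_indels(alignment) == []

    def test_insertion_called_for_converse_state(self):
        alignment = aln(("ACGTTTACGT", "X"), ("ACGT--ACGT", "Y"), ("ACGT--ACGT", "Y"))
        (indel,) = discover_diagnostic_indels(alignment)
        assert (indel.lineage, indel.kind, indel.length) == ("X", "insertion", 2)

    def test_shared_gap_disqualifies(self):
        # gap present in one Y row too: fixed in neither lineage
        alignment = aln(("ACGT--ACGT", "X"), ("ACGT--ACGT", "Y"), ("ACGTTTACGT", "Y"))
        assert discover_diagnostic_indels(alignment) == []

    def test_min_length_filters_short_runs(self):
        alignment = aln(("ACGT-TACGT", "X"), ("ACGTTTACGT", "Y"))
        assert discover_diagnostic_indels(alignment, min_length=2) == []

    def test_invariant_to_row_order_and_duplication(self, alignment):
        base = discover_diagnostic_indels(alignment, min_length=2)
        reordered = GappedAlignment(rows=tuple(reversed(alignment.rows)))
        duplicated = GappedAlignment(
            rows=alignment.rows
            + (AlignmentRow("dup", alignment.rows[0].residues, alignment.rows[0].label),)
        )
        for variant in (reordered, duplicated):
            got = discover_diagnostic_indels(variant, min_length=2)
            assert [(d.lineage, d.kind, d.length, d.columns) for d in got] == [
                (d.lineage, d.kind, d.length, d.columns) for d in base
            ]

    def test_unlabelled_row_is_an_error(self):
        alignment = GappedAlignment(
            rows=(AlignmentRow("r0", "AC-T", "X"), AlignmentRow("r1", "ACGT"))
        )
        with pytest.raises(DataError, match="unlabelled"):
            discover_diagnostic_indels(alignment)

    def test_single_lineage_is_an_error(self):
        alignment = aln(("AC-T", "X"), ("ACGT", "X"))
        with pytest.raises(DataError, match="two lineages"):
            discover_diagnostic_indels(alignment)

    @pytest.mark.parametrize("seed", range(2, 7))
    def test_generator_roundtrip_across_seeds(self, seed):
        from rflp.fixtures import make_alignment

        indels = discover_diagnostic_indels(make_alignment(seed), min_length=2)
        assert sorted((d.lineage, d.length) for d in indels) == [
            ("alpha", 8), ("beta", 6)
        ]


class TestEvaluateAssay:
    def test_alui_fully_distinguishes_at_gel_resolution(self, lineage_templates):
        evaluation = evaluate_assay(
            lineage_templates, PDAM_F, PDAM_R, ALU_I, resolution_bp=4
        )
        assert evaluation.distinguishable
        assert evaluation.flags == {}
        assert {lin: p.sizes for lin, p in evaluation.patterns.items()} == {
            "alpha": [84, 116, 389],
            "beta": [92, 110, 116, 389],
            "other": [92, 116, 389],
        }

    def test_uncut_amplicons_merge_at_coarse_resolution(self, lineage_templates):
        evaluation = evaluate_assay(
            lineage_templates, PDAM_F, PDAM_R, NO_SITE_ENZYME, resolution_bp=10
        )
        assert {lin: p.sizes for lin, p in evaluation.patterns.items()} == {
            "alpha": [705], "beta": [707], "other": [713]
        }
        assert not evaluation.distinguishable
        assert not any(evaluation.matrix.values())

    def test_single_lineage_trivially_distinguishable(self, alpha):
        evaluation = evaluate_assay([(alpha, "alpha")], PDAM_F, PDAM_R, ALU_I)
        assert evaluation.distinguishable
        assert evaluation.matrix == {}

    def test_no_amplification_is_flagged_not_fatal(self, decoy, alpha):
        evaluation = evaluate_assay(
            [(alpha, "alpha"), (decoy, "ghost")], PDAM_F, PDAM_R, ALU_I
        )
        assert evaluation.flags["ghost"] == "NO_AMPLIFICATION"
        assert evaluation.patterns["ghost"] is None
        assert evaluation.matrix[("alpha", "ghost")]

    def test_patterns_match_virtual_digest_at_resolution_zero(self, lineage_templates):
        from rflp.fixtures import fixture_amplicon
        from rflp.virtual_digest import band_pattern, digest

        evaluation = evaluate_assay(lineage_templates, PDAM_F, PDAM_R, ALU_I)
        for record, label in lineage_templates:
            expected = band_pattern(digest(fixture_amplicon(record), ALU_I))
            assert evaluation.patterns[label].sizes == expected.sizes

    def test_patterns_equivalent_helper(self):
        assert patterns_equivalent([705], [707], 10)
        assert not patterns_equivalent([705], [707], 1)
        assert not patterns_equivalent([84, 116, 389], [92, 110, 116, 389], 50)


class TestSelectEnzyme:
    def test_alui_ranked_above_non_cutter(self, lineage_templates):
        ranked = select_enzyme(
            lineage_templates, PDAM_F, PDAM_R, [NO_SITE_ENZYME, ALU_I], resolution_bp=4
        )
        assert [enzyme.name for enzyme, _ in ranked] == ["AluI", "NarI"]
        assert ranked[0][1].distinguishable

    def test_single_entry_catalog(self, lineage_templates):
        ranked = select_enzyme(lineage_templates, PDAM_F, PDAM_R, [ALU_I])
        assert len(ranked) == 1

    def test_empty_catalog_is_an_error(self, lineage_templates):
        with pytest.raises(ConfigError, match="catalog"):
            select_enzyme(lineage_templates, PDAM_F, PDAM_R, [])
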