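"""Hierarchical categorization, tie rules, and composition arithmetic."""

import numpy as np
import pytest

from pirnaflow import annotate, mapping, synthgen
from pirnaflow.core import AlignmentRecord, CollapsedRead, FeatureInterval


def _aln(rid, start, end, strand="+", contig="chrT"):
    return AlignmentRecord(rid, contig, start, end, strand)


def _read(rid, length=25, total=4):
    return CollapsedRead(rid, "A" * length, np.array([total]))


class TestAssignCategory:
    def test_transposon_sense_call(self, toy_genome):
        idx = annotate.FeatureIndex(toy_genome.features)
        a = annotate.assign_category(_read("r"), [_aln("r", 330, 355, "+")], idx)
        assert (a.category, a.te_class, a.sense) == ("transposon", "LTR", "sense")
        b = annotate.assign_category(_read("r"), [_aln("r", 330, 355, "-")], idx)
        assert b.sense == "antisense"

    def test_hierarchy_transposon_over_genic(self, toy_genome):
        idx = annotate.FeatureIndex(toy_genome.features)
        alns = [_aln("r", 90, 115, "+"), _aln("r", 330, 355, "+")]
        a = annotate.assign_category(_read("r"), alns, idx)
        assert a.category == "transposon"

    def test_adding_genic_feature_never_changes_transposon_call(self,
                                                                toy_genome):
        alns = [_aln("r", 330, 355, "+")]
        before = annotate.assign_category(
            _read("r"), alns, annotate.FeatureIndex(toy_genome.features))
        extra = FeatureInterval("chrT", 325, 400, "+", "CDS",
                                {"ID": "g9.p1", "gene_id": "gene9"})
        after = annotate.assign_category(
            _read("r"), alns,
            annotate.FeatureIndex(toy_genome.features + [extra]))
        assert before.category == after.category == "transposon"

    def test_half_overlap_rule(self, toy_genome):
        idx = annotate.FeatureIndex(toy_genome.features)
        # 24-nt read overlapping the TE [320,420) by 12 nt = exactly half: in
        a = annotate.assign_category(_read("r", 24),
                                     [_aln("r", 308, 332, "+")], idx)
        assert a.category == "transposon"
        # 11 nt < half: out (and nothing else there): unannotated
        b = annotate.assign_category(_read("r", 24),
                                     [_aln("r", 307, 331, "+")], idx)
        assert b.category == "unannotated" and b.sense == "none"

    def test_unannotated_in_background(self, toy_genome):
        idx = annotate.FeatureIndex(toy_genome.features)
        a = annotate.assign_category(_read("r"), [_aln("r", 0, 25, "+")], idx)
        assert (a.category, a.feature, a.te_class) == ("unannotated", "none",
                                                       "none")


class TestGenicFeature:
    def test_inside_cds_is_exon(self, toy_genome):
        idx = annotate.FeatureIndex(toy_genome.features)
        a = annotate.assign_category(_read("r"), [_aln("r", 90, 115, "+")], idx)
        assert (a.category, a.feature, a.target_id) == ("genic", "exon", "gene1")

    def test_exact_tie_prefers_exon_over_intron(self, toy_genome):
        # CDS [80,140) | intron [140,180): 24-nt read split 12/12
        idx = annotate.FeatureIndex(toy_genome.features)
        a = annotate.assign_category(_read("r", 24),
                                     [_aln("r", 128, 152, "+")], idx)
        assert a.feature == "exon"

    def test_exact_tie_prefers_utr3_over_exon(self, toy_genome):
        # CDS [180,240) | utr3 [240,290): split 12/12
        idx = annotate.FeatureIndex(toy_genome.features)
        a = annotate.assign_category(_read("r", 24),
                                     [_aln("r", 228, 252, "+")], idx)
        assert a.feature == "utr3"

    def test_majority_overlap_wins(self, toy_genome):
        # 25-nt read: 10 in CDS, 15 in intron -> intron
        idx = annotate.FeatureIndex(toy_genome.features)
        a = annotate.assign_category(_read("r", 25),
                                     [_aln("r", 130, 155, "+")], idx)
        assert a.feature == "intron"


class TestComposition:
    def test_single_read_is_hundred_percent(self):
        a = annotate.CategoryAssignment("r", "genic", feature="exon",
                                        sense="sense", weight=7)
        table = annotate.composition_summary([a])
        assert table.category_pct == {"genic": 100.0}
        assert table.genic_feature_pct == {"exon": 100.0}

    def test_weighted_arithmetic(self):
        a = annotate.CategoryAssignment("a", "transposon", te_class="LTR",
                                        sense="sense", weight=1)
        b = annotate.CategoryAssignment("b", "genic", feature="exon",
                                        sense="sense", weight=3)
        table = annotate.composition_summary([a, b])
        assert table.category_pct["transposon"] == pytest.approx(25.0)
        assert table.category_pct["genic"] == pytest.approx(75.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            annotate.composition_summary([])

    def test_invariant_assignment_consistency(self):
        with pytest.raises(ValueError):
            annotate.CategoryAssignment("r", "genic", sense="sense")  # no feature
        with pytest.raises(ValueError):
            annotate.CategoryAssignment("r", "transposon", sense="sense")


class TestPlantRecovery:
    def test_assignments_match_truth_labels(self, forged_genome):
        prof = synthgen.preset_profile("brain", seed=14)
        sim = synthgen.simulate_reads(forged_genome, prof, 4000)
        keep = [(r, t) for r, t in sim if t.category != "blacklist"]
        reads = [r for r, _ in keep]
        idx = mapping.SeedIndex(forged_genome.contigs)
        alns = mapping.map_reads(idx, reads)
        assigns = annotate.assign_all(reads, alns, forged_genome.features)
        by_id = {a.read_id: a for a in assigns}
        mismatch = 0
        for r, t in keep:
            a = by_id[r.id]
            if (a.category, a.sense) != (t.category, t.sense):
                mismatch += 1
            elif t.category == "genic" and a.feature != t.feature:
                mismatch += 1
        assert mismatch / len(keep) <= 0.01
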