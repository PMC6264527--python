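"""Filter-by-filter boundary behaviour and the cascade's bookkeeping."""

import numpy as np
import pandas as pd
import pytest

import lncdiscover as ld
from lncdiscover.cascade import (
    dedup_isoforms,
    filter_annotated_overlap,
    filter_basic,
    filter_expression,
    filter_intronic,
    filter_monoexonic,
    filter_nuclear_ratio,
    filter_repeats,
    flag_readthrough,
    partition_by_de,
    refine_tss,
    run_cascade,
)
from lncdiscover.expression import ExpressionTable
from lncdiscover.intervals import GenomicInterval

from conftest import make_gene, make_tx


def expr_table(values: dict, conditions=None):
    conditions = conditions or ["Meso_34", "Meso_68", "Meso_34_Nuc", "Meso_68_Nuc"]
    return ExpressionTable(
        pd.DataFrame.from_dict(values, orient="index", columns=conditions)
    )


class TestAnnotatedOverlap:
    def setup_method(self):
        self.ref = [make_gene("R", [[(1000, 2000)]], "+",
                              biotype="protein_coding")]

    def test_one_nt_same_strand_overlap_removed(self):
        cand = [make_gene("c", [[(1999, 3000)]], "+")]
        kept, st = filter_annotated_overlap(cand, self.ref)
        assert not kept and st.removed

    def test_antisense_only_overlap_retained(self):
        cand = [make_gene("c", [[(1500, 2500)]], "-")]
        kept, _ = filter_annotated_overlap(cand, self.ref)
        assert len(kept) == 1

    def test_intergenic_retained(self):
        cand = [make_gene("c", [[(5000, 6000)]], "+")]
        kept, _ = filter_annotated_overlap(cand, self.ref)
        assert len(kept) == 1


class TestIntronic:
    def setup_method(self):
        # host with intron [1000, 4000) on '+'
        self.ref = [make_gene("R", [[(500, 1000), (4000, 4500)]], "+",
                              biotype="protein_coding")]

    def test_intronic_sense_removed(self):
        cand = [make_gene("c", [[(2000, 2600)]], "+")]
        kept, st = filter_intronic(cand, self.ref)
        assert not kept
        assert st.removed["c.t1"] == "intron_embedded_sense"

    def test_antisense_exon_overlap_rescues(self):
        anti = make_gene("A", [[(1900, 2700)]], "-", biotype="lncRNA_annotated")
        cand = [make_gene("c", [[(2000, 2600)]], "+")]
        kept, _ = filter_intronic(cand, self.ref + [anti])
        assert len(kept) == 1

    def test_partially_intergenic_exon_retained(self):
        cand = [make_gene("c", [[(2000, 2600), (6000, 6300)]], "+")]
        kept, _ = filter_intronic(cand, self.ref)
        assert len(kept) == 1


def strand_counts(rows):
    return pd.DataFrame(
        rows, columns=["feature_id", "condition", "sense_reads",
                       "antisense_reads"]
    )


class TestMonoexonic:
    def test_unstranded_removed(self):
        cand = [make_gene("c", [[(0, 800)]], ".")]
        sc = strand_counts([("c.t1", "Meso_34", 100, 0)])
        kept, st = filter_monoexonic(cand, sc)
        assert st.removed["c.t1"] == "unstranded"

    def test_ratio_boundary_inclusive(self):
        cand = [make_gene("c", [[(0, 800)]], "+")]
        sc = strand_counts([("c.t1", "Meso_34", 8, 2)])  # exactly 0.8
        kept, _ = filter_monoexonic(cand, sc)
        assert len(kept) == 1
        sc = strand_counts([("c.t1", "Meso_34", 79, 21)])  # 0.79
        kept, st = filter_monoexonic(cand, sc)
        assert st.removed["c.t1"] == "low_sense_ratio"

    def test_one_good_sample_suffices(self):
        cand = [make_gene("c", [[(0, 800)]], "+")]
        sc = strand_counts(
            [("c.t1", "Meso_34", 50, 50), ("c.t1", "WE_68", 95, 5)]
        )
        kept, _ = filter_monoexonic(cand, sc)
        assert len(kept) == 1

    @pytest.mark.parametrize("length,kept_n", [(499, 0), (500, 1)])
    def test_length_boundary(self, length, kept_n):
        cand = [make_gene("c", [[(0, length)]], "+")]
        sc = strand_counts([("c.t1", "Meso_34", 100, 0)])
        kept, _ = filter_monoexonic(cand, sc)
        assert len(kept) == kept_n

    def test_missing_counts_removed_with_reason(self):
        cand = [make_gene("c", [[(0, 800)]], "+")]
        kept, st = filter_monoexonic(cand, strand_counts([]))
        assert st.removed["c.t1"] == "no_strand_support"

    def test_multiexonic_pass_through(self):
        cand = [make_gene("c", [[(0, 100), (300, 400)]], "+")]
        kept, _ = filter_monoexonic(cand, strand_counts([]))
        assert len(kept) == 1


class TestBasicAndExpression:
    def test_blacklist_and_length(self):
        cands = [
            make_gene("u", [[(0, 900)]], "+", chrom="U"),
            make_gene("s", [[(0, 199)]], "+"),
            make_gene("ok", [[(0, 200)]], "+"),
        ]
        kept, st = filter_basic(cands)
        assert [g.gene_id for g in kept] == ["ok"]
        assert st.removed["u.t1"] == "blacklist_chrom"
        assert st.removed["s.t1"] == "too_short"

    @pytest.mark.parametrize("fpkm,kept_n", [(2.0, 1), (1.9, 0), (0.0, 0)])
    def test_fpkm_boundary(self, fpkm, kept_n):
        cand = [make_gene("c", [[(0, 500)]], "+")]
        expr = expr_table({"c": [fpkm, 0.0, 0.0, 0.0]})
        kept, _ = filter_expression(cand, expr)
        assert len(kept) == kept_n

    def test_missing_gene_removed(self):
        cand = [make_gene("c", [[(0, 500)]], "+")]
        expr = expr_table({"other": [5.0, 5.0, 5.0, 5.0]})
        _, st = filter_expression(cand, expr)
        assert st.removed["c.t1"] == "no_expression_record"


class TestRepeats:
    def _mask(self, start, end):
        return [GenomicInterval("chr1", start, end)]

    def test_ninety_percent_boundary_is_strict(self):
        cand = [make_gene("c", [[(0, 1000)]], "+")]
        kept, _ = filter_repeats(cand, self._mask(0, 900))  # exactly 90%
        assert len(kept) == 1
        kept, st = filter_repeats(cand, self._mask(0, 910))  # 91%
        assert st.removed["c.t1"] == "repeat_masked"

    def test_no_overlap_retained(self):
        cand = [make_gene("c", [[(0, 1000)]], "+")]
        kept, _ = filter_repeats(cand, self._mask(5000, 6000))
        assert len(kept) == 1


class TestDedup:
    def test_identical_isoforms_keep_one(self):
        g = make_gene("g", [[(0, 1000)], [(0, 1000)]])
        kept, st = dedup_isoforms([g])
        assert len(kept[0].transcripts) == 1
        assert "g.t2" in st.removed

    def test_similarity_exactly_095_keeps_both(self):
        g = make_gene("g", [[(0, 1000)], [(0, 950)]])  # J = 0.95 exactly
        kept, _ = dedup_isoforms([g])
        assert len(kept[0].transcripts) == 2

    def test_three_near_identical_keep_longest(self):
        g = make_gene("g", [[(0, 1000)], [(0, 990)], [(0, 980)]])
        kept, _ = dedup_isoforms([g])
        assert [t.transcript_id for t in kept[0].transcripts] == ["g.t1"]


class TestNuclearRatio:
    def setup_method(self):
        self.ref = [make_gene("R", [[(500, 1000), (4000, 4500)]], "+",
                              biotype="protein_coding")]
        self.cand = [make_gene("c", [[(2000, 2600)]], "+")]

    def _run(self, nuc, whole):
        expr = expr_table({"c": [whole, whole, nuc, nuc]})
        return filter_nuclear_ratio(self.cand, expr, self.ref)

    def test_enriched_removed(self):
        _, st = self._run(nuc=4.2, whole=1.0)  # log2(4.3/1.1) ~ 1.97
        assert st.removed["c.t1"] == "nuclear_enriched_premrna"

    def test_equal_retained(self):
        kept, _ = self._run(nuc=3.0, whole=3.0)
        assert len(kept) == 1

    def test_ratio_exactly_two_retained(self):
        # (nuc + 0.1) / (whole + 0.1) == 2 -> log2 == 1, strict > keeps it
        kept, _ = self._run(nuc=4.1, whole=2.0)
        assert len(kept) == 1

    def test_non_intronic_monoexonic_untouched(self):
        cand = [make_gene("c", [[(8000, 8600)]], "+")]
        expr = expr_table({"c": [1.0, 1.0, 50.0, 50.0]})
        kept, _ = filter_nuclear_ratio(cand, expr, self.ref)
        assert len(kept) == 1

    def test_missing_nuclear_condition_errors(self):
        expr = ExpressionTable(
            pd.DataFrame({"Meso_34": [1.0]}, index=["c"])
        )
        with pytest.raises(ValueError, match="nuclear pair"):
            filter_nuclear_ratio(self.cand, expr, self.ref)


class TestReadthrough:
    def setup_method(self):
        # PCG on '+' with TES at 1999
        self.ref = [make_gene("R", [[(1000, 2000)]], "+",
                              biotype="protein_coding")]
        self.expr = expr_table({"R": [10.0, 10.0, 10.0, 10.0]})

    def _flags(self, cand):
        _, _, flags = flag_readthrough([cand], self.ref, self.expr)
        return flags

    def test_close_same_strand_flagged(self):
        assert self._flags(make_gene("c", [[(2099, 3000)]], "+"))

    def test_opposite_strand_not_flagged(self):
        assert not self._flags(make_gene("c", [[(2099, 3000)]], "-"))

    def test_gap_boundary(self):
        # 5' end 501 nt past the TES -> outside max_gap
        assert not self._flags(make_gene("c", [[(2501, 3500)]], "+"))
        assert self._flags(make_gene("c", [[(2499, 3500)]], "+"))

    def test_flag_only_keeps_transcripts(self):
        cand = make_gene("c", [[(2099, 3000)]], "+")
        kept, _, _ = flag_readthrough([cand], self.ref, self.expr)
        assert len(kept) == 1


class TestDePartition:
    def _de(self, padj):
        return ld.DETable(pd.DataFrame(
            {"comparison": ["S34_VS_S68"], "gene_id": ["c"],
             "log2fc": [2.0], "padj": [padj]}
        ))

    def test_significant_goes_main(self):
        cand = [make_gene("c", [[(0, 500)]], "+")]
        main, const, _ = partition_by_de(cand, self._de(0.005), [],
                                         expr=expr_table({"c": [1.0] * 4}))
        assert [g.gene_id for g in main] == ["c"] and not const

    @pytest.mark.parametrize("fpkm,expect_const", [(3.0, True), (2.5, False)])
    def test_constitutive_fpkm_boundary(self, fpkm, expect_const):
        cand = [make_gene("c", [[(0, 500)]], "+")]
        main, const, st = partition_by_de(
            cand, self._de(0.5), [], expr=expr_table({"c": [fpkm] * 4})
        )
        assert not main
        assert bool(const) == expect_const

    def test_constitutive_intronic_dropped(self):
        ref = [make_gene("R", [[(500, 1000), (4000, 4500)]], "+",
                         biotype="protein_coding")]
        cand = [make_gene("c", [[(2000, 2600)]], "+")]
        main, const, st = partition_by_de(
            cand, self._de(0.5), ref, expr=expr_table({"c": [5.0] * 4})
        )
        assert not main and not const
        assert st.removed["c.t1"] == "constitutive_intronic"


def cage(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])


class TestRefineTss:
    def tx(self, strand="+"):
        if strand == "+":
            return make_tx("t", [(10_000, 11_000)], "+")
        return make_tx("t", [(10_000, 11_000)], "-")

    def test_peak_upstream_extends(self):
        t = self.tx()
        refined, rec = refine_tss(t, cage([("chr1", 9_900, "+", 50)]))
        assert rec.direction == "extended" and rec.nt_moved == 100
        assert refined.tss == 9_900
        assert refined.exons[0].start == 9_900

    def test_49_tags_ignored(self):
        _, rec = refine_tss(self.tx(), cage([("chr1", 9_900, "+", 49)]))
        assert rec.direction == "unchanged"

    def test_900_nt_upstream_outside_window(self):
        _, rec = refine_tss(self.tx(), cage([("chr1", 9_100, "+", 200)]))
        assert rec.direction == "unchanged"

    def test_inward_beyond_30_percent_ignored(self):
        # L = 1000, window inward = 300; peak 350 inward
        _, rec = refine_tss(self.tx(), cage([("chr1", 10_350, "+", 200)]))
        assert rec.direction == "unchanged"

    def test_inward_clip_within_window(self):
        refined, rec = refine_tss(self.tx(), cage([("chr1", 10_250, "+", 80)]))
        assert rec.direction == "clipped" and rec.nt_moved == 250
        assert refined.exons[0].start == 10_250

    def test_minus_strand_symmetry(self):
        t = self.tx("-")  # TSS at 10_999
        refined, rec = refine_tss(t, cage([("chr1", 11_100, "-", 60)]))
        assert rec.direction == "extended" and rec.nt_moved == 101
        assert refined.tss == 11_100

    def test_upstream_wins_ties(self):
        t = self.tx()
        peaks = cage([("chr1", 9_950, "+", 60), ("chr1", 10_050, "+", 60)])
        _, rec = refine_tss(t, peaks)
        assert rec.new_tss == 9_950

    def test_never_crosses_first_intron(self):
        t = make_tx("t", [(10_000, 10_100), (12_000, 13_000)], "+")
        # 0.3 * L = 330 inward, but the peak is past the first exon
        _, rec = refine_tss(t, cage([("chr1", 10_200, "+", 90)]))
        assert rec.direction == "unchanged"

    def test_idempotent_when_peak_at_refined_tss(self):
        t = self.tx()
        peaks = cage([("chr1", 9_900, "+", 70)])
        refined, _ = refine_tss(t, peaks)
        again, rec = refine_tss(refined, peaks)
        assert rec.direction == "unchanged"
        assert again.exon_pairs == refined.exon_pairs

    def test_move_bounded_by_window(self, bundle, cascade_result):
        for rec in cascade_result.tss_records:
            assert rec.nt_moved <= 800 or rec.direction == "clipped"


class TestRunCascade:
    def test_empty_candidate_set(self, bundle):
        res = run_cascade([], bundle.reference, bundle.expr,
                          bundle.strand_counts, bundle.de, bundle.repeats,
                          bundle.cage)
        assert not res.hq
        assert all(s.n_input == 0 for s in res.report.stages)

    def test_counts_conserve_each_stage(self, cascade_result):
        for s in cascade_result.report.stages:
            assert len(s.retained) + len(s.removed) == s.n_input

    def test_stage_order_fixed(self, cascade_result):
        assert [s.name for s in cascade_result.report.stages] == [
            "annotated_overlap", "intronic", "monoexonic", "basic",
            "expression", "repeats", "dedup_isoforms", "nuclear_ratio",
            "readthrough", "de_partition",
        ]

    def test_truth_recovery(self, bundle, cascade_result):
        hq = {g.gene_id for g in cascade_result.hq}
        truth = bundle.truth
        assert truth.genes_with("planted_novel_lncRNA") <= hq
        for label in ("dna_contamination", "pre_mRNA_leftover", "repeat_decoy"):
            assert not (truth.genes_with(label) & hq)

    def test_readthrough_candidates_flagged(self, bundle, cascade_result):
        planted = {
            f"{g}.t1" for g in bundle.truth.genes_with("readthrough")
        }
        assert planted <= cascade_result.readthrough_flags

    def test_main_and_constitutive_partition(self, bundle, cascade_result):
        main = {g.gene_id for g in cascade_result.main}
        const = {g.gene_id for g in cascade_result.constitutive}
        assert not main & const
        truth = bundle.truth
        assert truth.genes_with("de_main") <= main
        assert truth.genes_with("constitutive") <= main | const
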