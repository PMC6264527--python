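"""Context hierarchy, TSS de-duplication, pair sets and correlations."""

import numpy as np
import pandas as pd
import pytest

from lncdiscover.context import (
    PairRecord,
    build_pair_sets,
    classify_context,
    compare_category_to_background,
    dedup_tss,
    pair_correlations,
    random_pairs,
)
from lncdiscover.expression import ExpressionTable

from conftest import make_gene


@pytest.fixture
def pcg():
    # '+' PCG: TSS 5000, exons [5000,5400) and [6000,6500), TES 6499
    return make_gene("P", [[(5000, 5400), (6000, 6500)]], "+",
                     biotype="protein_coding")


class TestHierarchy:
    def test_tss_beats_everything(self, pcg):
        lnc = make_gene("L", [[(4900, 6200)]], "-")  # covers TSS + intron + exon
        assert classify_context(lnc, [pcg]) == "TSS"

    def test_tes_beats_exon(self, pcg):
        lnc = make_gene("L", [[(6300, 6700)]], "-")  # covers exon and TES
        assert classify_context(lnc, [pcg]) == "TES"

    def test_exon_then_intron(self, pcg):
        assert classify_context(make_gene("L", [[(5100, 5200)]], "-"),
                                [pcg]) == "exon"
        assert classify_context(make_gene("L", [[(5500, 5900)]], "-"),
                                [pcg]) == "intron"

    def test_promoter_window_1kb_upstream(self, pcg):
        lnc = make_gene("L", [[(4200, 4600)]], "-")
        assert classify_context(lnc, [pcg]) == "promoter"

    def test_enhancer_then_intergenic(self, pcg):
        from lncdiscover.intervals import GenomicInterval
        enh = [GenomicInterval("chr1", 20_000, 21_000)]
        lnc = make_gene("L", [[(20_500, 20_800)]], "+")
        assert classify_context(lnc, [pcg], enh) == "enhancer"
        far = make_gene("L", [[(40_000, 40_500)]], "+")
        assert classify_context(far, [pcg], enh) == "intergenic"

    def test_strand_blind(self, pcg):
        sense = make_gene("L", [[(5100, 5200)]], "+")
        anti = make_gene("L", [[(5100, 5200)]], "-")
        assert classify_context(sense, [pcg]) == classify_context(anti, [pcg])

    def test_adding_tss_overlap_moves_toward_tss(self, pcg):
        # hierarchy property: a gene seeing one more TSS overlap can only
        # move up the ranking
        lnc = make_gene("L", [[(5500, 5900)]], "-")
        before = classify_context(lnc, [pcg])
        extra = make_gene("Q", [[(5600, 5800)]], "+", biotype="protein_coding")
        after = classify_context(lnc, [pcg, extra])
        order = ["TSS", "TES", "exon", "intron", "promoter", "enhancer",
                 "intergenic"]
        assert order.index(after) <= order.index(before)


class TestDedupTss:
    def test_close_tss_collapse_to_highest_fpkm(self):
        g = make_gene("g", [[(100, 1000)], [(130, 1000)]])
        expr = ExpressionTable(
            pd.DataFrame({"c": {"g.t1": 1.0, "g.t2": 9.0}}), level="transcript"
        )
        reps = dedup_tss(g, expr)
        assert reps == [("g.t2", 130)]

    def test_distant_tss_both_kept(self):
        g = make_gene("g", [[(100, 1000)], [(160, 1000)]])
        expr = ExpressionTable(
            pd.DataFrame({"c": {"g.t1": 1.0, "g.t2": 9.0}}), level="transcript"
        )
        assert len(dedup_tss(g, expr)) == 2

    def test_single_isoform(self):
        g = make_gene("g", [[(100, 1000)]])
        expr = ExpressionTable(pd.DataFrame({"c": {"g.t1": 1.0}}),
                               level="transcript")
        assert dedup_tss(g, expr) == [("g.t1", 100)]

    def test_gene_level_table_rejected(self):
        g = make_gene("g", [[(100, 1000)]])
        expr = ExpressionTable(pd.DataFrame({"c": {"g": 1.0}}))
        with pytest.raises(ValueError):
            dedup_tss(g, expr)


class TestPairSets:
    def test_intergenic_lnc_same_partner_in_both_closest_sets(self):
        lnc = make_gene("L", [[(10_000, 11_000)]], "+")
        p1 = make_gene("P1", [[(13_000, 14_000)]], "+", biotype="protein_coding")
        p2 = make_gene("P2", [[(30_000, 31_000)]], "+", biotype="protein_coding")
        pairs = build_pair_sets([lnc], [p1, p2])
        by_cat = {p.category: p for p in pairs}
        assert by_cat["closest_any"].pcg_id == "P1"
        assert by_cat["closest_nonoverlap"].pcg_id == "P1"

    def test_antisense_tss_longest_mrna_wins(self):
        lnc = make_gene("L", [[(4000, 8000)]], "-")
        short = make_gene("S", [[(5000, 5600)]], "+", biotype="protein_coding")
        longer = make_gene("G", [[(6000, 7500)]], "+", biotype="protein_coding")
        pairs = [p for p in build_pair_sets([lnc], [short, longer])
                 if p.category == "antisense_TSS"]
        assert len(pairs) == 1 and pairs[0].pcg_id == "G"

    def test_two_lncs_over_one_promoter_longest_lnc_wins(self):
        pcg = make_gene("P", [[(10_000, 12_000)]], "+", biotype="protein_coding")
        lnc_a = make_gene("A", [[(9_200, 9_700)]], "+")        # 500 nt
        lnc_b = make_gene("B", [[(9_100, 9_900)]], "-")        # 800 nt
        pairs = [p for p in build_pair_sets([lnc_a, lnc_b], [pcg])
                 if p.category == "promoter_overlap"]
        assert [p.lnc_id for p in pairs] == ["B"]

    def test_each_lnc_at_most_once_per_category(self, bundle):
        from lncdiscover.context import expressed_genes
        pcgs = expressed_genes(
            [g for g in bundle.reference if g.biotype == "protein_coding"],
            bundle.expr,
        )
        pairs = build_pair_sets(bundle.candidates, pcgs)
        df = pd.DataFrame([(p.lnc_id, p.category) for p in pairs],
                          columns=["lnc", "cat"])
        assert not df.duplicated().any()


class TestRandomPairs:
    def _sets(self, n_lnc=5, n_sets=10, seed=0):
        lncs = [make_gene(f"L{i}", [[(i * 10_000 + 100, i * 10_000 + 600)]])
                for i in range(n_lnc)]
        pcgs = [make_gene(f"P{i}", [[(i * 10_000 + 5_000, i * 10_000 + 6_000)]],
                          biotype="protein_coding") for i in range(3)]
        return random_pairs(lncs, pcgs, n_sets=n_sets, seed=seed)

    def test_size_is_nsets_times_lncs(self):
        assert len(self._sets(n_lnc=349, n_sets=100)) == 34_900

    def test_seed_reproducible(self):
        a = self._sets(seed=7)
        b = self._sets(seed=7)
        assert [(p.lnc_id, p.pcg_id) for p in a] == [
            (p.lnc_id, p.pcg_id) for p in b
        ]

    def test_zero_sets_empty(self):
        assert self._sets(n_sets=0) == []


class TestCorrelations:
    def _expr(self, rows):
        n = len(next(iter(rows.values())))
        return ExpressionTable(pd.DataFrame.from_dict(
            rows, orient="index", columns=[f"c{i}" for i in range(n)]
        ))

    def test_identical_and_opposite_profiles(self):
        expr = self._expr({
            "L": [1, 2, 3, 4], "Psame": [2, 4, 6, 8], "Popp": [4, 3, 2, 1],
        })
        pairs = [PairRecord("L", "Psame", "closest_any"),
                 PairRecord("L", "Popp", "closest_any")]
        tab, excluded = pair_correlations(pairs, expr, ["c0", "c1", "c2", "c3"])
        assert excluded == 0
        assert tab["r"].tolist() == pytest.approx([1.0, -1.0])

    def test_zero_variance_excluded_and_counted(self):
        expr = self._expr({"L": [1, 2, 3], "P": [5, 5, 5]})
        pairs = [PairRecord("L", "P", "closest_any")]
        tab, excluded = pair_correlations(pairs, expr, ["c0", "c1", "c2"])
        assert tab.empty and excluded == 1

    def test_unknown_condition_errors(self):
        expr = self._expr({"L": [1, 2, 3]})
        with pytest.raises(KeyError):
            pair_correlations([], expr, ["c0", "c1", "nope"])

    def test_too_few_conditions_error(self):
        expr = self._expr({"L": [1, 2, 3]})
        with pytest.raises(ValueError):
            pair_correlations([], expr, ["c0", "c1"])


class TestBackgroundComparison:
    def test_identical_samples_p_near_one(self):
        x = list(np.linspace(-1, 1, 50))
        _, p = compare_category_to_background(x, x)
        assert p > 0.9

    def test_shifted_sample_tiny_p(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 100)
        y = rng.uniform(0, 1, 100)
        _, p = compare_category_to_background(list(x + 1), list(y))
        assert p < 1e-6

    def test_degenerate_input_errors(self):
        with pytest.raises(ValueError):
            compare_category_to_background([0.1], [0.2, 0.3, 0.4, 0.5, 0.6])

    def test_random_background_centred_near_zero(self, bundle):
        from lncdiscover.context import expressed_genes
        pcgs = expressed_genes(
            [g for g in bundle.reference if g.biotype == "protein_coding"],
            bundle.expr,
        )
        rand = random_pairs(bundle.candidates, pcgs, n_sets=50, seed=0)
        conds = ["Meso_34", "Meso_46", "Meso_68", "Meso_34_Nuc",
                 "WE_34", "WE_46", "WE_68"]
        tab, _ = pair_correlations(rand, bundle.expr, conds)
        assert abs(tab["r"].median()) < 0.05
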