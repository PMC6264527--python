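"""Clustering recovery, divergent-transcription profiles, nuclear
enrichment and strain comparison."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import lncdiscover as ld
from lncdiscover.clusters import (
    compare_terciles,
    divergent_profiles,
    iterative_kmeans,
    nuclear_enriched,
    strain_specific,
)
from lncdiscover.simulate import simulate_cluster_profiles

from conftest import make_gene


class TestIterativeKmeans:
    def test_recovers_planted_archetypes(self):
        fpkm, labels = simulate_cluster_profiles(200, sigma=0.2, seed=0)
        res = iterative_kmeans(np.log2(fpkm + 0.1), seed=0)
        common = res.assignments.index
        assert len(common) >= 150
        ari = adjusted_rand_score(labels[common], res.assignments[common])
        assert ari >= 0.9

    def test_seed_reproducible_and_order_invariant(self):
        fpkm, _ = simulate_cluster_profiles(120, sigma=0.3, seed=1)
        a = iterative_kmeans(fpkm, seed=5)
        b = iterative_kmeans(fpkm, seed=5)
        pd.testing.assert_series_equal(a.assignments, b.assignments)
        shuffled = fpkm.sample(frac=1.0, random_state=3)
        c = iterative_kmeans(shuffled, seed=5)
        pd.testing.assert_series_equal(
            a.assignments.sort_index(), c.assignments.sort_index()
        )

    def test_planted_outlier_unassigned(self):
        fpkm, _ = simulate_cluster_profiles(100, sigma=0.1, seed=2)
        out = fpkm.copy()
        # an expression shape correlated with no archetype
        out.loc["OUTLIER"] = [900.0, 1.0, 900.0, 1.0, 900.0, 1.0]
        res = iterative_kmeans(np.log2(out + 0.1), seed=0)
        assert "OUTLIER" not in res.assignments.index

    def test_low_profile_correlation_removed(self):
        fpkm, _ = simulate_cluster_profiles(100, sigma=0.05, seed=3)
        res = iterative_kmeans(np.log2(fpkm + 0.1), seed=0)
        diag = res.diagnostics.set_index("gene_id")
        for g, row in diag.iterrows():
            assigned = g in res.assignments.index
            assert assigned == (row["median_corr"] > 0.905)

    def test_too_few_genes_error(self):
        fpkm, _ = simulate_cluster_profiles(5, sigma=0.1, seed=0)
        with pytest.raises(ValueError):
            iterative_kmeans(fpkm, k1=9)

    def test_every_cluster_has_two_members(self):
        fpkm, _ = simulate_cluster_profiles(150, sigma=0.4, seed=4)
        res = iterative_kmeans(np.log2(fpkm + 0.1), seed=1)
        assert (res.assignments.value_counts() >= 2).all()


def coverage_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])


class TestDivergentProfiles:
    def test_bin_count_is_200_per_strand(self, bundle):
        pcgs = [g for g in bundle.reference
                if g.biotype == "protein_coding"][:5]
        profs = divergent_profiles(pcgs, bundle.coverage)
        for p in profs:
            assert len(p.sense) == 200 and len(p.antisense) == 200

    def test_minus_strand_flip_hand_fixture(self):
        # three genes; the '-' gene's genomic downstream must appear on
        # the left of its profile after orientation normalisation
        plus = make_gene("P", [[(10_000, 11_000)]], "+",
                         biotype="protein_coding")
        minus = make_gene("M", [[(30_000, 31_000)]], "-",
                          biotype="protein_coding")
        other = make_gene("O", [[(50_000, 51_000)]], "+",
                          biotype="protein_coding")
        cov = coverage_frame([
            ("chr1", 10_005, "+", 7),    # P: 5 nt downstream of TSS, sense
            ("chr1", 9_950, "-", 3),     # P: 50 nt upstream, antisense
            ("chr1", 30_994, "-", 7),    # M: TSS at 30_999, 5 nt downstream
            ("chr1", 31_049, "+", 3),    # M: 50 nt upstream, antisense
        ])
        profs = {p.gene_id: p for p in divergent_profiles(
            [plus, minus, other], cov
        )}
        # sense read just downstream of the TSS: first bin right of centre
        assert profs["P"].sense[100] == 7
        assert profs["M"].sense[100] == 7
        # antisense read upstream: left of centre (bin index differs by one
        # between strands because reflection mirrors the half-open bins)
        assert profs["P"].antisense[95] == 3
        assert profs["M"].antisense[94] == 3
        assert profs["P"].antisense[100:].sum() == 0
        assert profs["M"].antisense[100:].sum() == 0

    def test_count_conservation(self, bundle):
        pcgs = [g for g in bundle.reference if g.biotype == "protein_coding"]
        profs = divergent_profiles(pcgs, bundle.coverage)
        total_prof = sum(p.sense.sum() + p.antisense.sum() for p in profs)
        assert total_prof == bundle.coverage["count"].sum()

    def test_zero_antisense_lands_bottom_tercile(self):
        genes = [
            make_gene(f"G{i}", [[(i * 10_000 + 5_000, i * 10_000 + 6_000)]],
                      "+", biotype="protein_coding")
            for i in range(6)
        ]
        rows = []
        for i in range(4):  # four genes with antisense signal
            rows.append(("chr1", i * 10_000 + 4_900, "-", 10 + i))
        cov = coverage_frame(rows)
        profs = {p.gene_id: p for p in divergent_profiles(genes, cov)}
        assert profs["G4"].tercile == "bottom"
        assert profs["G5"].tercile == "bottom"

    def test_edge_tss_padded_and_flagged(self):
        g = make_gene("E", [[(200, 1500)]], "+", biotype="protein_coding")
        profs = divergent_profiles([g], coverage_frame([]))
        assert profs[0].edge_padded


class TestCompareTerciles:
    def test_planted_divergent_high_in_top_tercile(self, bundle):
        pcgs = [g for g in bundle.reference if g.biotype == "protein_coding"]
        profs = divergent_profiles(pcgs, bundle.coverage)
        top = {p.gene_id for p in profs if p.tercile == "top"}
        assert bundle.truth.genes_with("divergent_high") <= top

    def test_planted_expression_effect_detected(self, bundle):
        pcgs = [g for g in bundle.reference if g.biotype == "protein_coding"]
        profs = divergent_profiles(pcgs, bundle.coverage)
        p, med = compare_terciles(profs, bundle.expr.fpkm["Meso_34"])
        assert p < 0.01
        assert med["median_top"] > med["median_bottom"]

    def test_identical_expression_p_near_one(self):
        genes = [
            make_gene(f"G{i}", [[(i * 10_000 + 5_000, i * 10_000 + 6_000)]],
                      "+", biotype="protein_coding")
            for i in range(9)
        ]
        profs = divergent_profiles(genes, coverage_frame([]))
        expr = pd.Series(3.0, index=[g.gene_id for g in genes])
        p, _ = compare_terciles(profs, expr)
        assert p == 1.0

    def test_small_terciles_error(self):
        genes = [make_gene("A", [[(5_000, 6_000)]], "+",
                           biotype="protein_coding")]
        profs = divergent_profiles(genes, coverage_frame([]))
        with pytest.raises(ValueError):
            compare_terciles(profs, pd.Series({"A": 1.0}))


class TestNuclearEnriched:
    def _de(self, padj, lfc, comparison="Nuclear34S_VS_S34"):
        return ld.DETable(pd.DataFrame(
            {"comparison": [comparison], "gene_id": ["g"],
             "log2fc": [lfc], "padj": [padj]}
        ))

    def test_significant_positive_included(self):
        assert nuclear_enriched(self._de(0.005, 2.0)) == {"g"}

    def test_wrong_direction_excluded(self):
        assert nuclear_enriched(self._de(0.005, -2.0)) == set()

    def test_not_significant_excluded(self):
        assert nuclear_enriched(self._de(0.02, 2.0)) == set()

    def test_non_nuclear_comparison_ignored(self):
        assert nuclear_enriched(self._de(0.001, 3.0, "S34_VS_S46")) == set()

    def test_planted_genes_recovered(self, bundle):
        found = nuclear_enriched(bundle.de)
        assert bundle.truth.genes_with("nuclear_enriched") <= found


class TestStrainSpecific:
    def test_threshold_rules(self):
        a = pd.Series({"x": 5.0, "y": 5.0, "z": 0.5, "w": 5.0})
        b = pd.Series({"x": 0.05, "y": 3.0, "z": 9.0, "w": 0.5})
        res = strain_specific(a, b)
        assert res.off_in_b == {"x"}
        assert res.shared == {"y"}
        assert res.intermediate == {"w"}
        assert "z" not in res.selected  # below the 1-FPKM selection gate

    def test_partition_disjoint_and_exhaustive(self, bundle):
        res = strain_specific(bundle.expr.fpkm["WE_68"], bundle.strain_b)
        parts = [res.shared, res.intermediate, res.off_in_b]
        assert sum(len(p) for p in parts) == len(res.selected)
        planted = bundle.truth.genes_with("strain_specific")
        selected_planted = planted & res.selected
        assert selected_planted <= res.off_in_b

    def test_disjoint_ids_error(self):
        with pytest.raises(ValueError):
            strain_specific(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))
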