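import math

import numpy as np
import pandas as pd
import pytest

from coexnet.annotate import (
    Fisher2x2Result,
    GeneSetLibrary,
    cross_disease_overlap,
    fisher_2x2,
    gwas_module_enrichment,
    overrepresentation_test,
    snp_mirna_filter_join,
)
from coexnet.core import UNASSIGNED, ModuleAssignment

from oracles import fisher_two_sided_oracle, hypergeom_upper_tail_oracle


class TestOverrepresentation:
    def test_exact_match_closed_form(self):
        bg = [f"g{i}" for i in range(10)]
        lib = GeneSetLibrary(sets={"S": bg[:5]})
        rec = overrepresentation_test(bg[:5], lib, bg)[0]
        assert rec.p_value == pytest.approx(1 / math.comb(10, 5))
        assert rec.overlap_string == "5/5"

    def test_disjoint_query_p_is_one(self):
        bg = [f"g{i}" for i in range(20)]
        lib = GeneSetLibrary(sets={"S": bg[:5]})
        rec = overrepresentation_test(bg[10:15], lib, bg)[0]
        assert rec.p_value == pytest.approx(1.0)
        assert rec.overlap_count == 0

    def test_overlap_string_uses_in_background_set_size(self):
        bg = [f"g{i}" for i in range(200)]
        # 108 genes in background + 8 outside it; overlap of 7
        lib = GeneSetLibrary(sets={"S": bg[:108] + [f"x{i}" for i in range(8)]})
        rec = overrepresentation_test(bg[:7], lib, bg)[0]
        assert rec.overlap_string == "7/108"

    def test_matches_enumeration_oracle(self, rng):
        bg = [f"g{i}" for i in range(25)]
        for _ in range(10):
            set_genes = list(rng.choice(bg, size=rng.integers(3, 12), replace=False))
            query = list(rng.choice(bg, size=rng.integers(3, 12), replace=False))
            lib = GeneSetLibrary(sets={"S": set_genes})
            rec = overrepresentation_test(query, lib, bg)[0]
            oracle = hypergeom_upper_tail_oracle(
                rec.overlap_count, 25, len(set_genes), len(query)
            )
            assert rec.p_value == pytest.approx(oracle, abs=1e-12)

    def test_stray_query_genes_dropped_with_warning(self):
        bg = [f"g{i}" for i in range(10)]
        lib = GeneSetLibrary(sets={"S": bg[:3]})
        with pytest.warns(UserWarning, match="outside background"):
            rec = overrepresentation_test(["g0", "NOT_THERE"], lib, bg)[0]
        assert rec.overlap_count == 1

    def test_empty_background_rejected(self):
        lib = GeneSetLibrary(sets={"S": ["g0"]})
        with pytest.raises(ValueError):
            overrepresentation_test(["g0"], lib, [])

    def test_records_sorted_by_pvalue_with_bh_column(self):
        bg = [f"g{i}" for i in range(30)]
        lib = GeneSetLibrary(sets={"hit": bg[:5], "miss": bg[20:25]})
        recs = overrepresentation_test(bg[:5], lib, bg)
        assert [r.set_name for r in recs] == ["hit", "miss"]
        assert recs[0].fdr is not None and recs[0].fdr <= recs[1].fdr


class TestFisher2x2:
    def test_balanced_singleton_table(self):
        res = fisher_2x2(1, 0, 0, 1)
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_five_table(self):
        res = fisher_2x2(5, 0, 0, 5)
        assert res.p_value == pytest.approx(2 / math.comb(10, 5))

    def test_zero_cell_conditional_mle_is_finite_or_infinite_without_crash(self):
        res = fisher_2x2(5, 0, 2, 7)
        assert res.odds_ratio == math.inf or res.odds_ratio > 1
        assert res.ci_low >= 0

    def test_invariant_to_simultaneous_row_and_column_swap(self, rng):
        for _ in range(5):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + b + c + d == 0:
                continue
            p1 = fisher_2x2(a, b, c, d).p_value
            p2 = fisher_2x2(d, c, b, a).p_value
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(8):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
            if a + b + c + d == 0 or a + b + c + d > 40:
                continue
            got = fisher_2x2(a, b, c, d).p_value
            want = fisher_two_sided_oracle(a, b, c, d)
            assert got == pytest.approx(want, abs=1e-10), (a, b, c, d)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2(-1, 2, 3, 4)

    def test_ci_brackets_conditional_mle_when_all_cells_positive(self):
        res = fisher_2x2(12, 4, 5, 13)
        assert res.ci_low <= res.odds_ratio <= res.ci_high


class TestGwasEnrichment:
    @staticmethod
    def _assignment(n_np=300, n_total=2000):
        labels = {}
        for i in range(n_total):
            labels[f"g{i:05d}"] = "NP" if i < n_np else ("M2" if i < 1000 else UNASSIGNED)
        return ModuleAssignment(labels=labels)

    def test_concentrated_gwas_genes_detected(self):
        assign = self._assignment()
        gwas = [f"g{i:05d}" for i in range(10)]  # all inside the NP module
        res = gwas_module_enrichment(assign, {"NP"}, gwas)
        assert res.p_value < 0.05
        assert res.odds_ratio == math.inf
        assert res.table[0][0] == 10

    def test_proportional_gwas_genes_not_significant(self, rng):
        assign = self._assignment()
        gwas = [f"g{int(i):05d}" for i in rng.choice(2000, size=15, replace=False)]
        res = gwas_module_enrichment(assign, {"NP"}, gwas)
        assert res.p_value > 0.001  # typically unremarkable

    def test_empty_gwas_list_rejected(self):
        with pytest.raises(ValueError, match="GWAS"):
            gwas_module_enrichment(self._assignment(), {"NP"}, [])

    def test_no_nonpreserved_modules_advises_skip(self):
        with pytest.raises(ValueError, match="skip"):
            gwas_module_enrichment(self._assignment(), set(), ["g00001"])


class TestSnpMirnaJoin:
    @staticmethod
    def _tables():
        gene_snp = pd.DataFrame(
            {
                "gene": ["gA", "gA", "gB", "gC", "gZ"],
                "snp_id": ["rs1", "rs2", "rs3", "rs4", "rs5"],
                "p_value": [1e-6, 1e-4, 1e-5, 1e-7, 1e-9],
                "frequency": [0.3, 0.3, 0.10, 0.2, 0.4],
            }
        )
        snp_mirna = pd.DataFrame(
            {
                "snp_id": ["rs1", "rs1", "rs3", "rs4", "rs5"],
                "mirna_id": ["miR-1", "miR-2", "miR-1", "miR-9", "miR-1"],
            }
        )
        return gene_snp, snp_mirna

    def test_hand_traced_join(self):
        gene_snp, snp_mirna = self._tables()
        # module gA..gC; rs2 fails p (==1e-4), rs3 fails freq (==0.10),
        # rs4 joins to a non-disease miRNA; rs1 joins twice
        hits = snp_mirna_filter_join(
            ["gA", "gB", "gC"], gene_snp, snp_mirna, ["miR-1", "miR-2"]
        )
        assert list(hits.itertuples(index=False, name=None)) == [
            ("gA", "rs1", "miR-1"),
            ("gA", "rs1", "miR-2"),
        ]

    def test_empty_module_gives_empty_table(self):
        gene_snp, snp_mirna = self._tables()
        hits = snp_mirna_filter_join([], gene_snp, snp_mirna, ["miR-1"])
        assert len(hits) == 0

    def test_infinite_thresholds_reproduce_unfiltered_join(self):
        gene_snp, snp_mirna = self._tables()
        hits = snp_mirna_filter_join(
            ["gA", "gB", "gC", "gZ"], gene_snp, snp_mirna,
            ["miR-1", "miR-2", "miR-9"], p_thresh=math.inf, freq_thresh=0.0,
        )
        merged = gene_snp.merge(snp_mirna, on="snp_id")
        assert len(hits) == len(merged[merged.frequency > 0])

    def test_missing_column_names_schema_error(self):
        gene_snp, snp_mirna = self._tables()
        with pytest.raises(ValueError, match="frequency"):
            snp_mirna_filter_join(
                ["gA"], gene_snp.drop(columns=["frequency"]), snp_mirna, ["miR-1"]
            )


class TestCrossDiseaseOverlap:
    @staticmethod
    def _hits(snps, genes=None):
        genes = genes or [f"g{i}" for i in range(len(snps))]
        return pd.DataFrame({"gene": genes, "snp_id": snps, "mirna_id": "miR-1"})

    def test_identical_tables_fully_overlap(self):
        h = self._hits(["rs1", "rs2", "rs3"])
        shared, counts = cross_disease_overlap(h, h)
        assert shared == ["rs1", "rs2", "rs3"]
        assert counts["n_shared"] == counts["n_a"] == 3

    def test_disjoint_tables_share_nothing(self):
        shared, counts = cross_disease_overlap(self._hits(["rs1"]), self._hits(["rs2"]))
        assert shared == []
        assert counts["n_shared"] == 0

    def test_planted_intersection_recovered(self):
        a = self._hits(["rs1", "rs2", "rs3", "rs4"])
        b = self._hits(["rs3", "rs4", "rs1", "rs9"])
        shared, counts = cross_disease_overlap(a, b)
        assert shared == ["rs1", "rs3", "rs4"]
        assert counts["n_shared"] == 3


def test_gmt_round_trip(tmp_path):
    lib = GeneSetLibrary(sets={"alpha": ["g1", "g2"], "beta": ["g3"]}, source="KEGG")
    path = tmp_path / "lib.gmt"
    lib.to_gmt(path)
    back = GeneSetLibrary.from_gmt(path)
    assert back.sets == lib.sets


def test_empty_gene_set_rejected():
    with pytest.raises(ValueError):
        GeneSetLibrary(sets={"empty": []})
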