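import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eqtplot import (AnalysisConfig, ValidationError, enrichment_test,
                     pp_correlation, pp_points, rank_genes, rank_tissues,
                     select_lead_variant)
from eqtplot.locus import collapse_tissues, define_locus, build_locus_table
from .oracles import fisher_two_sided, pearson_r


def _table_from_counts(a, b, c, d):
    """Locus-variant frame realizing given 2x2 enrichment counts."""
    n = a + b + c + d
    sig = [True] * (a + b) + [False] * (c + d)
    eqtl = [True] * a + [False] * b + [True] * c + [False] * d
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(n)],
        "bp": np.arange(n) + 1,
        "p_gwas": np.where(sig, 1e-9, 0.5),
        "beta": 1.0,
        "has_eqtl": eqtl,
        "p_eqtl": np.where(eqtl, 0.01, np.nan),
        "nes": np.where(eqtl, 0.5, np.nan),
        "congruence_class": "not_applicable",
        "gwas_significant": sig,
    })


class TestEnrichment:
    def test_printed_example_counts(self):
        res = enrichment_test(_table_from_counts(8, 2, 10, 80))
        assert (res.a, res.b, res.c, res.d) == (8, 2, 10, 80)
        assert res.fisher_p == pytest.approx(8.6e-6, rel=0.01)
        assert res.fisher_p < 1e-4
        assert res.proportion_sig == pytest.approx(0.8)

    def test_balanced_table_p_is_one(self):
        res = enrichment_test(_table_from_counts(5, 5, 5, 5))
        assert res.fisher_p == pytest.approx(1.0)

    def test_empty_margin_is_degenerate(self, caplog):
        with caplog.at_level("WARNING", logger="eqtplot"):
            res = enrichment_test(_table_from_counts(0, 0, 5, 5))
        assert res.degenerate and res.fisher_p == 1.0

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            counts = rng.multinomial(rng.integers(4, 60),
                                     [0.25, 0.25, 0.25, 0.25])
            a, b, c, d = (int(x) for x in counts)
            if (a + b) == 0 or (c + d) == 0:
                continue
            res = enrichment_test(_table_from_counts(a, b, c, d))
            assert res.fisher_p == pytest.approx(
                fisher_two_sided(a, b, c, d), rel=1e-12)

    def test_counts_conserved(self, locus_frame):
        res = enrichment_test(locus_frame)
        assert res.a + res.b == int(locus_frame["gwas_significant"].sum())
        assert res.a + res.b + res.c + res.d == len(locus_frame)

    def test_congruence_strata_partition_eqtls(self):
        table = _table_from_counts(8, 2, 10, 80)
        cls = np.where(table["has_eqtl"],
                       np.where(np.arange(len(table)) % 2 == 0,
                                "congruous", "incongruous"),
                       "not_applicable")
        table = table.assign(congruence_class=cls)
        con = enrichment_test(table, "congruous")
        inc = enrichment_test(table, "incongruous")
        # strata share the non-eQTL comparison group, split the eQTLs
        assert con.b == inc.b and con.d == inc.d
        assert con.a + inc.a == 8
        assert con.c + inc.c == 10


class TestPPCorrelation:
    def _frame(self, pairs):
        x, y = zip(*pairs)
        return pd.DataFrame({
            "snp": [f"rs{i}" for i in range(len(pairs))],
            "bp": np.arange(len(pairs)) + 1,
            "p_gwas": 10.0 ** (-np.asarray(y)),
            "beta": 1.0,
            "has_eqtl": True,
            "p_eqtl": 10.0 ** (-np.asarray(x)),
            "nes": 0.5,
            "congruence_class": "not_applicable",
            "gwas_significant": False,
        })

    def test_three_point_example_r_is_half(self):
        res = pp_correlation(self._frame([(1, 1), (2, 3), (3, 2)]))
        assert res.pearson_r == pytest.approx(0.5, abs=1e-12)
        assert res.pearson_r == pytest.approx(
            pearson_r([1, 2, 3], [1, 3, 2]), abs=1e-12)

    def test_collinear_points_r_is_one(self):
        res = pp_correlation(self._frame([(1, 1), (2, 2), (5, 5), (9, 9)]))
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_fewer_than_three_points_flagged(self):
        res = pp_correlation(self._frame([(1, 1), (2, 3)]))
        assert not res.defined and np.isnan(res.pearson_r)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.floats(0.1, 20), st.floats(0.1, 20)),
                    min_size=4, max_size=25, unique_by=lambda t: t[0]),
           st.floats(0.1, 5), st.floats(-3, 3))
    def test_affine_invariance_of_r(self, pairs, scale, shift):
        frame = self._frame(pairs)
        base = pp_correlation(frame)
        rescaled = frame.assign(
            p_eqtl=10.0 ** -(scale * (-np.log10(frame["p_eqtl"])) + shift))
        res = pp_correlation(rescaled)
        if base.defined and res.defined:
            assert res.pearson_r == pytest.approx(base.pearson_r, abs=1e-6)


class TestSelectLead:
    def _pts(self, triples):
        return pd.DataFrame(triples, columns=["snp", "x", "y"])

    def test_maximizes_coordinate_sum(self):
        pts = self._pts([("v1", 3, 2), ("v2", 4, 4), ("v3", 5, 2)])
        assert select_lead_variant(pts) == "v2"

    def test_single_point(self):
        assert select_lead_variant(self._pts([("v1", 1, 1)])) == "v1"

    def test_tie_broken_by_gwas_coordinate(self):
        pts = self._pts([("v1", 4, 4), ("v2", 5, 3)])
        assert select_lead_variant(pts) == "v1"

    def test_user_lead_must_be_in_both_tables(self):
        pts = self._pts([("v1", 1, 1)])
        assert select_lead_variant(pts, "v9", gwas_snps={"v9"},
                                   ld_snps={"v9"}) == "v9"
        with pytest.raises(ValidationError, match="GWAS"):
            select_lead_variant(pts, "v9", gwas_snps={"v1"}, ld_snps={"v9"})
        with pytest.raises(ValidationError, match="LD"):
            select_lead_variant(pts, "v9", gwas_snps={"v9"}, ld_snps={"v1"})


class TestRankings:
    def test_single_gene_list_matches_direct_correlation(self, shared_sim,
                                                         default_config):
        gwas, eqtl, genes, _ = shared_sim
        entries = rank_genes(gwas, eqtl, ["GENE1"], genes, default_config)
        locus = define_locus("GENE1", genes, default_config.range_kb)
        collapsed = collapse_tissues(eqtl, "all", "min")
        table = build_locus_table(gwas, collapsed, locus, default_config)
        direct = pp_correlation(table)
        assert len(entries) == 1
        assert entries[0].pearson_r == pytest.approx(direct.pearson_r)
        assert entries[0].p_correlation == pytest.approx(direct.p_correlation)

    def test_identical_genes_identical_r_and_stable_order(self, shared_sim,
                                                          default_config):
        gwas, eqtl, genes, _ = shared_sim
        twin = genes.iloc[[0]].assign(gene="GENE2")
        genes2 = pd.concat([genes, twin], ignore_index=True)
        eqtl2 = pd.concat([eqtl, eqtl.assign(gene="GENE2")],
                          ignore_index=True)
        entries = rank_genes(gwas, eqtl2, ["GENE2", "GENE1"], genes2,
                             default_config)
        assert entries[0].pearson_r == entries[1].pearson_r
        assert [e.key for e in entries] == ["GENE1", "GENE2"]  # name tiebreak

    def test_rank_tissues_all_gives_one_entry_per_tissue(self, shared_sim,
                                                         default_config):
        gwas, eqtl, genes, _ = shared_sim
        entries = rank_tissues(gwas, eqtl, "GENE1", "all", genes,
                               default_config)
        assert sorted(e.key for e in entries) == sorted(
            eqtl["tissue"].unique())
        ps = [e.p_correlation for e in entries if e.defined]
        assert ps == sorted(ps)

    def test_sparse_tissue_flagged_and_last(self, shared_sim,
                                            default_config):
        gwas, eqtl, genes, _ = shared_sim
        sparse = eqtl[eqtl["tissue"] == "Liver"].head(2).assign(
            tissue="Rare_Tissue")
        eqtl2 = pd.concat([eqtl, sparse], ignore_index=True)
        entries = rank_tissues(gwas, eqtl2, "GENE1", "all", genes,
                               default_config)
        assert entries[-1].key == "Rare_Tissue"
        assert not entries[-1].defined
        assert "insufficient" in entries[-1].format("tissue")
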