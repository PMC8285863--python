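import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eqtplot import (AnalysisConfig, EmptyInputError, MetaSampleSizeError,
                     UnknownGeneError, UnknownTissueError,
                     build_locus_table, classify_congruence, collapse_tissues,
                     define_locus, weighted_z_meta)
from .oracles import stouffer_two_sided

GENES = pd.DataFrame({"gene": ["ABC", "XYZ"], "chrom": [1, 2],
                      "start": [1_000_000, 500], "stop": [1_050_000, 900],
                      "build": "hg19"})


class TestDefineLocus:
    @pytest.mark.parametrize("range_kb,start,stop", [
        (200, 800_000, 1_250_000),
        (0, 1_000_000, 1_050_000),
    ])
    def test_flank_arithmetic(self, range_kb, start, stop):
        locus = define_locus("ABC", GENES, range_kb)
        assert (locus.start_bp, locus.stop_bp) == (start, stop)

    def test_lower_bound_floored_at_one(self):
        locus = define_locus("XYZ", GENES, 10)
        assert locus.start_bp == 1

    def test_unknown_gene_lists_nearby_symbols(self):
        with pytest.raises(UnknownGeneError, match="ABC"):
            define_locus("NOPE", GENES, 200)


class TestWeightedZMeta:
    def test_single_study_returns_its_own_p(self):
        assert weighted_z_meta([0.037], [1.0], [100]) == pytest.approx(
            0.037, rel=1e-9)

    def test_opposite_signs_equal_weight_cancel_to_one(self):
        assert weighted_z_meta([0.01, 0.01], [1.0, -1.0], [50, 50]) \
            == pytest.approx(1.0)

    def test_two_equal_studies_match_independent_oracle(self):
        got = weighted_z_meta([0.05, 0.05], [1.0, 1.0], [100, 100])
        expected = stouffer_two_sided([0.05, 0.05], [1, 1], [100, 100])
        assert got == pytest.approx(expected, rel=1e-6)
        assert got == pytest.approx(5.6e-3, rel=0.01)

    def test_missing_n_requires_equal_n_flag(self):
        with pytest.raises(MetaSampleSizeError, match="assume_equal_n"):
            weighted_z_meta([0.05, 0.05], [1.0, 1.0], None)
        p = weighted_z_meta([0.05, 0.05], [1.0, 1.0], None,
                            assume_equal_n=True)
        assert p == pytest.approx(5.6e-3, rel=0.01)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(1e-6, 1.0), st.sampled_from([-1, 1]),
                              st.integers(10, 1000)),
                    min_size=2, max_size=6))
    def test_permutation_invariance(self, studies):
        p, s, n = zip(*studies)
        forward = weighted_z_meta(p, s, n)
        reverse = weighted_z_meta(p[::-1], s[::-1], n[::-1])
        assert forward == pytest.approx(reverse, rel=1e-12)

    def test_monotone_in_component_significance(self):
        base = weighted_z_meta([0.05, 0.5], [1, 1], [100, 100])
        stronger = weighted_z_meta([0.05, 0.1], [1, 1], [100, 100])
        assert stronger < base


class TestClassifyCongruence:
    @pytest.mark.parametrize("beta,nes,expected", [
        (0.1, 0.8, "congruous"),
        (-0.1, -0.8, "congruous"),
        (0.1, -0.8, "incongruous"),
        (0.0, 0.8, "not_applicable"),
        (0.1, 0.0, "not_applicable"),
    ])
    def test_sign_rules(self, beta, nes, expected):
        assert classify_congruence(beta, nes) == expected


class TestCollapseTissues:
    def test_single_tissue_identity(self, small_eqtl):
        for method in ("min", "median", "mean", "meta"):
            out = collapse_tissues(small_eqtl, "Liver", method)
            rs1 = out[out["snp"] == "rs1"].iloc[0]
            assert rs1["p_eqtl"] == pytest.approx(0.01, rel=1e-9)
            if method != "meta":
                assert rs1["nes"] == pytest.approx(0.5)

    def test_min_takes_p_and_nes_from_same_tissue(self, small_eqtl):
        out = collapse_tissues(small_eqtl, "all", "min")
        rs2 = out[out["snp"] == "rs2"].iloc[0]
        assert (rs2["p_eqtl"], rs2["nes"]) == (0.04, -0.8)
        assert rs2["source_tissue"] == "Blood"

    def test_mean_collapses_both_p_and_nes(self, small_eqtl):
        out = collapse_tissues(small_eqtl, "all", "mean")
        rs1 = out[out["snp"] == "rs1"].iloc[0]
        assert rs1["p_eqtl"] == pytest.approx(0.105)
        assert rs1["nes"] == pytest.approx(0.1)

    def test_meta_has_no_nes_and_matches_oracle(self, small_eqtl):
        out = collapse_tissues(small_eqtl, "all", "meta")
        rs1 = out[out["snp"] == "rs1"].iloc[0]
        assert np.isnan(rs1["nes"])
        expected = stouffer_two_sided([0.01, 0.2], [1, -1], [100, 200])
        assert rs1["p_eqtl"] == pytest.approx(expected, rel=1e-6)

    def test_meta_without_n_column_errors(self, small_eqtl):
        no_n = small_eqtl.drop(columns="n")
        with pytest.raises(MetaSampleSizeError):
            collapse_tissues(no_n, "all", "meta")
        out = collapse_tissues(no_n, "all", "meta", assume_equal_n=True)
        assert len(out) == 3

    def test_unknown_tissue_errors(self, small_eqtl):
        with pytest.raises(UnknownTissueError, match="Kidney"):
            collapse_tissues(small_eqtl, "Kidney", "min")

    def test_min_tie_broken_by_larger_abs_nes_then_name(self):
        df = pd.DataFrame({
            "snp": ["rs1"] * 3, "gene": "G",
            "p_eqtl": [0.02, 0.02, 0.02],
            "nes": [0.1, -0.9, 0.9],
            "tissue": ["A", "C", "B"],
        })
        out = collapse_tissues(df, "all", "min")
        assert out["source_tissue"].iloc[0] == "B"
        assert out["nes"].iloc[0] == 0.9

    @pytest.mark.parametrize("method", ["min", "median", "mean"])
    def test_collapse_matches_bruteforce_on_random_fixtures(self, method):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_snp = rng.integers(1, 15)
            n_tis = rng.integers(1, 20)
            rows = []
            for i in range(n_snp):
                for t in rng.choice(n_tis, rng.integers(1, n_tis + 1),
                                    replace=False):
                    rows.append((f"rs{i}", rng.uniform(1e-8, 1),
                                 rng.normal(), f"t{t}"))
            df = pd.DataFrame(rows, columns=["snp", "p_eqtl", "nes",
                                             "tissue"]).assign(gene="G")
            out = collapse_tissues(df, "all", method).set_index("snp")
            for snp, grp in df.groupby("snp"):
                if method == "min":
                    best = grp.loc[grp["p_eqtl"].idxmin()]
                    assert out.loc[snp, "p_eqtl"] == best["p_eqtl"]
                else:
                    fn = np.median if method == "median" else np.mean
                    assert out.loc[snp, "p_eqtl"] == pytest.approx(
                        fn(grp["p_eqtl"]))
                    assert out.loc[snp, "nes"] == pytest.approx(
                        fn(grp["nes"]))


class TestBuildLocusTable:
    def _inputs(self):
        gwas = pd.DataFrame({
            "chrom": [1, 1, 1, 1], "bp": [100, 200, 300, 5000],
            "snp": ["rs1", "rs2", "rs3", "rs4"],
            "p_gwas": [1e-9, 0.5, 0.2, 1e-10],
            "beta": [0.3, -0.1, 0.2, 0.4],
        })
        collapsed = pd.DataFrame({
            "snp": ["rs1", "rs3", "rs9"],
            "p_eqtl": [0.001, 0.06, 0.001],
            "nes": [0.5, 0.2, 0.9],
            "source_tissue": "Liver", "method": "min",
        })
        from eqtplot.locus import Locus
        locus = Locus("G", 1, 50, 1000)
        return gwas, collapsed, locus

    def test_join_semantics(self, default_config):
        gwas, collapsed, locus = self._inputs()
        table = build_locus_table(gwas, collapsed, locus, default_config)
        assert table["snp"].tolist() == ["rs1", "rs2", "rs3"]  # rs4 outside
        by = table.set_index("snp")
        assert bool(by.loc["rs1", "has_eqtl"])          # qualifying eQTL
        assert not bool(by.loc["rs2", "has_eqtl"])      # no record
        assert not bool(by.loc["rs3", "has_eqtl"])      # p 0.06 > 0.05
        assert bool(by.loc["rs1", "gwas_significant"])
        assert "rs9" not in by.index                    # eQTL-only variant

    def test_row_count_equals_gwas_rows_in_window(self, shared_sim,
                                                  default_config):
        gwas, eqtl, genes, _ = shared_sim
        locus = define_locus("GENE1", genes, default_config.range_kb)
        collapsed = collapse_tissues(eqtl, "all", "min")
        table = build_locus_table(gwas, collapsed, locus, default_config)
        expected = int(((gwas["bp"] >= locus.start_bp)
                        & (gwas["bp"] <= locus.stop_bp)).sum())
        assert len(table) == expected
        assert table["snp"].is_unique

    def test_empty_locus_errors_with_bounds(self, default_config):
        gwas, collapsed, _ = self._inputs()
        from eqtplot.locus import Locus
        with pytest.raises(EmptyInputError, match="90000"):
            build_locus_table(gwas, collapsed, Locus("G", 1, 90000, 99000),
                              default_config)

    def test_congruence_classes_assigned_only_to_qualifying_eqtls(self):
        gwas = pd.DataFrame({
            "chrom": [1, 1], "bp": [100, 200], "snp": ["rs1", "rs2"],
            "p_gwas": [1e-9, 0.5], "beta": [0.3, -0.1]})
        collapsed = pd.DataFrame({
            "snp": ["rs1", "rs2"], "p_eqtl": [0.001, 0.001],
            "nes": [-0.5, 0.2], "source_tissue": "L", "method": "min"})
        from eqtplot.locus import Locus
        config = AnalysisConfig(congruence=True)
        table = build_locus_table(gwas, collapsed, Locus("G", 1, 50, 300),
                                  config).set_index("snp")
        assert table.loc["rs1", "congruence_class"] == "incongruous"
        assert table.loc["rs2", "congruence_class"] == "incongruous"
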