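import numpy as np
import pandas as pd
import pytest

from allomethyl import assoc, dmr

from conftest import make_matrix


def genes_df(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "homolog_id"]
    )


def dmrs_df(intervals):
    return pd.DataFrame(intervals, columns=["chrom", "start", "end"])


class TestGenesNearDmrs:
    gene = genes_df([("g1", "Chr1", 3000, 4000, "+", None)])

    def test_flank_boundary_inclusive(self):
        links = assoc.genes_near_dmrs(dmrs_df([("Chr1", 1000, 1100)]), self.gene)
        assert links["gene_id"].tolist() == ["g1"]
        assert links.iloc[0]["relation"] == "flank5"
        assert links.iloc[0]["distance"] == 1900

    def test_flank_boundary_exclusive(self):
        # DMR [999,1000) ends exactly where the 2-kb flank starts
        links = assoc.genes_near_dmrs(dmrs_df([("Chr1", 999, 1000)]), self.gene)
        assert links.empty

    def test_body_relation(self):
        links = assoc.genes_near_dmrs(dmrs_df([("Chr1", 3200, 3300)]), self.gene)
        assert links.iloc[0][["relation", "distance"]].tolist() == ["body", 0]

    def test_zero_flank_equals_body_only(self):
        d = dmrs_df([("Chr1", 2900, 3000), ("Chr1", 3000, 3100)])
        links = assoc.genes_near_dmrs(d, self.gene, flank=0)
        assert links["start"].tolist() == [3000]

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            assoc.genes_near_dmrs(dmrs_df([]), self.gene, flank=-1)


class TestGeneMethylation:
    def test_pooled_level(self):
        m = make_matrix(
            [("Chr1", 11, "+", "CG"), ("Chr1", 21, "+", "CG")],
            {"x": [(5, 10), (5, 10)]},
        )
        gene = genes_df([("g1", "Chr1", 0, 100, "+", None)]).iloc[0]
        assert assoc.gene_methylation(m, gene)["x"] == pytest.approx(0.5)

    def test_no_sites_flagged_missing(self):
        m = make_matrix([("Chr1", 500, "+", "CG")], {"x": [(1, 2)]})
        gene = genes_df([("g1", "Chr1", 0, 100, "+", None)]).iloc[0]
        assert np.isnan(assoc.gene_methylation(m, gene)["x"])

    def test_agrees_with_window_pooling_for_one_tile(self):
        m = make_matrix(
            [("Chr1", p, "+", "CG") for p in (5, 25, 45, 65)],
            {"x": [(2, 9), (3, 7), (0, 5), (4, 4)]},
        )
        gene = genes_df([("g1", "Chr1", 0, 100, "+", None)]).iloc[0]
        w = dmr.make_windows(m, 100, 100)
        pooled = w.iloc[0]["x.meth"] / w.iloc[0]["x.total"]
        assert assoc.gene_methylation(m, gene)["x"] == pytest.approx(pooled)


def expr_table(values, replicates=1):
    rows = []
    for gene, per_line in values.items():
        for line, tpms in per_line.items():
            tpms = np.atleast_1d(tpms)
            for r, v in enumerate(tpms, start=1):
                rows.append((gene, line, r, float(v)))
    return pd.DataFrame(rows, columns=["gene_id", "line", "replicate", "tpm"])


class TestExpressionRatio:
    def test_identity_and_hand_arithmetic(self):
        expr = expr_table({"g1": {"asu": 8.0, "aar": 8.0}, "g2": {"asu": 15.0, "aar": 3.0}})
        assert assoc.expression_ratio(expr, "g1", "asu", "aar") == 0.0
        assert assoc.expression_ratio(expr, "g2", "asu", "aar") == pytest.approx(2.0)

    def test_pseudocount_guard(self):
        expr = expr_table({"g1": {"asu": 0.0, "aar": 0.0}})
        assert assoc.expression_ratio(expr, "g1", "asu", "aar") == 0.0

    def test_absent_gene(self):
        expr = expr_table({"g1": {"asu": 1.0, "aar": 1.0}})
        with pytest.raises(KeyError):
            assoc.expression_ratio(expr, "gX", "asu", "aar")

    def test_vectorised_matches_scalar(self):
        expr = expr_table(
            {"g1": {"asu": [4.0, 6.0], "aar": [1.0, 3.0]}, "g2": {"asu": 2.0, "aar": 9.0}}
        )
        ratios = assoc.expression_ratios(expr, "asu", "aar")
        for g in ("g1", "g2"):
            assert ratios[g] == pytest.approx(assoc.expression_ratio(expr, g, "asu", "aar"))


class TestCompareGroups:
    def test_exact_enumeration_case(self):
        # complete separation of 3 vs 3: U = 0, two-sided p = 2/20
        u, p = assoc.compare_groups([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_central(self):
        _, p = assoc.compare_groups([1.0, 2.0, 3.0, 4.0], [1.5, 2.5, 3.5, 0.5])
        assert p > 0.5

    def test_label_swap_antisymmetry(self):
        x, y = [1.0, 5.0, 9.0, 11.0], [2.0, 3.0, 8.0]
        u1, p1 = assoc.compare_groups(x, y)
        u2, p2 = assoc.compare_groups(y, x)
        assert u1 + u2 == len(x) * len(y)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            assoc.compare_groups([], [1.0])


class TestCorrelation:
    def test_sign_on_opposing_monotone_data(self):
        r = assoc.methylation_expression_correlation(
            [0.9, 0.8, 0.7, 0.6, 0.2], [1, 2, 3, 4, 8]
        )
        assert r < 0

    def test_exact_linear_relation(self):
        m = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        r = assoc.methylation_expression_correlation(m, 5 - 2 * m)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        assert np.isnan(assoc.methylation_expression_correlation([0.5] * 5, [1, 2, 3, 4, 5]))

    def test_permutation_null_centred_at_zero(self):
        rng = np.random.default_rng(5)
        m = rng.random(5)
        e = rng.random(5)
        rs = [
            assoc.methylation_expression_correlation(m, rng.permutation(e))
            for _ in range(300)
        ]
        assert abs(np.mean(rs)) < 3 * np.std(rs) / np.sqrt(len(rs)) + 0.05


class TestHomologConvergence:
    def test_candidate_and_decreased_rules(self):
        pairs = pd.DataFrame(
            {
                "m_parent_a": [0.75, 0.45, 0.75],
                "m_parent_t": [0.15, 0.15, 0.15],
                "m_asu_a": [0.25, 0.15, 0.75],
                "m_asu_t": [0.15, 0.15, 0.15],
                "log2_parents": [2.0, 2.0, 2.0],
                "log2_asu": [0.5, 0.5, 2.5],
            }
        )
        out = assoc.homolog_convergence(pairs)
        # row 0: candidate and decreased; row 1: parent diff 0.3 < 0.5 -> not a
        # candidate; row 2: Asu homologs still differ by 0.6 -> not a candidate
        assert (out["n_candidates"], out["n_decreased"]) == (1, 1)
        assert out["fraction"] == 1.0

    def test_no_candidates_flagged(self):
        pairs = pd.DataFrame(
            {
                "m_parent_a": [0.2],
                "m_parent_t": [0.15],
                "m_asu_a": [0.2],
                "m_asu_t": [0.15],
                "log2_parents": [0.1],
                "log2_asu": [0.1],
            }
        )
        assert np.isnan(assoc.homolog_convergence(pairs)["fraction"])


class TestUpregulation:
    def test_flat_expression_gives_none(self):
        expr = expr_table(
            {
                g: {ln: [4.0, 4.1, 3.9] for ln in ("asu", "aar", "ath")}
                for g in ("a1", "t1")
            }
        )
        pairs = pd.DataFrame({"gene_a": ["a1"], "gene_t": ["t1"]})
        out = assoc.upregulation_breakdown(pairs, expr)
        assert out["counts"]["none"] == 1
        assert out["fraction_upregulated"] == 0.0

    def test_planted_a_only_effect_detected(self):
        rng = np.random.default_rng(2)
        noise = lambda: (1 + rng.normal(0, 0.02, 3)).tolist()
        expr = expr_table(
            {
                "a1": {"asu": (16 * np.array(noise())).tolist(), "aar": (8 * np.array(noise())).tolist()},
                "t1": {"asu": (8 * np.array(noise())).tolist(), "ath": (8 * np.array(noise())).tolist()},
            }
        )
        pairs = pd.DataFrame({"gene_a": ["a1"], "gene_t": ["t1"]})
        out = assoc.upregulation_breakdown(pairs, expr)
        assert out["counts"]["A_only"] == 1

    def test_missing_homolog_skipped_and_counted(self):
        expr = expr_table({"a1": {"asu": 4.0, "aar": 4.0, "ath": 4.0}})
        pairs = pd.DataFrame({"gene_a": ["a1"], "gene_t": ["missing"]})
        out = assoc.upregulation_breakdown(pairs, expr)
        assert out["counts"]["skipped"] == 1
        assert np.isnan(out["fraction_upregulated"])

    def test_classes_partition_the_pairs(self):
        rng = np.random.default_rng(9)
        values, pairs = {}, []
        for i in range(12):
            up_a, up_t = rng.random() < 0.5, rng.random() < 0.5
            mk = lambda up: (np.full(3, 16.0 if up else 4.0) * (1 + rng.normal(0, 0.02, 3))).tolist()
            values[f"a{i}"] = {"asu": mk(up_a), "aar": mk(False)}
            values[f"t{i}"] = {"asu": mk(up_t), "ath": mk(False)}
            pairs.append((f"a{i}", f"t{i}"))
        out = assoc.upregulation_breakdown(
            pd.DataFrame(pairs, columns=["gene_a", "gene_t"]), expr_table(values)
        )
        c = out["counts"]
        assert c["A_only"] + c["T_only"] + c["both"] + c["none"] == 12
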