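"""Unit and property tests for the window-level DMR caller.

The Fisher test is checked against an exact integer-arithmetic enumeration
of the hypergeometric distribution (and against scipy), the BH adjustment
against a hand-rolled step-up, and the calling logic against worked tables.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from allomethyl import dmr

from conftest import fisher_oracle, make_matrix


def bh_oracle(p):
    """Hand step-up: q_(i) = min_{j >= i} p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = min(running, 1.0)
    return q


class TestWeightedMethylation:
    def test_hand_summed_pool(self):
        # sites (5/10), (3/10), (0/10) pooled -> 8/30
        assert dmr.weighted_methylation(8, 30) == pytest.approx(8 / 30)

    def test_extremes_and_missing(self):
        assert dmr.weighted_methylation(7, 7) == 1.0
        assert dmr.weighted_methylation(0, 9) == 0.0
        assert np.isnan(dmr.weighted_methylation(0, 0))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            dmr.weighted_methylation(5, 3)


class TestFisher:
    def test_worked_examples(self):
        assert dmr.fisher_exact_2x2(1, 0, 0, 1) == pytest.approx(1.0, abs=1e-12)
        assert dmr.fisher_exact_2x2(2, 0, 0, 2) == pytest.approx(1 / 3, abs=1e-12)
        assert dmr.fisher_exact_2x2(10, 10, 10, 10) == pytest.approx(1.0, abs=1e-12)

    def test_zero_margin_convention(self):
        assert dmr.fisher_exact_2x2(0, 0, 3, 4) == 1.0
        assert dmr.fisher_exact_2x2(0, 5, 0, 7) == 1.0

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            dmr.fisher_exact_2x2(-1, 1, 1, 1)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(0, 16), st.integers(0, 16), st.integers(0, 16), st.integers(0, 16)))
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        expected = float(fisher_oracle(a, b, c, d))
        assert dmr.fisher_exact_2x2(a, b, c, d) == pytest.approx(expected, rel=1e-9, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)))
    def test_matches_scipy(self, table):
        from scipy.stats import fisher_exact

        a, b, c, d = table
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return  # convention differs only in flagging, both return 1
        expected = fisher_exact([[a, b], [c, d]]).pvalue
        assert dmr.fisher_exact_2x2(a, b, c, d) == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestBH:
    def test_worked_example(self):
        q = dmr.bh_fdr([0.01, 0.02, 0.03, 0.5])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.5], abs=1e-12)

    def test_degenerate_inputs(self):
        assert dmr.bh_fdr([0.2]) == pytest.approx([0.2])
        assert dmr.bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            dmr.bh_fdr([0.5, 1.5])

    def test_properties_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = rng.random(rng.integers(1, 60))
            q = dmr.bh_fdr(p)
            assert np.all(q >= p - 1e-12)
            assert np.all(q <= 1.0 + 1e-12)
            order = np.argsort(p, kind="mergesort")
            assert np.all(np.diff(q[order]) >= -1e-12)  # monotone transform
            assert q == pytest.approx(bh_oracle(p), abs=1e-12)


class TestMakeWindows:
    def test_arithmetic_tiling(self):
        m = make_matrix(
            [("Chr1", p, "+", "CG") for p in (11, 51, 151)],  # 0-based 10, 50, 150
            {"x": [(1, 2)] * 3},
        )
        w = dmr.make_windows(m, 100, 100)
        assert w[["start", "n_sites"]].values.tolist() == [[0, 2], [100, 1]]

    def test_overlapping_step(self):
        m = make_matrix([("Chr1", 61, "+", "CG")], {"x": [(1, 2)]})
        w = dmr.make_windows(m, 100, 50)
        assert w["start"].tolist() == [0, 50]

    def test_empty_matrix(self):
        m = make_matrix([], {"x": []})
        assert dmr.make_windows(m).empty

    def test_invalid_geometry(self):
        m = make_matrix([("Chr1", 1, "+", "CG")], {"x": [(1, 2)]})
        with pytest.raises(ValueError):
            dmr.make_windows(m, 0, 100)


def _one_window(meth_focal, total_focal, meth_ref, total_ref, context="CG", n_sites=4):
    return pd.DataFrame(
        {
            "chrom": ["Chr1"],
            "start": [0],
            "end": [100],
            "context": [context],
            "n_sites": [n_sites],
            "f.meth": [meth_focal],
            "f.total": [total_focal],
            "r.meth": [meth_ref],
            "r.total": [total_ref],
        }
    )


class TestCallDmrs:
    def test_large_difference_is_hyper(self):
        out = dmr.call_dmrs(_one_window(90, 100, 20, 100), "f", "r", "CG")
        assert len(out) == 1
        row = out.iloc[0]
        assert row["direction"] == "hyper"
        assert row["delta"] == pytest.approx(0.7)
        assert row["p"] == pytest.approx(float(fisher_oracle(90, 10, 20, 80)), rel=1e-9)

    def test_below_effect_cutoff_not_called(self):
        # delta 0.4 < 0.5: significant p but fails the CG effect cutoff
        out = dmr.call_dmrs(_one_window(900, 1000, 500, 1000), "f", "r", "CG")
        assert out.empty

    def test_swap_flips_direction_same_p(self):
        a = dmr.test_windows(_one_window(90, 100, 20, 100), "f", "r", "CG")
        b = dmr.test_windows(_one_window(20, 100, 90, 100), "f", "r", "CG")
        assert a.iloc[0]["p"] == pytest.approx(b.iloc[0]["p"], rel=1e-12)
        assert (a.iloc[0]["direction"], b.iloc[0]["direction"]) == ("hyper", "hypo")

    def test_site_minimum_enforced_per_context(self):
        few = _one_window(90, 100, 10, 100, context="CHH", n_sites=15)
        assert dmr.test_windows(few, "f", "r", "CHH").empty
        enough = _one_window(90, 100, 10, 100, context="CHH", n_sites=16)
        assert len(dmr.test_windows(enough, "f", "r", "CHH")) == 1

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError):
            dmr.call_dmrs(_one_window(1, 2, 1, 2), "f", "r", "CpG")

    def test_estimator_interface(self):
        m = make_matrix(
            [("Chr1", p, "+", "CG") for p in (1, 11, 21, 31)],
            {"f": [(25, 25)] * 4, "r": [(0, 25)] * 4},
        )
        caller = dmr.DMRCaller("f", "r", "CG").fit(m)
        assert caller.get_params()["fdr"] == 0.05
        assert len(caller.dmrs_) == 1
        assert caller.dmrs_.iloc[0]["direction"] == "hyper"
        hypo = set(caller.windows_.loc[caller.windows_["direction"] == "hypo", "start"])
        hyper = set(caller.windows_.loc[caller.windows_["direction"] == "hyper", "start"])
        assert not hypo & hyper
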