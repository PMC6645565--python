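import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from deconcord import DETable, bh_adjust, call_de, screen_candidates

pvec = st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([1.0], [1.0]),
            ([0.01, 0.04, 0.03, 0.02], [0.04, 0.04, 0.04, 0.04]),
            ([0.001, 0.5], [0.002, 0.5]),
        ],
    )
    def test_hand_worked_step_up(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected)

    def test_empty_input_empty_output(self):
        assert bh_adjust([]).size == 0

    @pytest.mark.parametrize("bad", [[-0.1], [1.1], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(pvec)
    def test_monotone_and_dominates_input(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(pvals, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    @settings(deadline=None, derandomize=True)
    @given(pvec, st.randoms(use_true_random=False))
    def test_order_equivariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        direct = bh_adjust(pvals)[perm]
        permuted = bh_adjust([pvals[i] for i in perm])
        np.testing.assert_allclose(direct, permuted, rtol=1e-12)


def table_of(rows, with_padj=True):
    cols = ["gene_id", "log2fc", "pvalue"] + (["padj"] if with_padj else [])
    return DETable("t", pd.DataFrame(rows, columns=cols))


class TestCallDE:
    def test_boundaries_are_inclusive(self):
        # a gene sitting exactly on both thresholds is called
        calls = call_de(table_of([("g", 0.5, 0.001, 0.05)]))
        assert "g" in calls.up

    def test_zero_effect_is_unchanged(self):
        calls = call_de(table_of([("g", 0.0, 1e-6, 1e-6)]))
        assert "g" in calls.unchanged and "g" in calls.universe

    def test_down_call(self):
        calls = call_de(table_of([("g", -0.6, 0.01, 0.01)]))
        assert "g" in calls.down

    def test_padj_computed_when_absent(self):
        # two genes: BH doubles the smaller p, so only the first survives 0.05
        t = table_of([("a", -1.0, 0.01), ("b", -1.0, 0.2)], with_padj=False)
        calls = call_de(t)
        assert calls.down == frozenset({"a"})

    def test_shipped_padj_used_as_is_unless_recomputed(self):
        # padj says significant even though raw p would not survive BH
        t = table_of([("a", -1.0, 0.9, 0.01), ("b", -1.0, 0.8, 0.9)])
        assert call_de(t).down == frozenset({"a"})
        assert call_de(t, recompute_padj=True).down == frozenset()

    def test_nan_padj_is_unchanged_but_tested(self):
        t = table_of([("a", -1.0, 0.001, np.nan), ("b", -1.0, 0.001, 0.01)])
        calls = call_de(t)
        assert "a" in calls.unchanged and "a" in calls.universe

    def test_nonpositive_lfc_min_rejected(self):
        with pytest.raises(ValueError):
            call_de(table_of([("g", 1.0, 0.01, 0.01)]), lfc_min=0.0)

    def test_extreme_thresholds(self, small_table):
        none = call_de(small_table, lfc_min=1e9)
        assert not none.up and not none.down
        everything = call_de(small_table, lfc_min=1e-12, fdr_max=1.0)
        moved = {
            g
            for g, lfc in zip(small_table.gene_ids, small_table.data["log2fc"])
            if lfc != 0.0
        }
        assert everything.up | everything.down == moved


class TestScreenCandidates:
    def make_pair(self, pa=0.9, pb=0.8):
        a = table_of([("g1", -0.5, pa), ("g2", -0.4, 1e-9), ("g3", -2.0, 0.5)],
                     with_padj=False)
        b = table_of([("g1", -0.7, pb), ("g2", -1.0, 1e-9), ("g4", -2.0, 0.5)],
                     with_padj=False)
        return a, b

    def test_fold_only_selection(self):
        a, b = self.make_pair()
        got = screen_candidates(a, b)
        # g1 passes in both despite p ~ 1; g2 fails fold in a; g3/g4 not shared
        assert got.ids == ("g1",)

    def test_invariant_to_p_values(self):
        sel1 = screen_candidates(*self.make_pair(0.9, 0.8)).ids
        sel2 = screen_candidates(*self.make_pair(1e-12, 0.5)).ids
        assert sel1 == sel2

    def test_membership_required_in_both(self):
        a, b = self.make_pair()
        assert "g3" not in screen_candidates(a, b).ids
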