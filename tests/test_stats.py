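"""Contrast engine: t-test, BH adjustment, fold change and exclusion flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import mgfscreen as m
from conftest import make_dataset


def bh_oracle(p):
    """Brute-force step-up adjustment: adj_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


class TestStudentT:
    def test_identical_groups(self):
        assert m.student_t([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_equal_means_different_order(self):
        t, p = m.student_t([2, 4], [4, 2])
        assert (t, p) == (0.0, 1.0)

    def test_matches_scipy_on_fixed_example(self):
        t, p = m.student_t([1, 2, 3, 4], [5, 6, 7, 8])
        ref = sps.ttest_ind([1, 2, 3, 4], [5, 6, 7, 8], equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_unequal_means(self):
        t, p = m.student_t([1, 1], [2, 2])
        assert t == -np.inf and p == 0.0

    def test_groups_of_one_rejected(self):
        with pytest.raises(ValueError, match="two observations"):
            m.student_t([1], [1, 2])

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 3, 9)
        t, p = m.student_t(a, b, equal_var=False)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.01, 0.01, 0.01, 0.01], [0.01, 0.01, 0.01, 0.01]),
        ],
    )
    def test_hand_computed_examples(self, p, expected):
        assert np.allclose(m.benjamini_hochberg(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            m.benjamini_hochberg([0.5, 1.5])

    @settings(max_examples=300, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_bruteforce_oracle(self, p):
        assert np.allclose(m.benjamini_hochberg(p), bh_oracle(p), atol=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=2,
            max_size=8,
        )
    )
    def test_adjusted_order_statistics_monotone(self, p):
        adj = np.asarray(m.benjamini_hochberg(p))
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)


def _two_group_dataset(rng, n_genes=8, n_a=5, n_b=5, shift_gene=None, log2_shift=0.0,
                       sigma=0.25, absent_in_a=()):
    """Log-normal two-population dataset; optionally shift one gene in group A."""
    mu = np.full((n_genes, n_a + n_b), 7.0)
    if shift_gene is not None:
        mu[shift_gene, :n_a] += log2_shift
    signal = 2.0 ** rng.normal(mu, sigma)
    calls = np.full((n_genes, n_a + n_b), "P", dtype=object)
    for g in absent_in_a:
        calls[g, :n_a] = "A"
    return make_dataset(signal, calls, ["MMC"] * n_a + ["BMSC"] * n_b)


def _views(ds):
    return [
        m.GeneExpressionView(f"G{p}", p, ds.signal.loc[p], ds.call.loc[p])
        for p in ds.probe_ids
    ]


class TestCompareGroups:
    def test_identical_groups_not_significant(self, cfg):
        ds = _two_group_dataset(np.random.default_rng(0))
        results = m.compare_groups(
            ds, _views(ds), ds.samples_in("MMC"), ds.samples_in("BMSC"), cfg
        )
        assert not any(r.significant_over_b for r in results)

    def test_planted_eightfold_elevation_detected(self, cfg):
        rng = np.random.default_rng(42)
        ds = _two_group_dataset(rng, shift_gene=0, log2_shift=3.0)
        results = m.compare_groups(
            ds, _views(ds), ds.samples_in("MMC"), ds.samples_in("BMSC"), cfg
        )
        hit = results[0]
        assert hit.significant_over_b
        assert hit.fold_change > 2

        # independent permutation oracle for the same gene
        values = np.log2(ds.signal.loc["p1"].to_numpy())
        observed = abs(values[:5].mean() - values[5:].mean())
        perm_rng = np.random.default_rng(7)
        exceed = 0
        for _ in range(2000):
            perm = perm_rng.permutation(values)
            exceed += abs(perm[:5].mean() - perm[5:].mean()) >= observed
        assert (exceed + 1) / 2001 < 0.05

    def test_absent_call_exclusion(self, cfg):
        rng = np.random.default_rng(1)
        ds = _two_group_dataset(rng, shift_gene=0, log2_shift=2.0, absent_in_a=(0,))
        results = m.compare_groups(
            ds, _views(ds), ds.samples_in("MMC"), ds.samples_in("BMSC"), cfg
        )
        hit = results[0]
        assert hit.fold_change >= 2 and hit.p_adj <= cfg.alpha
        assert hit.all_absent_in_winner
        assert not hit.significant_over_b

    def test_swapping_groups_inverts_fold_and_negates_t(self, cfg):
        ds = _two_group_dataset(np.random.default_rng(2), shift_gene=1, log2_shift=1.5)
        a, b = ds.samples_in("MMC"), ds.samples_in("BMSC")
        fwd = m.compare_groups(ds, _views(ds), a, b, cfg)
        rev = m.compare_groups(ds, _views(ds), b, a, cfg)
        for f, r in zip(fwd, rev):
            assert f.fold_change == pytest.approx(1.0 / r.fold_change, rel=1e-12)
            assert f.t_statistic == pytest.approx(-r.t_statistic, abs=1e-12)
            assert f.p_raw == pytest.approx(r.p_raw, abs=1e-12)
            assert f.p_adj >= f.p_raw

    def test_wbm_samples_rejected(self, cfg):
        ds = _two_group_dataset(np.random.default_rng(3))
        ds.populations.iloc[0] = "WBM"
        with pytest.raises(ValueError, match="bone-marrow"):
            m.compare_groups(
                ds, _views(ds), ds.sample_ids[:5], ds.sample_ids[5:], cfg
            )

    def test_overlapping_groups_rejected(self, cfg):
        ds = _two_group_dataset(np.random.default_rng(4))
        with pytest.raises(ValueError, match="overlap"):
            m.compare_groups(
                ds, _views(ds), ds.sample_ids[:5], ds.sample_ids[4:], cfg
            )

    def test_bh_family_is_the_gene_set_of_the_call(self, cfg):
        ds = _two_group_dataset(np.random.default_rng(8))
        views = _views(ds)
        a, b = ds.samples_in("MMC"), ds.samples_in("BMSC")
        all_genes = m.compare_groups(ds, views, a, b, cfg)
        subset = m.compare_groups(ds, views[:1], a, b, cfg)
        assert subset[0].p_raw == pytest.approx(all_genes[0].p_raw, abs=1e-12)
        assert subset[0].p_adj == pytest.approx(subset[0].p_raw, abs=1e-12)
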