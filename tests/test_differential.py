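"""Paired/unpaired t-tests, fold changes, BH adjustment, DEG selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import icrprofiler as icp
from icrprofiler.differential import DifferentialError


def _expr(values, genes=None, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return icp.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


PAIRS3 = [("s0", "s1"), ("s2", "s3"), ("s4", "s5")]


class TestPairedTtest:
    def test_hand_oracle_differences_1_2_3(self):
        # per-patient post-pre differences {1, 2, 3}: t = 2*sqrt(3), df = 2
        expr = _expr([[0.0, 1.0, 0.0, 2.0, 0.0, 3.0]])
        res = icp.paired_ttest(expr, PAIRS3)
        assert res.loc["g0", "t"] == pytest.approx(2 * np.sqrt(3), abs=1e-4)
        assert res.loc["g0", "df"] == 2
        assert res.loc["g0", "p_value"] == pytest.approx(0.0742, abs=2e-4)

    def test_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(50, 8))
        expr = _expr(values)
        pairs = [(f"s{2 * i}", f"s{2 * i + 1}") for i in range(4)]
        res = icp.paired_ttest(expr, pairs)
        ref = stats.ttest_rel(values[:, 1::2], values[:, ::2], axis=1)
        assert np.allclose(res["t"], ref.statistic)
        assert np.allclose(res["p_value"], ref.pvalue)

    def test_post_equals_pre_flagged_degenerate(self):
        expr = _expr([[1.0, 1.0, 2.0, 2.0, 3.0, 3.0]])
        res = icp.paired_ttest(expr, PAIRS3)
        assert bool(res.loc["g0", "degenerate"])
        assert res.loc["g0", "p_value"] == 1.0

    def test_needs_two_pairs(self):
        expr = _expr([[1.0, 2.0]])
        with pytest.raises(DifferentialError, match="2 complete pairs"):
            icp.paired_ttest(expr, [("s0", "s1")])


class TestUnpairedTtest:
    def test_identical_groups_give_p_one(self):
        expr = _expr([[1.0, 2.0, 1.0, 2.0]])
        res = icp.unpaired_ttest(expr, ["s0", "s1"], ["s2", "s3"])
        assert res.loc["g0", "t"] == pytest.approx(0.0)
        assert res.loc["g0", "p_value"] == pytest.approx(1.0)

    def test_zero_variance_groups_flagged(self):
        expr = _expr([[0.0, 0.0, 1.0, 1.0]])
        res = icp.unpaired_ttest(expr, ["s0", "s1"], ["s2", "s3"])
        assert bool(res.loc["g0", "degenerate"])
        assert res.loc["g0", "p_value"] == 1.0

    def test_pooled_matches_scipy(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(30, 7))
        expr = _expr(values)
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5", "s6"]
        res = icp.unpaired_ttest(expr, a, b, variance_mode="pooled")
        ref = stats.ttest_ind(values[:, :3], values[:, 3:], axis=1, equal_var=True)
        assert np.allclose(res["p_value"], ref.pvalue)

    def test_welch_differs_from_pooled_with_unequal_variances(self):
        rng = np.random.default_rng(2)
        values = np.column_stack(
            [rng.normal(0, 0.1, size=(20, 2)), rng.normal(1, 3.0, size=(20, 5))]
        )
        expr = _expr(values)
        a, b = ["s0", "s1"], [f"s{j}" for j in range(2, 7)]
        pooled = icp.unpaired_ttest(expr, a, b, "pooled")
        welch = icp.unpaired_ttest(expr, a, b, "welch")
        assert not np.allclose(pooled["p_value"], welch["p_value"])

    def test_group_too_small_rejected(self):
        expr = _expr([[1.0, 2.0, 3.0]])
        with pytest.raises(DifferentialError, match="at least 2"):
            icp.unpaired_ttest(expr, ["s0"], ["s1", "s2"])


class TestFoldChange:
    def test_equal_means_give_unity(self):
        expr = _expr([[3.0, 3.0, 3.0, 3.0]])
        fc = icp.fold_change(expr, ["s0", "s1"], ["s2", "s3"])
        assert fc["g0"] == pytest.approx(1.0)

    def test_log2_difference_of_one_doubles(self):
        expr = _expr([[4.0, 4.0, 3.0, 3.0]])
        fc = icp.fold_change(expr, ["s0", "s1"], ["s2", "s3"])
        assert fc["g0"] == pytest.approx(2.0)

    def test_swap_inverts(self):
        rng = np.random.default_rng(3)
        expr = _expr(rng.normal(size=(20, 6)))
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        fwd = icp.fold_change(expr, a, b)
        rev = icp.fold_change(expr, b, a)
        assert np.allclose(fwd * rev, 1.0)

    def test_swap_preserves_p_exactly(self):
        rng = np.random.default_rng(4)
        expr = _expr(rng.normal(size=(15, 6)))
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        fwd = icp.unpaired_ttest(expr, a, b)
        rev = icp.unpaired_ttest(expr, b, a)
        assert np.array_equal(fwd["p_value"], rev["p_value"])


def oracle_bh(p, m):
    """Brute-force step-up oracle: q_(i) = min over tail of p_(j)*m/j."""
    order = np.argsort(p, kind="stable")
    q = np.empty(len(p))
    for pos, idx in enumerate(order):
        tail = [p[order[j]] * m / (j + 1) for j in range(pos, len(p))]
        q[idx] = min(1.0, min(tail))
    return q


class TestBhAdjust:
    def test_single_p_equals_itself(self):
        assert icp.bh_adjust([0.03], m=1)[0] == pytest.approx(0.03)

    def test_hand_example(self):
        q = icp.bh_adjust([0.01, 0.02, 0.03], m=3)
        assert np.allclose(q, [0.03, 0.03, 0.03])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_tail_min_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        p = rng.uniform(size=n)
        m = n + int(rng.integers(0, 20))
        assert np.allclose(icp.bh_adjust(p, m=m), oracle_bh(p, m), atol=1e-12)

    def test_matches_statsmodels_at_full_universe(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=60)
        q = icp.bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, ref)

    def test_never_below_p(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=30)
        assert (icp.bh_adjust(p) >= p - 1e-15).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DifferentialError):
            icp.bh_adjust([1.2])
        with pytest.raises(DifferentialError):
            icp.bh_adjust([0.1, 0.2], m=1)


class TestSelectDegsAndComparisons:
    def test_all_null_empty(self):
        table = pd.DataFrame(
            {"p_value": [0.5, 0.5], "q_value": [0.9, 0.9], "fold_change": [1.0, 2.0]},
            index=["a", "b"],
        )
        assert len(icp.select_degs(table)) == 0

    def test_ordered_by_fold_change_descending(self):
        table = pd.DataFrame(
            {"p_value": [0.01, 0.04], "q_value": [0.1, 0.2], "fold_change": [1.2, 3.0]},
            index=["a", "b"],
        )
        degs = icp.select_degs(table)
        assert list(degs.index) == ["b", "a"]

    def test_fdr_filter(self):
        table = pd.DataFrame(
            {"p_value": [0.01, 0.01], "q_value": [0.1, 0.5], "fold_change": [2.0, 2.0]},
            index=["a", "b"],
        )
        assert list(icp.select_degs(table, fdr_cut=0.25).index) == ["a"]

    def test_study_comparisons_exclude_pr_from_unpaired(self, default_dataset):
        _, samples, _ = default_dataset
        comps = {c.name: c for c in icp.study_comparisons(samples)}
        assert set(comps) == {"post_vs_pre", "CR_vs_NR_pre", "CR_vs_NR_post"}
        pr_samples = set(samples.samples_where(response="PR"))
        for name in ("CR_vs_NR_pre", "CR_vs_NR_post"):
            members = set(comps[name].group_a) | set(comps[name].group_b)
            assert not (members & pr_samples)
        # the paired contrast includes every complete pair, PR too
        paired = set(comps["post_vs_pre"].group_a) | set(comps["post_vs_pre"].group_b)
        assert pr_samples <= paired

    def test_differential_table_annotations_and_q(self, default_dataset):
        counts, samples, _ = default_dataset
        expr, _ = icp.normalize_pipeline(counts)
        comp = icp.study_comparisons(samples)[0]
        table = icp.differential_table(expr, comp, panel=counts.panel)
        assert ((table["q_value"] + 1e-15) >= table["p_value"]).all()
        assert ((table["fold_change"] > 0).all())
        assert table["annotation"].str.len().sum() > 0

    def test_null_deg_fraction_binomially_calibrated(self):
        """Under a no-effect generator, ~5% of genes pass p < 0.05."""
        cfg = icp.SyntheticConfig(
            seed=3,
            icr_post_effect_log2=0.0,
            baseline_responder_effect_log2=0.0,
            tcell_post_effect_log2=0.0,
        )
        counts, samples, _ = icp.generate_dataset(cfg)
        expr, _ = icp.normalize_pipeline(counts)
        res = icp.paired_ttest(expr, samples.pairs())
        frac = float((res["p_value"] < 0.05).mean())
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / len(res))
        assert abs(frac - 0.05) < half_width
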