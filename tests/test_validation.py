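"""Correlations, signed-rank change test, group t-test, cut-off tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sleepfactor.validation import (
    biomarker_null_screen,
    correlate,
    cutoff_confusion,
    group_ttest,
    wilcoxon_signed_rank,
)


def test_perfect_correlation():
    x = np.array([1.0, 2.0, 5.0, 9.0])
    res = correlate(x, x, "pearson")
    assert res.r == pytest.approx(1.0)
    assert res.r_squared == pytest.approx(1.0)


def test_linear_transform_pearson_exact():
    x = np.arange(10.0)
    assert correlate(x, 3 + 2 * x, "pearson").r == pytest.approx(1.0)
    assert correlate(x, 3 - 2 * x, "pearson").r == pytest.approx(-1.0)


def test_independent_samples_near_zero():
    rng = np.random.default_rng(0)
    res = correlate(rng.normal(size=10000), rng.normal(size=10000), "pearson")
    assert abs(res.r) < 0.03


def test_spearman_worked_example():
    """ranks (1,2,3,4) vs (2,1,4,3): 1 - 6*4/(4*15) = 0.6."""
    res = correlate([1, 2, 3, 4], [2, 1, 4, 3], "spearman")
    assert res.r == pytest.approx(0.6)
    assert res.r_squared == pytest.approx(0.36)


def test_correlate_requires_three_pairs():
    with pytest.raises(ValueError):
        correlate([1, 2], [3, 4])


def test_correlate_pairwise_complete():
    x = [1.0, 2.0, np.nan, 4.0, 5.0]
    y = [1.0, np.nan, 3.0, 4.0, 5.0]
    assert correlate(x, y).n == 3


def test_signed_rank_zero_for_identical_pairs():
    res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
    assert res.s == 0.0 and res.p_value == 1.0 and res.n_nonzero == 0


def test_signed_rank_worked_example():
    """d = (+1, +2, +3): positive ranks sum 6, S = 6 - 3*4/4 = 3."""
    res = wilcoxon_signed_rank([0, 0, 0], [1, 2, 3])
    assert res.s == 3.0
    assert res.n_nonzero == 3


def test_signed_rank_symmetry_and_sign_flip():
    pre = np.array([1.0, 4.0, 2.0, 8.0])
    post = np.array([2.0, 3.0, 4.0, 5.0])
    a = wilcoxon_signed_rank(pre, post)
    b = wilcoxon_signed_rank(post, pre)
    assert a.s == -b.s
    assert a.p_value == pytest.approx(b.p_value)
    mirrored = wilcoxon_signed_rank([0, 0, 0, 0], [1, -1, 2, -2])
    assert mirrored.s == 0.0


def test_signed_rank_exact_p_matches_scipy_without_ties():
    rng = np.random.default_rng(4)
    pre = rng.normal(0, 1, 12)
    post = pre + rng.normal(0.4, 1, 12)
    mine = wilcoxon_signed_rank(pre, post)
    ref = stats.wilcoxon(post - pre, mode="exact")
    assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_signed_rank_t_approximation_reasonable():
    rng = np.random.default_rng(5)
    pre = rng.normal(0, 1, 60)
    post = pre + rng.normal(0.3, 1, 60)
    mine = wilcoxon_signed_rank(pre, post)
    ref = stats.wilcoxon(post - pre)
    # different approximations; p-values should be close
    assert mine.p_value == pytest.approx(ref.pvalue, rel=0.25, abs=0.01)


def test_group_ttest_identical_groups():
    vals = np.r_[np.arange(10.0), np.arange(10.0)]
    groups = np.r_[np.zeros(10), np.ones(10)]
    res = group_ttest(vals, groups)
    assert res.t == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    assert res.means[0] == res.means[1]


def test_group_ttest_power_under_unit_shift():
    """N(0,1) vs N(1,1) with n = 200 each rejects essentially always."""
    rejections = 0
    for s in range(25):
        rng = np.random.default_rng(s)
        vals = np.r_[rng.normal(0, 1, 200), rng.normal(1, 1, 200)]
        groups = np.r_[np.zeros(200), np.ones(200)]
        rejections += group_ttest(vals, groups).p_value < 0.05
    assert rejections == 25


def test_group_ttest_single_member_group_rejected():
    with pytest.raises(ValueError):
        group_ttest([1.0, 2.0, 3.0], [0, 0, 1])


def test_group_ttest_matches_scipy_pooled():
    rng = np.random.default_rng(6)
    vals = np.r_[rng.normal(0, 1, 30), rng.normal(0.5, 1.5, 40)]
    groups = np.r_[np.zeros(30), np.ones(40)]
    mine = group_ttest(vals, groups)
    ref = stats.ttest_ind(vals[groups == 0], vals[groups == 1])
    assert mine.t == pytest.approx(ref.statistic)
    assert mine.p_value == pytest.approx(ref.pvalue)
    welch = group_ttest(vals, groups, welch=True)
    refw = stats.ttest_ind(vals[groups == 0], vals[groups == 1], equal_var=False)
    assert welch.p_value == pytest.approx(refw.pvalue)


def test_cutoff_confusion_boundary_semantics():
    tab = cutoff_confusion([13, 14], [0, 1], cutoff=14)
    np.testing.assert_array_equal(tab.counts, [[1, 0], [0, 1]])
    assert tab.sensitivity == 1.0 and tab.specificity == 1.0


def test_cutoff_confusion_all_flagged():
    tab = cutoff_confusion([20, 25, 30], [1, 1, 1], cutoff=14)
    assert tab.counts[1, 1] == 3
    assert tab.sensitivity == 1.0
    assert np.isnan(tab.specificity)


def test_cutoff_confusion_matches_bruteforce_recount(default_cohort):
    from sleepfactor.instruments import score_dataframe

    scored = score_dataframe(default_cohort.records)
    bl = scored[scored["timepoint"] == "baseline"]
    ok = bl["sq"].notna() & bl["anamnesis_sleep"].notna()
    tab = cutoff_confusion(bl["sq"], bl["anamnesis_sleep"], 14)
    counts = np.zeros((2, 2), dtype=int)
    for _, row in bl[ok].iterrows():
        counts[int(row["sq"] >= 14), int(row["anamnesis_sleep"])] += 1
    np.testing.assert_array_equal(tab.counts, counts)
    assert tab.n == int(ok.sum())


def test_biomarker_screen_reports_all_pairs(default_cohort):
    from sleepfactor.instruments import score_dataframe

    scored = score_dataframe(default_cohort.records)
    out = biomarker_null_screen(scored)
    assert set(out["score"]) == {"sq", "dts"}
    assert set(out["timepoint"]) == {"baseline", "followup"}
    assert (out["n"] >= 3).all()
    bh = biomarker_null_screen(scored, benjamini_hochberg=True)
    assert "p_adjusted" in bh.columns
    assert (bh["p_adjusted"] >= bh["p_value"] - 1e-12).all()
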