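"""Statistics pipeline against textbook-formula and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from bstask.analysis import (
    block_metrics,
    cohens_d_paired,
    format_p,
    friedman_kendall,
    gg_epsilon,
    kendalls_w_from_chi2,
    paired_compare,
    percent_decline,
    pvt_metrics,
    rank_biserial_from_diffs,
    rm_anova_gg,
    spearman_matrix,
    tlx_total,
)
from bstask.types import FEEDBACK_CORRECT, PVTTrial

# -- from-scratch oracles -----------------------------------------------------


def friedman_chi2_textbook(data):
    """12/(nk(k+1)) * sum Rj^2 - 3n(k+1), with within-row midranks."""
    n, k = data.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    rank_sums = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * (rank_sums**2).sum() - 3.0 * n * (k + 1)


def kendalls_w_from_ranks(data):
    """W = (12 sum Rj^2 - 3 n^2 k (k+1)^2) / (n^2 k (k^2 - 1)), untied data."""
    n, k = data.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    rank_sums = ranks.sum(axis=0)
    return (12.0 * (rank_sums**2).sum() - 3.0 * n**2 * k * (k + 1) ** 2) / (
        n**2 * k * (k**2 - 1)
    )


def rm_anova_textbook(data):
    """Plain sums-of-squares decomposition; returns (F, partial eta squared)."""
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_err = ((data - grand) ** 2).sum() - ss_cond - ss_subj
    f = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    return f, ss_cond / (ss_cond + ss_err)


# -- scale scoring ------------------------------------------------------------


def test_tlx_total_examples():
    assert tlx_total([11.64, 3.08, 9.11, 6.31, 12.81, 7.72]) == pytest.approx(50.67)
    assert tlx_total([0] * 6) == 0.0
    assert tlx_total([20] * 6) == 120.0
    assert tlx_total(
        {
            "mental_demand": 1,
            "physical_demand": 2,
            "temporal_demand": 3,
            "performance": 4,
            "effort": 5,
            "frustration": 6,
        }
    ) == 21.0


def test_tlx_total_rejects_out_of_range():
    with pytest.raises(ValueError):
        tlx_total([21, 0, 0, 0, 0, 0])
    with pytest.raises(ValueError):
        tlx_total([1, 2, 3])


# -- behavioral metrics -------------------------------------------------------


def test_percent_decline_examples():
    assert percent_decline(150.47, 141.07) == 6.25
    assert percent_decline(94.68, 91.77) == 3.07
    assert percent_decline(5.0, 5.0) == 0.0
    with pytest.raises(ValueError):
        percent_decline(0.0, 1.0)


def test_block_metrics_recount_oracle(one_tot_log):
    """Recounting feedback symbols independently reproduces every metric."""
    for m, block in zip(block_metrics(one_tot_log), one_tot_log.blocks):
        n_correct = sum(r.feedback == FEEDBACK_CORRECT for r in block.records)
        assert m.correct_count == n_correct
        assert m.accuracy == pytest.approx(n_correct / len(block.records))
        assert 0.0 <= m.accuracy <= 1.0
        assert m.correct_count <= m.n_scored


def test_pvt_metrics_hand_arithmetic():
    trials = [
        PVTTrial(3000.0, 250.0, True, False),
        PVTTrial(3000.0, 99.0, False, False),
        PVTTrial(3000.0, 600.0, True, True),
    ]
    m = pvt_metrics(trials)
    assert m.mean_rt_ms == pytest.approx(425.0)  # mean of {250, 600}
    assert m.lapse_count == 1 and m.n_valid == 2


def test_pvt_metrics_all_same_and_empty():
    same = [PVTTrial(2500.0, 300.0, True, False)] * 5
    m = pvt_metrics(same)
    assert (m.mean_rt_ms, m.lapse_count) == (300.0, 0)
    empty = pvt_metrics([PVTTrial(2500.0, 50.0, False, False)])
    assert empty.mean_rt_ms is None and empty.n_valid == 0


# -- paired comparisons -------------------------------------------------------


def test_paired_compare_identical_samples_degenerate():
    x = np.arange(10.0)
    res = paired_compare(x, x)
    assert res.degenerate and res.effect_size == 0.0 and res.p_value == 1.0


def test_paired_compare_recovers_known_cohens_d():
    rng = np.random.default_rng(0)
    y = rng.normal(0.0, 1.0, size=100)
    x = y + rng.normal(1.0, 1.0, size=100)
    res = paired_compare(x, y)
    assert res.method == "paired_t"
    se_d = np.sqrt(1.0 / 100 + 1.0 / 200)  # approximate SE of d
    assert abs(res.effect_size - 1.0) < 3 * se_d
    assert res.effect_size == pytest.approx(cohens_d_paired(x - y))


def test_paired_compare_routes_skewed_to_wilcoxon():
    hits = 0
    for seed in range(40):
        rng = np.random.default_rng(seed)
        y = rng.normal(0.0, 1.0, size=50)
        x = y + rng.exponential(1.0, size=50) ** 3  # heavily skewed differences
        if paired_compare(x, y).method == "wilcoxon":
            hits += 1
    assert hits >= 38  # > 95% of replicate seeds


def test_rank_biserial_bounds_and_sign():
    all_pos = np.ones(10)
    assert rank_biserial_from_diffs(all_pos) == 1.0
    assert rank_biserial_from_diffs(-all_pos) == -1.0
    rng = np.random.default_rng(1)
    r = rank_biserial_from_diffs(rng.normal(size=50))
    assert -1.0 <= r <= 1.0


def test_lilliefors_route_available():
    rng = np.random.default_rng(2)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    res = paired_compare(x, y, normality="lilliefors")
    assert res.normality_route.startswith("lilliefors")


# -- RM-ANOVA with Greenhouse-Geisser -----------------------------------------


def test_rm_anova_matches_manual_ss_on_hand_matrix():
    data = np.array(
        [
            [10.0, 12.0, 15.0],
            [11.0, 14.0, 14.0],
            [9.0, 11.0, 13.0],
            [12.0, 13.0, 16.0],
        ]
    )
    f_ref, np2_ref = rm_anova_textbook(data)
    res = rm_anova_gg(data, correction="never")
    assert res.statistic == pytest.approx(f_ref, abs=1e-12)
    assert res.effect_size == pytest.approx(np2_ref, abs=1e-12)
    assert res.extras["uncorrected_df"] == (2, 6)


def test_rm_anova_two_conditions_epsilon_one():
    rng = np.random.default_rng(3)
    data = rng.normal(size=(10, 2))
    res = rm_anova_gg(data)
    assert res.extras["epsilon_gg"] == 1.0
    assert res.extras["mauchly_p"] == 1.0
    # and it agrees with the paired t-test: F = t^2
    t = stats.ttest_rel(data[:, 0], data[:, 1])
    assert res.statistic == pytest.approx(t.statistic**2)
    assert res.p_value == pytest.approx(t.pvalue)


def test_rm_anova_compound_symmetry_epsilon_near_one():
    rng = np.random.default_rng(4)
    subject = rng.normal(0.0, 2.0, size=(200, 1))
    data = subject + rng.normal(0.0, 1.0, size=(200, 4))
    res = rm_anova_gg(data)
    assert res.extras["epsilon_gg"] > 0.95
    assert res.p_value == pytest.approx(res.extras["uncorrected_p"], rel=0.05)


def test_rm_anova_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    data = rng.normal(size=(12, 4)) + np.array([0.0, 0.3, 0.6, 0.9])
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(12), 4),
            "cond": np.tile(np.arange(4), 12),
            "y": data.ravel(),
        }
    )
    aov = pingouin.rm_anova(data=long, dv="y", within="cond", subject="subject", correction=True)
    res = rm_anova_gg(data, correction="always")
    assert res.statistic == pytest.approx(float(aov["F"].iloc[0]), abs=1e-8)
    assert res.extras["epsilon_gg"] == pytest.approx(float(aov["eps"].iloc[0]), abs=1e-8)
    assert res.p_value == pytest.approx(float(aov["p_GG_corr"].iloc[0]), abs=1e-8)
    spher = pingouin.sphericity(data=long, dv="y", within="cond", subject="subject")
    assert res.extras["mauchly_w"] == pytest.approx(float(spher.W), abs=1e-8)
    assert res.extras["mauchly_p"] == pytest.approx(float(spher.pval), abs=1e-8)


def test_rm_anova_rank_deficient_rejected():
    data = np.tile(np.arange(5.0), (8, 1)) + np.arange(8.0)[:, None]  # zero error variance
    with pytest.raises(ValueError):
        rm_anova_gg(data)


@given(
    arrays(
        float,
        st.tuples(st.integers(8, 15), st.integers(3, 6)),
        elements=st.floats(-100, 100, allow_nan=False, width=32),
    )
)
@settings(max_examples=40, deadline=None)
def test_gg_epsilon_bounds_property(data):
    k = data.shape[1]
    try:
        eps = gg_epsilon(data)
    except Exception:
        return  # degenerate random matrix (zero variance)
    assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12


# -- Friedman / Kendall's W ---------------------------------------------------


def test_friedman_matches_textbook_formula():
    rng = np.random.default_rng(6)
    data = rng.normal(size=(5, 4))
    res = friedman_kendall(data)
    assert res.statistic == pytest.approx(friedman_chi2_textbook(data), abs=1e-10)


def test_kendalls_w_identity_and_printed_value():
    assert kendalls_w_from_chi2(310.89, 72, 7) == pytest.approx(0.720, abs=5e-4)
    rng = np.random.default_rng(7)
    for _ in range(10):
        data = rng.normal(size=(rng.integers(5, 12), rng.integers(3, 7)))
        res = friedman_kendall(data)
        n, k = data.shape
        assert res.effect_size == pytest.approx(res.statistic / (n * (k - 1)), abs=1e-14)
        assert res.effect_size == pytest.approx(kendalls_w_from_ranks(data), abs=1e-10)


def test_kendalls_w_perfect_concordance():
    data = np.tile(np.arange(6.0), (10, 1)) + np.random.default_rng(8).normal(0, 1e-6, (10, 6))
    res = friedman_kendall(np.tile(np.arange(6.0), (10, 1)))
    assert res.effect_size == pytest.approx(1.0)
    assert friedman_kendall(data).effect_size == pytest.approx(1.0)


def test_friedman_degenerate_constant_matrix():
    res = friedman_kendall(np.full((6, 4), 3.0))
    assert res.degenerate and res.effect_size == 0.0


def test_friedman_posthoc_bonferroni():
    rng = np.random.default_rng(9)
    data = rng.normal(size=(20, 3)) + np.array([0.0, 1.0, 2.0])
    res = friedman_kendall(data, posthoc=True)
    ph = res.extras["posthoc"]
    assert len(ph) == 3
    for comp in ph:
        assert comp["p_bonferroni"] == pytest.approx(min(1.0, comp["p_raw"] * 3))
        assert -1.0 <= comp["rank_biserial"] <= 1.0


def test_friedman_agrees_with_rm_anova_on_strong_order():
    """Both tests reject decisively on ordered block-scale drift at n=72."""
    rng = np.random.default_rng(10)
    data = rng.normal(0, 2.0, size=(72, 6)) + np.linspace(0, 3, 6)
    assert friedman_kendall(data).p_value < 0.001
    assert rm_anova_gg(data).p_value < 0.001


# -- Spearman matrix ----------------------------------------------------------


def test_spearman_monotone_pair_and_symmetry():
    rng = np.random.default_rng(11)
    x = rng.normal(size=60)
    table = pd.DataFrame({"a": x, "b": np.exp(x), "c": rng.normal(size=60)})
    rho, p, constant = spearman_matrix(table)
    assert constant == []
    assert rho.loc["a", "b"] == pytest.approx(1.0)
    assert np.allclose(rho.values, rho.values.T, equal_nan=True)
    assert np.allclose(np.diag(rho.values), 1.0)
    # oracle: Spearman = Pearson correlation of the ranks
    ra, rc = stats.rankdata(x), stats.rankdata(table["c"])
    assert rho.loc["a", "c"] == pytest.approx(np.corrcoef(ra, rc)[0, 1], abs=1e-12)


def test_spearman_null_columns_small_rho():
    rng = np.random.default_rng(12)
    table = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
    rho, _, _ = spearman_matrix(table)
    off = rho.values[~np.eye(4, dtype=bool)]
    assert np.all(np.abs(off) < 0.15)


def test_spearman_constant_column_flagged_not_zero():
    table = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0], "b": [2.0] * 5})
    rho, p, constant = spearman_matrix(table)
    assert constant == ["b"]
    assert np.isnan(rho.loc["a", "b"])


def test_format_p_styles():
    assert format_p(0.0004) == "<0.001"
    assert format_p(0.0314) == "0.031"
    assert format_p(float("nan")) == "NA"
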