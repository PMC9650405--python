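"""Cohort statistics: test gates, exact oracles, matching, balance, summaries."""

from __future__ import annotations

from fractions import Fraction
from itertools import product
from math import comb, factorial

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vesselmorph.cohort import default_cohort_params, simulate_cohort
from vesselmorph.stats import (
    balance_smd,
    compare_continuous,
    contingency_test,
    fit_logistic,
    format_percent,
    greedy_match,
    propensity_scores,
    spearman_corr,
    summarize_groups,
)


# ---------------------------------------------------------------------------
# contingency tests

def _chi2_oracle(table):
    table = np.asarray(table, dtype=float)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    return ((table - expected) ** 2 / expected).sum()


def _fisher_2x2_oracle(table):
    """Full hypergeometric enumeration, independent of scipy."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)
        )

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def _fisher_2xk_oracle(table):
    """Brute-force enumeration over all tables with the observed margins."""
    table = np.asarray(table)
    row, col = table.sum(1), table.sum(0)
    n = int(table.sum())

    def prob(top):
        bottom = col - np.asarray(top)
        if np.any(bottom < 0):
            return 0.0
        num = factorial(int(row[0])) * factorial(int(row[1]))
        for c in col:
            num *= factorial(int(c))
        den = factorial(n)
        for t in top:
            den *= factorial(int(t))
        for b in bottom:
            den *= factorial(int(b))
        return float(Fraction(num, den))

    p_obs = prob(table[0])
    total = 0.0
    for top in product(*[range(int(c) + 1) for c in col]):
        if sum(top) != row[0]:
            continue
        p = prob(top)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def test_perfect_independence():
    res = contingency_test([[10, 10], [10, 10]])
    assert res.test_used == "pearson_chi2"
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.pvalue == pytest.approx(1.0)


def test_chi2_matches_closed_form_on_matched_complication_table():
    table = [[20, 9], [46, 59]]
    res = contingency_test(table)
    assert res.test_used == "pearson_chi2"
    assert res.statistic == pytest.approx(_chi2_oracle(table), abs=1e-10)


def test_fisher_selected_and_matches_enumeration():
    table = [[1, 9], [11, 2]]  # min expected count 10*11/23 = 4.78 < 5
    res = contingency_test(table)
    assert res.test_used == "fisher_exact"
    assert (res.expected < 5).any()
    assert res.pvalue == pytest.approx(_fisher_2x2_oracle(table), abs=1e-10)


def test_fisher_2xk_matches_bruteforce():
    table = [[1, 4, 2], [6, 1, 3]]
    res = contingency_test(table)
    assert res.test_used == "fisher_exact"
    assert res.pvalue == pytest.approx(_fisher_2xk_oracle(table), abs=1e-8)


def test_gate_reproduces_expected_count_rule():
    rng = np.random.default_rng(42)
    for _ in range(50):
        table = rng.integers(0, 30, size=(2, rng.integers(2, 4)))
        if (table.sum(1) == 0).any() or (table.sum(0) == 0).any():
            continue
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        res = contingency_test(table)
        should_fisher = bool((expected < 5).any())
        assert (res.test_used == "fisher_exact") == should_fisher


def test_zero_margin_rejected():
    with pytest.raises(ValueError, match="zero margin"):
        contingency_test([[0, 0], [5, 3]])


# ---------------------------------------------------------------------------
# continuous comparisons and correlation

def test_identical_normal_samples_t_branch():
    rng = np.random.default_rng(0)
    x = rng.normal(50, 5, size=100)
    res = compare_continuous(x, x)
    assert res.test_used == "t"
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.pvalue == pytest.approx(1.0)


def test_age_contrast_detected_by_t_test():
    rng = np.random.default_rng(1)
    enlarged_age = rng.normal(54.4, 9.3, size=200)
    other_age = rng.normal(61.0, 9.7, size=200)
    res = compare_continuous(enlarged_age, other_age)
    assert res.test_used == "t"
    assert res.pvalue < 0.001
    assert res.statistic < 0  # enlarged group younger


def test_skewed_samples_fall_back_to_mannwhitney():
    rng = np.random.default_rng(2)
    res = compare_continuous(
        rng.exponential(1.0, size=80), rng.exponential(2.0, size=80)
    )
    assert res.test_used == "mannwhitney"


def test_degenerate_constant_samples_flagged():
    res = compare_continuous([1.0] * 5, [1.0] * 6)
    assert res.test_used == "none"
    assert res.pvalue is None


def test_spearman_monotone_and_reversed():
    x = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
    assert spearman_corr(x, np.exp(x / 10)) == pytest.approx(1.0)
    assert spearman_corr(x, -x) == pytest.approx(-1.0)


def test_spearman_with_tie_matches_midrank_oracle():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 5.0])
    # mid-ranks of y: [2, 1, 3.5, 3.5, 6, 5]; oracle = Pearson(rank(x), rank(y))
    rx = np.array([1, 2, 3, 4, 5, 6], dtype=float)
    ry = np.array([2, 1, 3.5, 3.5, 6, 5])
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert spearman_corr(x, y) == pytest.approx(oracle, abs=1e-12)


def test_spearman_constant_input_rejected():
    with pytest.raises(ValueError, match="constant"):
        spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# logistic regression

def test_null_model_cis_cover_unity():
    rng = np.random.default_rng(3)
    n = 10_000
    design = pd.DataFrame(
        {
            "a": rng.random(n) < 0.3,
            "b": rng.random(n) < 0.5,
            "c": rng.normal(size=n),
        }
    )
    outcome = rng.random(n) < 0.4
    fit = fit_logistic(design, outcome)
    assert fit.converged
    for term in ("a", "b", "c"):
        lo, hi = fit.terms.loc[term, ["ci_low", "ci_high"]]
        assert lo < 1.0 < hi


def test_single_covariate_equals_cross_product_ratio():
    rng = np.random.default_rng(4)
    n = 500
    x = rng.random(n) < 0.4
    y = rng.random(n) < np.where(x, 0.6, 0.3)
    a = int((x & y).sum())
    b = int((x & ~y).sum())
    c = int((~x & y).sum())
    d = int((~x & ~y).sum())
    oracle = (a * d) / (b * c)
    fit = fit_logistic(pd.DataFrame({"x": x}), y)
    assert fit.odds_ratio("x") == pytest.approx(oracle, abs=1e-8)
    lo, hi = fit.terms.loc["x", ["ci_low", "ci_high"]]
    assert lo < fit.odds_ratio("x") < hi


def test_mean_or_recovery_over_seeded_cohorts():
    """The generative odds ratios are recovered on average across cohorts."""
    ors_enl, ors_tum = [], []
    for seed in range(20):
        df = simulate_cohort(default_cohort_params(n=50_000, seed=100 + seed))
        fit = fit_logistic(df[["enlarged", "large_tumor"]], df["complication"])
        ors_enl.append(fit.odds_ratio("enlarged"))
        ors_tum.append(fit.odds_ratio("large_tumor"))
    assert np.mean(ors_enl) == pytest.approx(3.084, rel=0.05)
    assert np.mean(ors_tum) == pytest.approx(3.173, rel=0.05)


# ---------------------------------------------------------------------------
# propensity scores and matching

def test_propensity_scores_null_has_no_discrimination():
    rng = np.random.default_rng(5)
    n = 4_000
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "enlarged": rng.random(n) < 0.1,
            "age": rng.normal(60, 10, size=n),
            "cci": rng.integers(0, 6, size=n),
            "uniportal": rng.random(n) < 0.3,
        }
    )
    scores = propensity_scores(df)
    case_scores = scores[df.enlarged].to_numpy()
    control_scores = scores[~df.enlarged].to_numpy()
    # empirical AUC of the score for group membership
    auc = (case_scores[:, None] > control_scores[None, :]).mean()
    assert auc == pytest.approx(0.5, abs=0.03)


def test_propensity_scores_confounded_cohort(default_cohort):
    scores = propensity_scores(default_cohort)
    assert scores[default_cohort.enlarged].mean() > scores[~default_cohort.enlarged].mean()
    again = propensity_scores(default_cohort)
    np.testing.assert_allclose(scores, again)


def _toy_cohort(case_scores, control_scores):
    n_case, n_ctrl = len(case_scores), len(control_scores)
    df = pd.DataFrame(
        {
            "id": np.arange(n_case + n_ctrl),
            "enlarged": [True] * n_case + [False] * n_ctrl,
        }
    )
    scores = pd.Series(list(case_scores) + list(control_scores))
    return df, scores


def test_greedy_match_hand_enumeration():
    df, scores = _toy_cohort([0.0, 1.0], [0.05, 0.06, 0.9])
    res = greedy_match(df, scores, k=2, caliper=0.2)
    assert res.matches == {1: [4], 0: [2, 3]}
    assert res.distances[1] == [pytest.approx(0.1)]


def test_zero_caliper_with_distinct_scores_matches_nothing():
    df, scores = _toy_cohort([0.0], [0.3, 0.4])
    res = greedy_match(df, scores, caliper=0.0)
    assert res.matches == {}
    assert res.discarded_cases == [0]


def test_tied_scores_take_k_smallest_ids():
    df, scores = _toy_cohort([1.0], [1.0] * 10)
    res = greedy_match(df, scores, k=4)
    assert res.matches == {0: [1, 2, 3, 4]}


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    case_scores=st.lists(
        st.floats(-3, 3, allow_nan=False), min_size=1, max_size=8
    ),
    control_scores=st.lists(
        st.floats(-3, 3, allow_nan=False), min_size=1, max_size=40
    ),
    k=st.integers(1, 5),
)
def test_greedy_match_invariants(case_scores, control_scores, k):
    df, scores = _toy_cohort(case_scores, control_scores)
    res = greedy_match(df, scores, k=k)
    used = [c for ctrls in res.matches.values() for c in ctrls]
    assert len(used) == len(set(used))  # no control reuse
    s = scores.to_numpy()
    for case_id, ctrl_ids in res.matches.items():
        assert 1 <= len(ctrl_ids) <= k
        for cid in ctrl_ids:
            assert abs(s[case_id] - s[cid]) <= res.caliper + 1e-12
    assert set(res.discarded_cases).isdisjoint(res.matches)


# ---------------------------------------------------------------------------
# balance and summaries

def test_smd_zero_for_identical_groups():
    rng = np.random.default_rng(6)
    half = pd.DataFrame(
        {
            "age": rng.normal(60, 9, size=50),
            "cci": rng.integers(0, 6, size=50).astype(float),
            "uniportal": (rng.random(50) < 0.3).astype(float),
        }
    )
    df = pd.concat([half, half], ignore_index=True)
    df["enlarged"] = [True] * 50 + [False] * 50
    df["id"] = np.arange(100)
    smd = balance_smd(df, None)
    assert np.allclose(smd["smd_before"], 0.0, atol=1e-12)


def test_matching_reduces_age_imbalance(default_cohort):
    scores = propensity_scores(default_cohort)
    match = greedy_match(default_cohort, scores)
    smd = balance_smd(default_cohort, match)
    assert smd.loc["age", "smd_before"] < 0  # enlarged generated younger
    assert abs(smd.loc["age", "smd_after"]) < abs(smd.loc["age", "smd_before"])


def test_matching_reduces_all_confounders_across_seeds():
    reduced = 0
    total = 0
    for seed in range(10):
        df = simulate_cohort(default_cohort_params(n=3_000, seed=500 + seed))
        match = greedy_match(df, propensity_scores(df))
        smd = balance_smd(df, match)
        for cov in ("age", "cci"):
            total += 1
            if abs(smd.loc[cov, "smd_after"]) < abs(smd.loc[cov, "smd_before"]):
                reduced += 1
    assert reduced / total >= 0.9


def test_format_percent_half_up():
    assert format_percent(20, 29) == "69.0"
    assert format_percent(46, 105) == "43.8"
    assert format_percent(29, 383, 2) == "7.57"
    assert format_percent(1, 8, 1) == "12.5"
    assert format_percent(1, 800, 1) == "0.1"


def test_summarize_groups_layout(default_cohort):
    scores = propensity_scores(default_cohort)
    match = greedy_match(default_cohort, scores)
    tables = summarize_groups(default_cohort, match)
    assert set(tables) == {"before", "after"}
    before = tables["before"].set_index("variable")
    assert "(" in before.loc["complication", "cases"]
    assert "±" in before.loc["age", "cases"]
    n_matched = len(match.matched_case_ids) + len(match.matched_control_ids)
    after = tables["after"]
    assert len(after) == len(before)


def test_summarize_groups_empty_group_renders_dash():
    df = pd.DataFrame(
        {
            "id": range(6),
            "enlarged": [False] * 6,
            "age": [60.0, 61, 59, 62, 58, 60],
            "cci": [1, 2, 3, 1, 2, 2],
            "uniportal": [True, False] * 3,
            "large_tumor": [False] * 6,
            "complication": [True, False] * 3,
        }
    )
    table = summarize_groups(df)["before"].set_index("variable")
    assert table.loc["complication", "cases"] == "-"
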