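"""Matched-cohort outcome statistics.

Implements the analysis stage applied to the measured cohort: gated
two-group tests (chi-square vs Fisher's exact by the expected-count-< 5
rule; t test vs Mann-Whitney U by Shapiro-Wilk normality), Spearman
correlation between 3D and 2D measurements, multivariable logistic
regression with Wald intervals, and propensity-score matching of the
enlarged (PA/Ao >= 1) group to the non-enlarged group in a 1:4 ratio under
a caliper of 0.1 standard deviations of the logit propensity score.

Matching is greedy nearest-neighbour without replacement, cases processed in
descending score order; cases retaining at least one in-caliper control are
kept (variable 1..k matching), which reproduces the published incomplete
1:4 pattern (29 cases : 105 controls).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

log = logging.getLogger(__name__)

__all__ = [
    "ContingencyResult",
    "ComparisonResult",
    "LogisticFit",
    "MatchResult",
    "contingency_test",
    "compare_continuous",
    "spearman_corr",
    "fit_logistic",
    "propensity_scores",
    "greedy_match",
    "balance_smd",
    "summarize_groups",
    "format_percent",
]

DEFAULT_PS_COVARIATES = ("age", "cci", "uniportal")


# ---------------------------------------------------------------------------
# contingency tables

@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray
    expected: np.ndarray
    test_used: str  # "pearson_chi2" | "fisher_exact"
    statistic: float | None
    pvalue: float


def _fisher_exact_2xk(table: np.ndarray) -> float:
    """Exact conditional p value for a 2xK table by full enumeration.

    Enumerates all tables with the observed margins; the p value is the sum
    of probabilities (under the multivariate hypergeometric null) not
    exceeding the observed table's probability.
    """
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = int(table.sum())
    k = table.shape[1]

    def lcomb(m: int, j: int) -> float:
        return lgamma(m + 1) - lgamma(j + 1) - lgamma(m - j + 1)

    def log_prob(top: tuple[int, ...]) -> float:
        # P = prod_j C(col_j, top_j) / C(n, row_0)
        num = sum(lcomb(int(col[j]), top[j]) for j in range(k))
        return num - lcomb(n, int(row[0]))

    obs = tuple(int(x) for x in table[0])
    p_obs = log_prob(obs)
    total = 0.0

    def recurse(j: int, remaining: int, prefix: list[int]) -> None:
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= col[j]:
                cand = tuple(prefix + [remaining])
                lp = log_prob(cand)
                if lp <= p_obs + 1e-10:
                    total += np.exp(lp)
            return
        lo = max(0, remaining - int(col[j + 1 :].sum()))
        hi = min(int(col[j]), remaining)
        for t in range(lo, hi + 1):
            recurse(j + 1, remaining - t, prefix + [t])

    recurse(0, int(row[0]), [])
    return min(1.0, float(total))


def contingency_test(table) -> ContingencyResult:
    """Pearson chi-square (no continuity correction) or Fisher's exact test.

    Fisher's exact test is selected exactly when any expected cell count is
    below 5 (hypergeometric for 2x2, full enumeration for 2xK).
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2xK table of counts")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise ValueError("table must contain nonnegative integers")
        table = table.astype(int)
    row, col = table.sum(axis=1), table.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero margin in contingency table")
    expected = np.outer(row, col) / table.sum()
    if (expected < 5).any():
        if table.shape[1] == 2:
            _, p = sps.fisher_exact(table)
        else:
            p = _fisher_exact_2xk(table)
        return ContingencyResult(table, expected, "fisher_exact", None, float(p))
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return ContingencyResult(table, expected, "pearson_chi2", float(stat), float(p))


# ---------------------------------------------------------------------------
# continuous two-group comparison

@dataclass(frozen=True)
class ComparisonResult:
    test_used: str  # "t" | "mannwhitney" | "none"
    statistic: float | None
    pvalue: float | None
    note: str = ""


def compare_continuous(x, y, alpha: float = 0.05) -> ComparisonResult:
    """Two-sample location test gated by Shapiro-Wilk normality at ``alpha``.

    Both samples normal -> pooled-variance Student t test; otherwise
    Mann-Whitney U (exact for small tie-free samples, normal approximation
    with tie correction otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return ComparisonResult("none", None, None, "degenerate zero-variance samples")
    normal = True
    for s in (x, y):
        if np.ptp(s) == 0:
            normal = False
            break
        if sps.shapiro(s).pvalue <= alpha:
            normal = False
            break
    if normal:
        res = sps.ttest_ind(x, y, equal_var=True)
        return ComparisonResult("t", float(res.statistic), float(res.pvalue))
    small = max(len(x), len(y)) <= 20
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ComparisonResult("mannwhitney", float(res.statistic), float(res.pvalue))


def spearman_corr(x, y) -> float:
    """Tie-aware Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("samples must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    return float(sps.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# logistic regression

@dataclass(frozen=True)
class LogisticFit:
    """Per-term estimates of a maximum-likelihood logistic fit."""

    terms: pd.DataFrame  # index: term; columns: coef, or, ci_low, ci_high, pvalue
    converged: bool
    n: int

    def odds_ratio(self, term: str) -> float:
        return float(self.terms.loc[term, "or"])


def fit_logistic(design: pd.DataFrame, outcome) -> LogisticFit:
    """Multivariable logistic regression with Wald 95% intervals.

    ``design`` holds named covariates (booleans are cast to 0/1); an
    intercept is added.  Separation or non-convergence is flagged on the
    result and logged, never silently ignored.
    """
    X = design.astype(float)
    y = np.asarray(outcome, dtype=float)
    if len(X) <= X.shape[1]:
        raise ValueError("need more observations than model terms")
    Xc = sm.add_constant(X, has_constant="add")
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception as exc:  # e.g. perfect separation
            log.warning("logistic fit failed (%s); refitting via IRLS GLM", exc)
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit()
            converged = False
        for w in caught:
            if "separation" in str(w.message).lower() or "converge" in str(
                w.message
            ).lower():
                converged = False
    if not converged:
        log.warning("logistic regression did not converge cleanly")
    coefs = res.params
    ses = res.bse
    terms = pd.DataFrame(
        {
            "coef": coefs,
            "or": np.exp(coefs),
            "ci_low": np.exp(coefs - 1.959963984540054 * ses),
            "ci_high": np.exp(coefs + 1.959963984540054 * ses),
            "pvalue": res.pvalues,
        }
    )
    return LogisticFit(terms, converged, int(len(y)))


def propensity_scores(
    cohort: pd.DataFrame,
    covariates=DEFAULT_PS_COVARIATES,
    group_col: str = "enlarged",
) -> pd.Series:
    """Logit of the fitted probability of enlarged-group membership."""
    missing = [c for c in (*covariates, group_col) if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing columns: {missing}")
    fit = fit_logistic(cohort[list(covariates)], cohort[group_col])
    X = sm.add_constant(cohort[list(covariates)].astype(float), has_constant="add")
    logit = X.to_numpy() @ fit.terms["coef"].to_numpy()
    return pd.Series(logit, index=cohort.index, name="logit_ps")


# ---------------------------------------------------------------------------
# greedy caliper matching

@dataclass(frozen=True)
class MatchResult:
    """1:k greedy caliper matching assignment on the logit propensity score."""

    matches: dict[int, list[int]]  # case id -> control ids (1..k each)
    distances: dict[int, list[float]]
    caliper: float
    discarded_cases: list[int]
    k: int

    @property
    def matched_case_ids(self) -> list[int]:
        return sorted(self.matches)

    @property
    def matched_control_ids(self) -> list[int]:
        return sorted(cid for ctrls in self.matches.values() for cid in ctrls)

    @property
    def n_controls(self) -> int:
        return sum(len(v) for v in self.matches.values())


def greedy_match(
    cohort: pd.DataFrame,
    scores: pd.Series,
    k: int = 4,
    caliper: float | None = None,
    caliper_multiplier: float = 0.1,
    group_col: str = "enlarged",
    id_col: str = "id",
) -> MatchResult:
    """Greedy 1:k nearest-neighbour matching within a logit caliper.

    The caliper defaults to ``caliper_multiplier`` x the standard deviation of
    all (pre-match) logit scores.  Cases are processed in descending score
    order; each takes its up-to-``k`` nearest unused controls within the
    caliper, without replacement, ties broken by smallest control id.  Cases
    with no in-caliper control are discarded.
    """
    ids = cohort[id_col].to_numpy()
    is_case = cohort[group_col].to_numpy().astype(bool)
    s = np.asarray(scores, dtype=float)
    if caliper is None:
        caliper = caliper_multiplier * float(np.std(s, ddof=1))
    case_order = sorted(
        np.nonzero(is_case)[0], key=lambda i: (-s[i], ids[i])
    )
    control_idx = np.nonzero(~is_case)[0]
    used: set[int] = set()
    matches: dict[int, list[int]] = {}
    distances: dict[int, list[float]] = {}
    discarded: list[int] = []
    for ci in case_order:
        cands = [
            (abs(s[ci] - s[j]), ids[j], j)
            for j in control_idx
            if j not in used and abs(s[ci] - s[j]) <= caliper
        ]
        cands.sort()
        take = cands[:k]
        if not take:
            discarded.append(int(ids[ci]))
            continue
        matches[int(ids[ci])] = [int(t[1]) for t in take]
        distances[int(ids[ci])] = [float(t[0]) for t in take]
        used.update(t[2] for t in take)
    return MatchResult(matches, distances, float(caliper), discarded, k)


def balance_smd(
    cohort: pd.DataFrame,
    match: MatchResult | None,
    covariates=DEFAULT_PS_COVARIATES,
    group_col: str = "enlarged",
    id_col: str = "id",
) -> pd.DataFrame:
    """Standardized mean differences before and (if matched) after matching.

    SMD = (mean_case - mean_control) / sqrt((var_case + var_control) / 2).
    """
    def smd(df: pd.DataFrame, cov: str) -> float:
        a = df.loc[df[group_col].astype(bool), cov].astype(float)
        b = df.loc[~df[group_col].astype(bool), cov].astype(float)
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        diff = a.mean() - b.mean()
        if pooled == 0:
            if diff == 0:
                return 0.0
            log.warning("zero pooled variance with unequal means for %r", cov)
            return float("nan")
        return float(diff / pooled)

    rows = {}
    for cov in covariates:
        before = smd(cohort, cov)
        after = np.nan
        if match is not None and match.matches:
            keep = set(match.matched_case_ids) | set(match.matched_control_ids)
            after = smd(cohort[cohort[id_col].isin(keep)], cov)
        rows[cov] = {"smd_before": before, "smd_after": after}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# group summaries

def format_percent(numerator: int, denominator: int, decimals: int = 1) -> str:
    """Half-up rounded percentage string, e.g. ``format_percent(20, 29) == '69.0'``."""
    if denominator == 0:
        raise ValueError("zero denominator")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return str(pct.quantize(q, rounding=ROUND_HALF_UP))


def _summary_one(
    df: pd.DataFrame,
    group_col: str,
    categorical: list[str],
    continuous: list[str],
) -> pd.DataFrame:
    groups = {
        "cases": df[df[group_col].astype(bool)],
        "controls": df[~df[group_col].astype(bool)],
    }
    rows = []
    for var in categorical:
        cells = {}
        counts = []
        for gname, gdf in groups.items():
            n = len(gdf)
            if n == 0:
                cells[gname] = "-"
                counts.append([0, 0])
                log.warning("group %s is empty", gname)
                continue
            k = int(gdf[var].astype(bool).sum())
            cells[gname] = f"{k} ({format_percent(k, n)}%)"
            counts.append([k, n - k])
        table = np.asarray(counts).T  # 2 (level) x 2 (group)
        try:
            p = contingency_test(table).pvalue
        except ValueError:
            p = np.nan
        rows.append({"variable": var, **cells, "pvalue": p})
    for var in continuous:
        cells = {}
        samples = []
        for gname, gdf in groups.items():
            if len(gdf) == 0:
                cells[gname] = "-"
                continue
            vals = gdf[var].astype(float)
            cells[gname] = f"{vals.mean():.1f} ± {vals.std(ddof=1):.1f}"
            samples.append(vals.to_numpy())
        p = np.nan
        if len(samples) == 2 and min(map(len, samples)) >= 3:
            res = compare_continuous(*samples)
            p = res.pvalue if res.pvalue is not None else np.nan
        rows.append({"variable": var, **cells, "pvalue": p})
    return pd.DataFrame(rows)


def summarize_groups(
    cohort: pd.DataFrame,
    match: MatchResult | None = None,
    categorical=("uniportal", "large_tumor", "complication"),
    continuous=("age", "cci"),
    group_col: str = "enlarged",
    id_col: str = "id",
) -> dict[str, pd.DataFrame]:
    """Two-group descriptive tables with gated p values.

    Returns ``{"before": table}`` and, when a match is supplied, an ``"after"``
    table restricted to the matched patients.  Counts are rendered as
    ``n (pct%)`` with half-up one-decimal percentages, continuous variables as
    ``mean +/- SD``.
    """
    categorical = [c for c in categorical if c in cohort.columns]
    continuous = [c for c in continuous if c in cohort.columns]
    out = {"before": _summary_one(cohort, group_col, categorical, continuous)}
    if match is not None:
        keep = set(match.matched_case_ids) | set(match.matched_control_ids)
        out["after"] = _summary_one(
            cohort[cohort[id_col].isin(keep)], group_col, categorical, continuous
        )
    return out
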