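"""Measurement and statistics pipeline for BS-task sessions.

Covers NASA-TLX scoring (unweighted sum of six 0-20 dimensions), block-wise
behavioral metrics, PVT metrics (mean valid RT and lapse count),
normality-routed paired comparisons (Shapiro-Wilk on the pairwise
differences, then matched t-test with Cohen's d or Wilcoxon signed-rank with
the matched-pairs rank-biserial correlation), one-way repeated-measures ANOVA
with Mauchly's sphericity test and the Greenhouse-Geisser correction,
Friedman tests with Kendall's W = chi2 / (n (k - 1)), and Spearman
correlation matrices between subjective and behavioral indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .types import FEEDBACK_CORRECT, TLX_DIMENSIONS, PVTTrial, SessionLog


@dataclass
class TestResult:
    """A single inferential test with its effect size and routing metadata."""

    method: str
    statistic: float
    df: Optional[tuple] = None
    p_value: float = float("nan")
    effect_size_name: Optional[str] = None
    effect_size: Optional[float] = None
    normality_route: Optional[str] = None
    degenerate: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def p_formatted(self) -> str:
        return format_p(self.p_value)


def format_p(p: float) -> str:
    """Three-decimal p-value formatting with the usual '<0.001' floor."""
    if np.isnan(p):
        return "NA"
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"


# -- Scale scoring ----------------------------------------------------------

def tlx_total(scores) -> float:
    """Unweighted NASA-TLX total: the arithmetic sum of the six dimensions.

    Accepts a mapping over :data:`~bstask.types.TLX_DIMENSIONS` or a sequence
    of six values; each must lie in [0, 20], so the total lies in [0, 120].
    """
    if hasattr(scores, "keys"):
        missing = set(TLX_DIMENSIONS) - set(scores)
        if missing:
            raise ValueError(f"missing NASA-TLX dimensions: {sorted(missing)}")
        values = [scores[d] for d in TLX_DIMENSIONS]
    else:
        values = list(scores)
        if len(values) != 6:
            raise ValueError(f"expected 6 dimension scores, got {len(values)}")
    for v in values:
        if not (0.0 <= v <= 20.0):
            raise ValueError(f"NASA-TLX dimension score {v} outside [0, 20]")
    return float(sum(values))


# -- Behavioral metrics -----------------------------------------------------

@dataclass(frozen=True)
class BlockMetrics:
    block_index: int
    correct_count: int
    accuracy: float
    mean_rt_ms: Optional[float]
    n_scored: int


def block_metrics(log: SessionLog, task: str = "bs") -> list[BlockMetrics]:
    """Correct counts, accuracy, and mean RT per block of a session.

    Accuracy counts "√" feedback over all scored trials; under the default
    engine switch no-response trials are errors.  Mean RT covers responded
    trials only (None if the block had no response at all).
    """
    blocks = [b for b in log.blocks if b.task == task]
    if not blocks:
        raise ValueError(f"session log has no {task!r} blocks")
    out: list[BlockMetrics] = []
    for i, block in enumerate(blocks, start=1):
        if not block.records:
            raise ValueError(f"block {i} has no scored trials")
        correct = sum(1 for r in block.records if r.feedback == FEEDBACK_CORRECT)
        rts = [r.rt_ms for r in block.records if r.rt_ms is not None]
        out.append(
            BlockMetrics(
                block_index=i,
                correct_count=correct,
                accuracy=correct / len(block.records),
                mean_rt_ms=float(np.mean(rts)) if rts else None,
                n_scored=len(block.records),
            )
        )
    return out


def percent_decline(first: float, last: float) -> float:
    """Percent change from the first to the last block: 100 (first - last) / first.

    Reported to two decimals, matching how block-wise declines are usually
    printed (e.g. correct-trial means 150.47 -> 141.07 give 6.25).
    """
    if first <= 0:
        raise ValueError(f"first must be positive, got {first}")
    return round(100.0 * (first - last) / first, 2)


@dataclass(frozen=True)
class PVTMetrics:
    mean_rt_ms: Optional[float]
    lapse_count: int
    n_valid: int
    n_trials: int


def pvt_metrics(trials: Sequence[PVTTrial]) -> PVTMetrics:
    """Mean RT over valid (>= 100 ms) responses and the attention-lapse count."""
    valid_rts = [t.rt_ms for t in trials if t.valid]
    lapses = sum(1 for t in trials if t.lapse)
    return PVTMetrics(
        mean_rt_ms=float(np.mean(valid_rts)) if valid_rts else None,
        lapse_count=lapses,
        n_valid=len(valid_rts),
        n_trials=len(trials),
    )


# -- Paired comparisons -----------------------------------------------------

def cohens_d_paired(diff: np.ndarray) -> float:
    """Cohen's d for paired data: mean difference / SD of the differences."""
    sd = diff.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(diff.mean() / sd)


def rank_biserial_from_diffs(diff: np.ndarray) -> float:
    """Matched-pairs rank-biserial correlation r = (W+ - W-) / (W+ + W-).

    Zero differences are dropped (the signed-rank convention); ranks of the
    absolute differences use midranks for ties.
    """
    nz = diff[diff != 0]
    if nz.size == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    w_neg = float(ranks[nz < 0].sum())
    return (w_pos - w_neg) / (w_pos + w_neg)


def paired_compare(
    x,
    y,
    alpha_normality: float = 0.05,
    normality: str = "shapiro",
) -> TestResult:
    """Paired comparison routed on a normality test of the differences.

    Normal-looking differences (p >= ``alpha_normality``) get a matched
    t-test with Cohen's d (mean diff / SD of diffs); otherwise a Wilcoxon
    signed-rank test with the matched-pairs rank-biserial correlation.
    ``normality`` selects Shapiro-Wilk or the Lilliefors-corrected
    Kolmogorov-Smirnov test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = x - y
    if np.all(diff == 0):
        return TestResult(
            method="paired_t",
            statistic=0.0,
            df=(x.size - 1,),
            p_value=1.0,
            effect_size_name="cohens_d",
            effect_size=0.0,
            normality_route="degenerate",
            degenerate=True,
        )
    if normality == "shapiro":
        norm_p = float(stats.shapiro(diff).pvalue)
        route = f"shapiro(p={norm_p:.3f})"
    elif normality == "lilliefors":
        _, norm_p = lilliefors(diff, dist="norm")
        route = f"lilliefors(p={float(norm_p):.3f})"
    else:
        raise ValueError("normality must be 'shapiro' or 'lilliefors'")
    if norm_p >= alpha_normality:
        t = stats.ttest_rel(x, y)
        return TestResult(
            method="paired_t",
            statistic=float(t.statistic),
            df=(x.size - 1,),
            p_value=float(t.pvalue),
            effect_size_name="cohens_d",
            effect_size=cohens_d_paired(diff),
            normality_route=route,
            extras={"normality_p": norm_p},
        )
    w = stats.wilcoxon(x, y)
    return TestResult(
        method="wilcoxon",
        statistic=float(w.statistic),
        df=None,
        p_value=float(w.pvalue),
        effect_size_name="rank_biserial",
        effect_size=rank_biserial_from_diffs(diff),
        normality_route=route,
        extras={"normality_p": norm_p},
    )


# -- Repeated-measures ANOVA with Greenhouse-Geisser ------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows sum to zero)."""
    helmert = np.zeros((k - 1, k))
    for i in range(1, k):
        helmert[i - 1, :i] = 1.0 / i
        helmert[i - 1, i] = -1.0
        helmert[i - 1] /= np.linalg.norm(helmert[i - 1])
    return helmert


def mauchly_test(data: np.ndarray) -> tuple[float, float, int, float]:
    """Mauchly's sphericity test on an n x k repeated-measures matrix.

    Returns (W, chi2, df, p).  With k == 2 sphericity holds trivially
    (W = 1, p = 1).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if k == 2:
        return 1.0, 0.0, 0, 1.0
    c = _orthonormal_contrasts(k)
    s = c @ np.cov(data, rowvar=False, ddof=1) @ c.T
    eig = np.linalg.eigvalsh(s)
    if np.any(eig <= 1e-12):
        raise ValueError("rank-deficient covariance: Mauchly's W undefined")
    d = k - 1
    w = float(np.prod(eig) / (eig.mean() ** d))
    df = d * (d + 1) // 2 - 1
    # Box's chi-square approximation with the second-order correction term
    # used by ezANOVA-style implementations.
    f = 1 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(w)
    w2 = (
        (d + 2)
        * (d - 1)
        * (d - 2)
        * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * ((n - 1) * d * f) ** 2)
    )
    p1 = stats.chi2.sf(chi2, df)
    p2 = stats.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return w, float(chi2), df, p


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon estimate, bounded in [1/(k-1), 1]."""
    data = np.asarray(data, dtype=float)
    k = data.shape[1]
    c = _orthonormal_contrasts(k)
    s = c @ np.cov(data, rowvar=False, ddof=1) @ c.T
    eig = np.linalg.eigvalsh(s)
    denom = (k - 1) * (eig**2).sum()
    if denom <= 0:
        raise ValueError("zero between-condition covariance: epsilon undefined")
    eps = float(eig.sum() ** 2 / denom)
    return min(1.0, max(1.0 / (k - 1), eps))


def rm_anova_gg(data, sphericity_alpha: float = 0.05, correction: str = "auto") -> TestResult:
    """One-way repeated-measures ANOVA with sphericity handling.

    ``data`` is an n-participants x k-conditions matrix.  The classical
    within-subject sums-of-squares decomposition gives F on ((k-1),
    (n-1)(k-1)) df and partial eta squared = SS_cond / (SS_cond + SS_err).
    Under ``correction='auto'`` both dfs are multiplied by the
    Greenhouse-Geisser epsilon when Mauchly's test rejects sphericity;
    ``'always'``/``'never'`` force the behavior.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be an n x k matrix")
    n, k = data.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < k + 1:
        raise ValueError("need at least k+1 participants")
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_cond, ms_err = ss_cond / df1, ss_err / df2
    if ms_err <= 0:
        raise ValueError("zero error variance: F undefined")
    f = float(ms_cond / ms_err)
    np2 = float(ss_cond / (ss_cond + ss_err))
    w, chi2, mdf, mp = mauchly_test(data)
    eps = gg_epsilon(data) if k > 2 else 1.0
    apply_gg = {"auto": mp < sphericity_alpha, "always": k > 2, "never": False}[correction]
    if apply_gg:
        cdf1, cdf2 = df1 * eps, df2 * eps
    else:
        cdf1, cdf2 = float(df1), float(df2)
    p = float(stats.f.sf(f, cdf1, cdf2))
    return TestResult(
        method="rm_anova_gg",
        statistic=f,
        df=(cdf1, cdf2),
        p_value=p,
        effect_size_name="partial_eta_sq",
        effect_size=np2,
        extras={
            "epsilon_gg": eps,
            "gg_applied": bool(apply_gg),
            "mauchly_w": w,
            "mauchly_chi2": chi2,
            "mauchly_df": mdf,
            "mauchly_p": mp,
            "uncorrected_df": (df1, df2),
            "uncorrected_p": float(stats.f.sf(f, df1, df2)),
            "ss": {"condition": float(ss_cond), "error": float(ss_err), "subjects": float(ss_subj)},
        },
    )


# -- Friedman test with Kendall's W -----------------------------------------

def kendalls_w_from_chi2(chi2: float, n: int, k: int) -> float:
    """Kendall's W from a Friedman chi-square: W = chi2 / (n (k - 1))."""
    if n < 1 or k < 2:
        raise ValueError("need n >= 1 participants and k >= 2 timepoints")
    return chi2 / (n * (k - 1))


def friedman_kendall(data, posthoc: bool = False, posthoc_alpha: float = 0.05) -> TestResult:
    """Friedman test on an n x k matrix with Kendall's W as the effect size.

    Within-participant ranks use midranks for ties (scipy's tie-corrected
    chi-square).  On request, Bonferroni-corrected pairwise Wilcoxon
    signed-rank post hocs are attached in ``extras['posthoc']``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be an n x k matrix")
    n, k = data.shape
    if n < 2 or k < 3:
        raise ValueError("need n >= 2 participants and k >= 3 timepoints")
    if np.all(data == data[:, :1]):
        return TestResult(
            method="friedman",
            statistic=0.0,
            df=(k - 1,),
            p_value=1.0,
            effect_size_name="kendalls_w",
            effect_size=0.0,
            degenerate=True,
        )
    chi2, p = stats.friedmanchisquare(*(data[:, j] for j in range(k)))
    result = TestResult(
        method="friedman",
        statistic=float(chi2),
        df=(k - 1,),
        p_value=float(p),
        effect_size_name="kendalls_w",
        effect_size=kendalls_w_from_chi2(float(chi2), n, k),
    )
    if posthoc:
        comparisons = []
        m = k * (k - 1) // 2
        for i in range(k):
            for j in range(i + 1, k):
                diff = data[:, i] - data[:, j]
                if np.all(diff == 0):
                    w_stat, raw_p = 0.0, 1.0
                else:
                    res = stats.wilcoxon(data[:, i], data[:, j])
                    w_stat, raw_p = float(res.statistic), float(res.pvalue)
                comparisons.append(
                    {
                        "pair": (i, j),
                        "statistic": w_stat,
                        "p_raw": raw_p,
                        "p_bonferroni": min(1.0, raw_p * m),
                        "rank_biserial": rank_biserial_from_diffs(diff),
                    }
                )
        result.extras["posthoc"] = comparisons
    return result


# -- Spearman correlation matrix --------------------------------------------

def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pairwise Spearman correlations over the columns of a per-participant table.

    Returns (rho, p, constant_columns).  Constant columns have undefined
    rank correlations; they are reported by name and their entries are NaN
    rather than silently zero.  The rho matrix is symmetric with unit
    diagonal.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    if len(table) < 4:
        raise ValueError("need at least 4 rows")
    cols = list(table.columns)
    constant = [c for c in cols if table[c].nunique() <= 1]
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pvals = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    np.fill_diagonal(pvals.values, np.nan)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            if a in constant or b in constant:
                r, p = np.nan, np.nan
            else:
                res = stats.spearmanr(table[a], table[b])
                r, p = float(res.statistic), float(res.pvalue)
            rho.loc[a, b] = rho.loc[b, a] = r
            pvals.loc[a, b] = pvals.loc[b, a] = p
    for c in constant:
        rho.loc[c, c] = np.nan
    return rho, pvals, constant


# -- Cohort-level convenience -----------------------------------------------

def cohort_block_table(logs: Sequence[SessionLog], metric: str = "accuracy") -> np.ndarray:
    """Stack one block-wise metric across a cohort into an n x k matrix.

    ``metric`` is one of 'accuracy', 'correct_count', 'mean_rt_ms'.
    """
    rows = []
    for log in logs:
        ms = block_metrics(log)
        rows.append([getattr(m, metric) for m in ms])
    return np.asarray(rows, dtype=float)


def cohort_vas_table(logs: Sequence[SessionLog], item: str, include_baseline: bool = True) -> np.ndarray:
    """Stack one VAS item across a cohort into an n x (timepoints) matrix."""
    rows = []
    for log in logs:
        recs = log.vas_records
        if not include_baseline:
            recs = [r for r in recs if r.anchor != "baseline"]
        rows.append([r.items[item] for r in recs])
    return np.asarray(rows, dtype=float)


def cohort_spearman_block(logs: Sequence[SessionLog], block: int) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Spearman matrix of {VAS items, correct count, accuracy} within one block."""
    rows = []
    for log in logs:
        m = block_metrics(log)[block - 1]
        vas = next(r for r in log.vas_records if r.anchor == f"block_{block}")
        row = dict(vas.items)
        row["correct_count"] = m.correct_count
        row["accuracy"] = m.accuracy
        rows.append(row)
    return spearman_matrix(pd.DataFrame(rows))
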