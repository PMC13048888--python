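"""Shared inferential primitives: Fisher odds-ratio inference and rank-sum tests.

Both the spatial colocalization analysis and the multiplex-IF ROI
quantification compare pooled 2x2 count tables with one-sided Fisher's exact
tests and compare continuous per-unit quantities with Wilcoxon rank-sum /
Mann-Whitney U tests.  A single implementation lives here so that every
consumer shares the same exactness guarantees and zero-cell conventions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["FisherResult", "RankTestResult", "fisher_or", "rank_sum_test", "bh_adjust"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class FisherResult:
    """Odds-ratio inference on a 2x2 table.

    ``odds_ratio``/``ci_low``/``ci_high`` use the sample (Woolf) odds ratio
    with a Haldane-Anscombe 0.5 correction applied to *all* cells iff any
    cell is zero; the exact p-value is always computed on the uncorrected
    table.  ``odds_ratio_cmle`` and its CI are the conditional
    maximum-likelihood alternative.
    """

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    alternative: str
    corrected: bool
    odds_ratio_cmle: float
    ci_low_cmle: float
    ci_high_cmle: float
    table: tuple[tuple[int, int], tuple[int, int]]


def fisher_or(
    table,
    alternative: str = "greater",
    zero_cell_correction: float = 0.5,
    ci_level: float = 0.95,
    cmle: bool = True,
) -> FisherResult:
    """Fisher's exact test and odds-ratio confidence interval for a 2x2 table.

    Parameters
    ----------
    table
        ``[[a, b], [c, d]]`` with rows = groups (e.g. disease, control) and
        columns = outcome (e.g. positive, negative).  Cells must be
        nonnegative integers and both group (row) margins positive; an empty
        outcome column is allowed (e.g. no positive cell anywhere gives
        p = 1 under ``"greater"`` and a finite corrected odds ratio).
    alternative
        ``"greater"`` (default) tests enrichment of the outcome in the first
        row: p = P[X >= a] under the central hypergeometric null with all
        margins fixed.  ``"less"`` and ``"two_sided"`` are also supported.
    zero_cell_correction
        Added to every cell before computing OR and Woolf CI when any cell is
        zero (Haldane-Anscombe).  The p-value is unaffected.
    cmle
        Also compute the conditional-MLE odds ratio and CI (noncentral
        hypergeometric inversion; markedly slower for large counts).  When
        False those fields are NaN.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table cells must be nonnegative integers")
    t = np.round(t).astype(np.int64)
    if np.any(t.sum(axis=1) == 0):
        raise ValueError("both group (row) margins must be positive")

    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    total = a + b + c + d
    row1 = a + b  # first-group margin
    col1 = a + c  # outcome margin

    # exact p on the uncorrected table: hypergeometric tail sum
    if alternative == "greater":
        p = float(sps.hypergeom.sf(a - 1, total, row1, col1))
    elif alternative == "less":
        p = float(sps.hypergeom.cdf(a, total, row1, col1))
    elif alternative == "two_sided":
        p = float(sps.fisher_exact(t, alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = min(p, 1.0)

    corrected = bool((t == 0).any() and zero_cell_correction > 0)
    tc = t.astype(float) + (zero_cell_correction if corrected else 0.0)
    odds = (tc[0, 0] * tc[1, 1]) / (tc[0, 1] * tc[1, 0])
    se = math.sqrt(float((1.0 / tc).sum()))
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    ci_low = math.exp(math.log(odds) - z * se)
    ci_high = math.exp(math.log(odds) + z * se)

    if cmle:
        res = sps.contingency.odds_ratio(t, kind="conditional")
        ci_c = res.confidence_interval(confidence_level=ci_level)
        or_cmle, lo_cmle, hi_cmle = float(res.statistic), float(ci_c.low), float(ci_c.high)
    else:
        or_cmle = lo_cmle = hi_cmle = float("nan")

    return FisherResult(
        odds_ratio=float(odds),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p,
        alternative=alternative,
        corrected=corrected,
        odds_ratio_cmle=or_cmle,
        ci_low_cmle=lo_cmle,
        ci_high_cmle=hi_cmle,
        table=((a, b), (c, d)),
    )


@dataclass(frozen=True)
class RankTestResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    method: str  # "exact" | "enumeration" | "asymptotic"
    n1: int
    n2: int


_ENUM_LIMIT = 200_000  # max number of subsets to enumerate exactly


def rank_sum_test(
    x,
    y,
    alternative: str = "two-sided",
    method: str = "auto",
) -> RankTestResult:
    """Wilcoxon rank-sum / Mann-Whitney U test of two independent samples.

    The statistic is the Mann-Whitney U of ``x`` computed from mid-ranks.
    Method resolution under ``"auto"``:

    * no ties and both samples <= 25 cells: exact null distribution
      (delegated to :func:`scipy.stats.mannwhitneyu`);
    * ties present and C(n1+n2, n1) small enough to enumerate: full
      enumeration of all group assignments with mid-rank tie handling;
    * otherwise: normal approximation with tie correction and continuity
      correction.

    ``alternative`` is ``"two-sided"``, ``"greater"`` (x tends larger) or
    ``"less"``.  All values tied across both samples gives p = 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # mid-ranks
    u_stat = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if np.all(pooled == pooled[0]):
        return RankTestResult(u_stat, 1.0, "degenerate", n1, n2)

    has_ties = len(np.unique(pooled)) < n1 + n2
    if method == "auto":
        if not has_ties and n1 <= 25 and n2 <= 25:
            method = "exact"
        elif math.comb(n1 + n2, n1) <= _ENUM_LIMIT:
            method = "enumeration"
        else:
            method = "asymptotic"

    if method == "exact":
        alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
        res = sps.mannwhitneyu(x, y, alternative=alt, method="exact")
        return RankTestResult(u_stat, float(res.pvalue), "exact", n1, n2)

    if method == "enumeration":
        return _rank_test_enumeration(ranks, n1, n2, u_stat, alternative)

    return _rank_test_asymptotic(ranks, n1, n2, u_stat, alternative)


def _rank_test_enumeration(ranks, n1, n2, u_obs, alternative) -> RankTestResult:
    """Exact permutation p-value by enumerating all C(n1+n2, n1) assignments."""
    n = n1 + n2
    offset = n1 * (n1 + 1) / 2.0
    u_all = np.fromiter(
        (sum(ranks[i] for i in idx) - offset for idx in combinations(range(n), n1)),
        dtype=float,
        count=math.comb(n, n1),
    )
    total = len(u_all)
    tol = 1e-9
    if alternative == "greater":
        p = np.count_nonzero(u_all >= u_obs - tol) / total
    elif alternative == "less":
        p = np.count_nonzero(u_all <= u_obs + tol) / total
    else:
        prod = n1 * n2
        lo = min(u_obs, prod - u_obs)
        p = (
            np.count_nonzero(u_all <= lo + tol)
            + np.count_nonzero(u_all >= prod - lo - tol)
        ) / total
    return RankTestResult(u_obs, float(min(p, 1.0)), "enumeration", n1, n2)


def _rank_test_asymptotic(ranks, n1, n2, u_obs, alternative) -> RankTestResult:
    """Normal approximation with tie correction and continuity correction."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return RankTestResult(u_obs, 1.0, "asymptotic", n1, n2)
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (u_obs - mu - 0.5) / sd
        p = float(sps.norm.sf(z))
    elif alternative == "less":
        z = (u_obs - mu + 0.5) / sd
        p = float(sps.norm.cdf(z))
    else:
        z = max(abs(u_obs - mu) - 0.5, 0.0) / sd
        p = float(2.0 * sps.norm.sf(z))
    return RankTestResult(u_obs, min(p, 1.0), "asymptotic", n1, n2)
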