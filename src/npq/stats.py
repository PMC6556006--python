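"""Exact matched-pair statistics.

Matched index/dementia pairs are compared with the Wilcoxon matched-pairs
signed-ranks test for continuous and ordinal variables, McNemar's test with
exact binomial p-values for binary variables, and a chi-square
goodness-of-fit test against expected Mendelian ratios for segregation
counts.

The Wilcoxon null distribution is computed exactly by dynamic programming
over the 2ⁿ sign assignments of the (mid-)ranks, so tied |differences| are
handled exactly; zero differences are dropped (the classical treatment).
Two-sided exact p-values double the smaller tail and cap at 1. No
multiple-testing correction is applied; per-variable p-values are reported
raw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float       # W+ = sum of ranks of positive differences
    pvalue: float
    n_effective: int       # pairs remaining after zero differences dropped
    method: str            # "exact" or "normal"
    degenerate: bool = False


@dataclass(frozen=True)
class McNemarResult:
    pvalue: float
    b: int
    c: int
    degenerate: bool = False


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    pvalue: float


def _signed_rank_null_pmf(double_ranks: np.ndarray) -> np.ndarray:
    """Exact pmf of Σ ranks over the positive set, on the doubled-rank grid.

    Mid-ranks are multiples of ½, so doubling makes them integers; the pmf
    of the null statistic 2·W+ is built by convolving (½, ½·x^r) factors.
    """
    total = int(double_ranks.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in double_ranks:
        r = int(r)
        nxt = 0.5 * pmf
        nxt[r:] += 0.5 * pmf[: total + 1 - r]
        pmf = nxt
    return pmf


def wilcoxon_signed_rank(
    index_values, match_values=None, exact_max_n: int = 25
) -> WilcoxonResult:
    """Wilcoxon matched-pairs signed-ranks test, exact for small n.

    Pass paired (index, match) vectors, or a single vector of differences.
    Zero differences are dropped; tied |differences| receive mid-ranks.
    The null distribution is enumerated exactly (sign-flip DP) when the
    effective n is at most ``exact_max_n``; larger samples use the normal
    approximation with tie correction.
    """
    x = np.asarray(index_values, dtype=float)
    d = x - np.asarray(match_values, dtype=float) if match_values is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "exact", degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        dr = np.rint(2 * ranks).astype(int)
        pmf = _signed_rank_null_pmf(dr)
        w2 = int(round(2 * w_pos))
        lower = pmf[: w2 + 1].sum()
        upper = pmf[w2:].sum()
        p = min(1.0, 2.0 * min(lower, upper))
        return WilcoxonResult(w_pos, float(p), n, "exact")
    mean = n * (n + 1) / 4
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - np.sum(tie_counts**3 - tie_counts) / 48
    z = (w_pos - mean) / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return WilcoxonResult(w_pos, float(min(1.0, p)), n, "normal")


def mcnemar_exact(b: int, c: int) -> McNemarResult:
    """McNemar's test with exact binomial p-value.

    ``b`` and ``c`` are the discordant-pair counts (index-only positives
    and match-only positives). Under the null the smaller count is
    Binomial(b+c, ½); the two-sided p doubles the lower tail and caps at 1.
    Concordant pairs carry no information and are not needed.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return McNemarResult(1.0, b, c, degenerate=True)
    p = min(1.0, 2.0 * float(sps.binom.cdf(min(b, c), n, 0.5)))
    return McNemarResult(p, b, c)


def chi_square_goodness_of_fit(observed_counts, expected_ratios) -> ChiSquareResult:
    """χ² goodness of fit of observed counts to expected ratios.

    Expected counts are N·ratio; df = k − 1. Ratios must sum to 1 and every
    expected count must be positive.
    """
    obs = np.asarray(observed_counts, dtype=float)
    ratios = np.asarray(expected_ratios, dtype=float)
    if obs.shape != ratios.shape:
        raise ValueError("observed and expected shapes differ")
    if (obs < 0).any() or obs.sum() <= 0:
        raise ValueError("observed counts must be non-negative with positive total")
    if not np.isclose(ratios.sum(), 1.0):
        raise ValueError("expected ratios must sum to 1")
    expected = obs.sum() * ratios
    if (expected <= 0).any():
        raise ValueError("every expected count must be positive")
    chi2, p = sps.chisquare(obs, expected)
    return ChiSquareResult(float(chi2), obs.size - 1, float(p))
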