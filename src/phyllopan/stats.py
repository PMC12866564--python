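"""Statistical kernels used throughout the pipeline.

From-scratch implementations of the tests every downstream stage relies
on: Fisher's exact test on 2x2 tables, Benjamini–Hochberg and Bonferroni
multiplicity corrections, the Mann–Whitney U rank-sum test (exact
permutation distribution for small samples, tie-corrected normal
approximation otherwise), and the rank-based ROC/AUC. Keeping these in
one module means a single convention for two-sided p-values and odds
ratios across the enrichment, differential and classification stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, ndtr

# Tolerance for "probability at most that of the observed table" when
# summing the hypergeometric tail: float arithmetic can split exact ties.
_REL_TIE_TOL = 1e-7

# Exact Mann-Whitney permutation distribution is used when n1+n2 is at
# most this; the rank-sum dynamic program keeps it cheap well past the
# point where naive enumeration stops being feasible.
EXACT_MWU_MAX_N = 20


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts a, b, c, d with rows (target, reference).

    a = target genes in the category, b = target genes outside it,
    c = reference (core) genes in the category, d = outside it.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError(f"negative cell count in {self}")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("each row of a 2x2 table needs a positive total")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)


def _log_hypergeom_pmf(k: np.ndarray, n_total: int, n_success: int, n_draw: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(n_total, n_success, n_draw)."""
    k = np.asarray(k, dtype=float)
    return (
        gammaln(n_success + 1)
        - gammaln(k + 1)
        - gammaln(n_success - k + 1)
        + gammaln(n_total - n_success + 1)
        - gammaln(n_draw - k + 1)
        - gammaln(n_total - n_success - n_draw + k + 1)
        - (gammaln(n_total + 1) - gammaln(n_draw + 1) - gammaln(n_total - n_draw + 1))
    )


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test.

    Returns the unconditional sample odds ratio (a*d)/(b*c) — +inf when
    b*c == 0 and a*d > 0, NaN when both products vanish — and the
    two-sided p-value by the method of small p-values: the sum of the
    probabilities of all tables with the observed margins whose
    hypergeometric probability does not exceed the observed one.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    ad, bc = a * d, b * c
    if bc == 0:
        odds_ratio = math.inf if ad > 0 else math.nan
    else:
        odds_ratio = ad / bc

    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    logpmf = _log_hypergeom_pmf(support, n, col1, row1)
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + _REL_TIE_TOL)].sum())
    return odds_ratio, min(p, 1.0)


def log_odds_ratio(table: ContingencyTable2x2) -> tuple[float, bool]:
    """Natural-log odds ratio, with a Haldane–Anscombe 0.5 continuity
    correction applied only when a zero cell makes the plain estimator
    degenerate. Returns (LOR, corrected?)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return math.log((a * d) / (b * c)), True
    return math.log((a * d) / (b * c)), False


def bh_adjust(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i}(p_(j) * m / j), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def bonferroni_adjust(pvals: list[float] | np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(xi, yj): xi > yj} + 0.5 * #ties, via pairwise comparison."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def _rankdata(values: np.ndarray) -> np.ndarray:
    """Midranks of a 1-d array (average rank for ties), 1-based."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _exact_mwu_pvalue(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p over the permutation distribution of U.

    All C(n1+n2, n1) relabelings of the pooled (possibly tied) values
    are weighted equally; the distribution of the rank sum — hence of U,
    via U = R1 - n1(n1+1)/2 with midranks — is tabulated by a dynamic
    program over doubled midranks (integers even with ties), which is
    exactly equivalent to full enumeration. p = P(|U - mu| >= |U_obs - mu|);
    the distribution is symmetric about mu under exchangeability.
    """
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * _rankdata(pooled)).astype(int)  # doubled midranks
    max_sum = int(ranks2.sum())
    # table[k, s] = number of k-subsets with doubled-rank sum s
    table = np.zeros((n1 + 1, max_sum + 1))
    table[0, 0] = 1.0
    for r in ranks2:
        table[1:, r:] += table[:-1, : max_sum + 1 - r]
    counts = table[n1]
    total = counts.sum()
    # doubled U for each doubled rank sum s: 2U = s - n1(n1+1)
    support_2u = np.arange(max_sum + 1) - n1 * (n1 + 1)
    mu2 = n1 * n2  # doubled mean of U
    dev = np.abs(support_2u - mu2)
    dev_obs = abs(2 * u_obs - mu2)
    return float(counts[dev >= dev_obs - 1e-9].sum() / total)


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U (Wilcoxon rank-sum) test.

    mode 'exact' enumerates the permutation distribution of U over all
    C(n1+n2, n1) group labelings of the observed (possibly tied) pooled
    values; 'normal' uses the tie-corrected normal approximation with
    continuity correction; 'auto' picks exact when n1+n2 <= 20 (the
    rank-sum dynamic program keeps exact mode cheap at these sizes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("exact", "normal", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = x.size, y.size
    if mode == "auto":
        mode = "exact" if n1 + n2 <= EXACT_MWU_MAX_N else "normal"

    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if mode == "exact":
        p = _exact_mwu_pvalue(x, y, u_obs)
        return TestResult(u_obs, p, "mann-whitney-exact")

    # Tie-corrected variance; ties counted over the pooled sample.
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return TestResult(u_obs, 1.0, "mann-whitney-normal")
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(ndtr(-z)))
    return TestResult(u_obs, p, "mann-whitney-normal")


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """AUC and ROC points from real-valued scores and binary labels.

    AUC is the fraction of (positive, negative) pairs ranked correctly,
    ties counting one half — the normalized Mann–Whitney U. ROC points
    are (FPR, TPR) at every distinct score threshold, tie groups moved
    together, from (0,0) to (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute ROC/AUC")

    auc = _u_statistic(scores[labels == 1], scores[labels == 0]) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(1 - sorted_labels)
    # keep only the last index within each tie group
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    points = np.column_stack([fps[distinct] / n_neg, tps[distinct] / n_pos])
    points = np.vstack([[0.0, 0.0], points])
    return float(auc), points
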