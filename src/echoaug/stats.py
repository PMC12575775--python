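"""Agreement and hypothesis-testing statistics.

Conventions: Bland-Altman uses 1.96 and the sample (n-1) standard deviation;
the signed-rank test is two-sided with zero differences dropped, exact (full
sign enumeration with midranks) for small n and a tie-corrected normal
approximation otherwise; the binomial test defaults to the one-sided
(greater) exact tail.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sstats

from .errors import InvalidArgumentError, UndefinedTestError

__all__ = [
    "AgreementResult",
    "bland_altman",
    "wilcoxon_bonferroni",
    "cohens_kappa",
    "average_pairwise_kappa",
    "binomial_test",
]


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self):
        if not self.loa_low <= self.bias <= self.loa_high:
            raise InvalidArgumentError("limits of agreement must bracket the bias")


def bland_altman(reference, estimates) -> AgreementResult:
    """Bias and 1.96-sd limits of agreement of ``estimates - reference``."""
    ref = np.asarray(reference, dtype=np.float64)
    est = np.asarray(estimates, dtype=np.float64)
    if ref.shape != est.shape or ref.ndim != 1:
        raise InvalidArgumentError("inputs must be equal-length 1-D sequences")
    n = ref.size
    if n < 2:
        raise InvalidArgumentError("at least two paired values are required")
    d = est - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=n)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with Bonferroni correction
# ---------------------------------------------------------------------------

_EXACT_ENUM_N = 15


def _signed_rank_exact_p(ranks, w_plus):
    """Two-sided p by exhaustive enumeration of all sign assignments
    (handles tied |differences| through midranks)."""
    n = len(ranks)
    mu = ranks.sum() / 2.0
    obs = abs(w_plus - mu)
    count = 0
    total = 2**n
    # vectorized enumeration: bit masks x ranks
    signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
    w = signs @ ranks
    count = int(np.sum(np.abs(w - mu) >= obs - 1e-12))
    return count / total


def wilcoxon_bonferroni(scores_a, scores_b, m: int = 6, alpha: float = 0.05):
    """Two-sided Wilcoxon signed-rank test on paired scores with Bonferroni
    correction for ``m`` comparisons.

    Returns ``(statistic W+, raw p, adjusted p, significant)``.  Zero
    differences are dropped; the exact distribution is enumerated for
    n <= 15 (midranks allowed), scipy's exact method is used for tie-free
    n <= 25, else the tie-corrected normal approximation.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidArgumentError("paired scores must be equal-length 1-D sequences")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    ranks = _sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    if n <= _EXACT_ENUM_N:
        p = _signed_rank_exact_p(ranks, w_plus)
    elif not has_ties and n <= 25:
        p = float(_sstats.wilcoxon(d, alternative="two-sided", method="exact").pvalue)
    else:
        p = float(
            _sstats.wilcoxon(
                d, alternative="two-sided", method="approx", correction=False
            ).pvalue
        )
    p = min(1.0, p)
    p_adj = min(1.0, m * p)
    return w_plus, p, p_adj, bool(p_adj < alpha)


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

def cohens_kappa(ratings_1, ratings_2) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    Degenerate contract: when both raters are constant, kappa is 1 if they
    agree and 0 if they differ.
    """
    r1 = np.asarray(ratings_1)
    r2 = np.asarray(ratings_2)
    if r1.shape != r2.shape or r1.ndim != 1 or r1.size == 0:
        raise InvalidArgumentError("ratings must be equal-length non-empty sequences")
    cats = np.unique(np.concatenate([r1, r2]))
    n = r1.size
    p_o = float(np.mean(r1 == r2))
    p1 = np.array([np.mean(r1 == c) for c in cats])
    p2 = np.array([np.mean(r2 == c) for c in cats])
    p_e = float(p1 @ p2)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def average_pairwise_kappa(group_a, group_b=None) -> float:
    """Mean kappa over rater pairs.

    With one group: all distinct within-group pairs.  With two groups: all
    cross pairs (every rater of group_a against every rater of group_b).
    """
    group_a = [np.asarray(r) for r in group_a]
    if group_b is None:
        if len(group_a) < 2:
            raise InvalidArgumentError("need at least two raters for within-group kappa")
        pairs = list(itertools.combinations(group_a, 2))
    else:
        group_b = [np.asarray(r) for r in group_b]
        if not group_a or not group_b:
            raise InvalidArgumentError("both groups must be non-empty")
        pairs = list(itertools.product(group_a, group_b))
    return float(np.mean([cohens_kappa(x, y) for x, y in pairs]))


def binomial_test(k: int, n: int, p0: float = 0.5, alternative: str = "greater") -> float:
    """Exact binomial tail probability.

    ``alternative='greater'`` (default) is the one-sided upper tail;
    ``'two-sided'`` sums all outcome probabilities no larger than the
    observed one.
    """
    k, n = int(k), int(n)
    if not 0 <= k <= n:
        raise InvalidArgumentError(f"k must be in [0, n], got k={k}, n={n}")
    if alternative not in ("greater", "less", "two-sided"):
        raise InvalidArgumentError(f"unknown alternative {alternative!r}")
    return float(_sstats.binomtest(k, n, p0, alternative=alternative).pvalue)
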