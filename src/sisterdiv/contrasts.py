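"""Matched-pair contrast metrics and significance tests for sister clades.

Species richness (or host-MRCA age) of each sister pair is reduced to a
single contrast — raw difference ``a - b``, proportional difference
``(a - b)/(a + b)``, or log ratio ``ln(a/b)`` — and the set of contrasts is
tested against the null that each sister is equally likely to be the larger.

The significance test is dispatched on the number of nonzero contrasts m:

* m <= 10 — exact randomization (sign-permutation) test for matched pairs:
  all 2^m sign assignments of the contrasts are enumerated and the fraction
  of |sum|s at least as extreme as observed is the two-tailed p.
* 11 <= m <= 19 — Wilcoxon signed-rank test with the null distribution of W+
  enumerated exactly over all 2^m sign patterns on the realized
  (tie-averaged) ranks.
* m >= 20 — normal approximation to the signed-rank test with tie correction
  and a 0.5 continuity correction.

Zero contrasts are dropped before ranking and dispatch (standard Wilcoxon
practice); Pratt's zero-inclusion variant is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from sisterdiv.core_io import SisterPairTable

__all__ = [
    "ContrastResult", "contrast", "sign_permutation_test",
    "wilcoxon_signed_rank_exact", "wilcoxon_normal_approx",
    "binomial_sign_test", "diversity_contrast_analysis",
    "host_specificity_test",
]

Metric = Literal["raw", "proportional", "logratio"]

_MAX_ENUM = 22  # 2^22 sums ~ 34 MB; enumeration above this is a usage error


@dataclass(frozen=True)
class ContrastResult:
    """Outcome of one matched-pair contrast analysis."""

    metric: str
    contrasts: tuple[float, ...]     #: per-pair values, input order, zeros kept
    statistic: float                 #: sum of contrasts, or W+
    test_used: str                   #: sign_permutation | wilcoxon_exact | wilcoxon_normal | binomial
    tails: str                       #: "one" | "two"
    p_value: float
    n_used: int                      #: contrasts entering the test after zero handling
    n_positive: int = 0              #: nonzero contrasts with positive sign


def contrast(metric: Metric, a: float, b: float) -> float:
    """Single sister contrast between quantities ``a`` (focal) and ``b``."""
    if metric == "raw":
        return a - b
    if metric == "proportional":
        if a + b == 0:
            raise ValueError("proportional contrast undefined for a + b == 0")
        return (a - b) / (a + b)
    if metric == "logratio":
        if a <= 0 or b <= 0:
            raise ValueError("log-ratio contrast requires positive inputs")
        return math.log(a / b)
    raise ValueError(f"unknown metric {metric!r}")


def _nonzero(contrasts: Sequence[float]) -> np.ndarray:
    arr = np.asarray(contrasts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("contrasts must be one-dimensional")
    return arr[arr != 0.0]


def _all_sums(values: np.ndarray) -> np.ndarray:
    """Sums over all 2^m sign assignments of ``values``."""
    m = values.size
    if m > _MAX_ENUM:
        raise ValueError(f"enumeration over 2^{m} sign patterns refused")
    sums = np.zeros(1)
    for v in values:
        sums = np.concatenate([sums + v, sums - v])
    return sums


def sign_permutation_test(contrasts: Sequence[float]) -> float:
    """Exact two-tailed randomization test for matched pairs.

    Permutes the sign of each contrast, enumerating all 2^m assignments; the
    returned p is the fraction of assignments whose |sum of contrasts| is at
    least the observed |sum| (inclusive, so p >= 2/2^m and p <= 1).
    """
    vals = _nonzero(contrasts)
    if vals.size == 0:
        raise ValueError("no nonzero contrasts to test")
    observed = abs(vals.sum())
    sums = np.abs(_all_sums(vals))
    tol = 1e-9 * max(1.0, observed)
    return float(np.count_nonzero(sums >= observed - tol)) / sums.size


def _signed_ranks(vals: np.ndarray) -> np.ndarray:
    """Tie-averaged ranks of |contrasts|, doubled so they are integers."""
    ranks = stats.rankdata(np.abs(vals))          # average ranks for ties
    doubled = np.rint(ranks * 2).astype(np.int64)
    return doubled


def _wplus_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Exact counts of 2*W+ over all sign patterns, by convolution."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts  # counts[w2] = #assignments with 2*W+ == w2


def wilcoxon_signed_rank_exact(
    contrasts: Sequence[float],
    alternative: Literal["two-sided", "greater"] = "two-sided",
    drop_zeros: bool = True,
) -> tuple[float, float]:
    """Exact Wilcoxon signed-rank test; returns (W+, p).

    The null distribution of W+ is enumerated over all 2^m sign patterns on
    the realized tie-averaged ranks (a conditional-on-ties exact test).  The
    two-sided p is P(W >= max(W+, W-)) + P(W <= min(W+, W-)), capped at 1;
    the one-sided p ("greater") is P(W >= W+).

    With ``drop_zeros=False`` zeros are kept with rank handling after Pratt:
    zeros enter the ranking of |contrasts| but contribute no rank to W+ or
    W-, and their signs are not permuted.
    """
    arr = np.asarray(contrasts, dtype=float)
    if drop_zeros:
        vals = _nonzero(arr)
        if vals.size == 0:
            raise ValueError("no nonzero contrasts after zero removal")
        doubled = _signed_ranks(vals)
    else:
        if not np.any(arr != 0):
            raise ValueError("all contrasts are zero")
        all_doubled = _signed_ranks(arr)
        vals = arr[arr != 0]
        doubled = all_doubled[arr != 0]
    if vals.size > _MAX_ENUM:
        raise ValueError("exact enumeration refused beyond m = 22; "
                         "use wilcoxon_normal_approx")
    w2_plus = int(doubled[vals > 0].sum())
    counts = _wplus_distribution(doubled)
    total = counts.sum()
    if alternative == "greater":
        p = counts[w2_plus:].sum() / total
    else:
        w2_minus = int(doubled.sum()) - w2_plus
        hi, lo = max(w2_plus, w2_minus), min(w2_plus, w2_minus)
        p = (counts[hi:].sum() + counts[: lo + 1].sum()) / total
        p = min(1.0, p)
    return w2_plus / 2.0, float(p)


def wilcoxon_normal_approx(
    contrasts: Sequence[float],
    alternative: Literal["two-sided", "greater"] = "two-sided",
) -> tuple[float, float]:
    """Normal approximation to the signed-rank test; returns (W+, p).

    z = (W+ - m(m+1)/4) / sqrt(m(m+1)(2m+1)/24 - tie correction), with a 0.5
    continuity correction toward the mean.
    """
    vals = _nonzero(contrasts)
    if vals.size == 0:
        raise ValueError("all contrasts are zero")
    m = vals.size
    ranks = stats.rankdata(np.abs(vals))
    w_plus = float(ranks[vals > 0].sum())
    mean = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    # tie correction: sum(t^3 - t)/48 over groups of tied |contrasts|
    _, tie_counts = np.unique(np.abs(vals), return_counts=True)
    var -= float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
    if var <= 0:
        raise ValueError("zero variance: all |contrasts| tied at one value")
    dev = w_plus - mean
    if alternative == "greater":
        z = (dev - 0.5) / math.sqrt(var) if dev != 0 else 0.0
        p = float(stats.norm.sf(z))
    else:
        if dev == 0:
            return w_plus, 1.0
        z = (abs(dev) - 0.5) / math.sqrt(var)
        p = float(2.0 * stats.norm.sf(z))
    return w_plus, min(1.0, p)


def binomial_sign_test(n_success: int, n_trials: int) -> float:
    """Exact two-tailed binomial sign test at p = 0.5, by tail doubling."""
    if not 0 <= n_success <= n_trials or n_trials < 1:
        raise ValueError("need 0 <= n_success <= n_trials, n_trials >= 1")
    lo = stats.binom.cdf(n_success, n_trials, 0.5)
    hi = stats.binom.sf(n_success - 1, n_trials, 0.5)
    return float(min(1.0, 2.0 * min(lo, hi)))


# ---------------------------------------------------------------------------
# dispatched analyses


def _dispatch(
    contrasts_all: Sequence[float],
    metric: str,
    tails: Literal["one", "two"],
) -> ContrastResult:
    vals = _nonzero(contrasts_all)
    m = vals.size
    if m == 0:
        raise ValueError("no nonzero contrasts: every pair is tied")
    n_positive = int(np.count_nonzero(vals > 0))
    alt = "greater" if tails == "one" else "two-sided"
    if m <= 10:
        if tails == "one":
            w_plus, p = wilcoxon_signed_rank_exact(vals, alternative="greater")
            return ContrastResult(metric, tuple(contrasts_all), w_plus,
                                  "wilcoxon_exact", tails, p, m, n_positive)
        p = sign_permutation_test(vals)
        return ContrastResult(metric, tuple(contrasts_all), float(vals.sum()),
                              "sign_permutation", tails, p, m, n_positive)
    if m <= 19:
        w_plus, p = wilcoxon_signed_rank_exact(vals, alternative=alt)
        return ContrastResult(metric, tuple(contrasts_all), w_plus,
                              "wilcoxon_exact", tails, p, m, n_positive)
    w_plus, p = wilcoxon_normal_approx(vals, alternative=alt)
    return ContrastResult(metric, tuple(contrasts_all), w_plus,
                          "wilcoxon_normal", tails, p, m, n_positive)


def diversity_contrast_analysis(
    table: SisterPairTable, metric: Metric = "logratio"
) -> ContrastResult:
    """Two-tailed test of diversification asymmetry across sister pairs.

    Contrasts are galler vs non-galler species richness under ``metric``;
    exact zeros are dropped, then the test is dispatched on the number of
    remaining contrasts (<=10 sign permutation, 11-19 exact signed-rank,
    >=20 normal approximation).
    """
    cons = [contrast(metric, p.n_galler, p.n_nongaller) for p in table]
    return _dispatch(cons, metric, "two")


def host_specificity_test(table: SisterPairTable) -> ContrastResult:
    """One-tailed test that gallers are more host-specific than non-gallers.

    Differences d = host-MRCA age(non-galler) - host-MRCA age(galler); pairs
    with equal ages (including both-zero rows, where no MRCA depth is
    resolvable) contribute nothing.  The alternative is d > 0 — gallers with
    the narrower (younger-MRCA) host range.  Exact signed-rank enumeration
    for m <= 19 nonzero differences, normal approximation beyond.
    """
    diffs = [p.host_age_nongaller - p.host_age_galler for p in table]
    return _dispatch(diffs, "raw", "one")
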