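"""Validation arithmetic: hypergeometric enrichment of a prediction set
against a curated set, match and expansion percentages.

The enrichment question is the classic urn draw: out of ``N`` genes (or
miRNAs), ``K`` are curated disease entries; a method proposes ``n`` of the
``N``; ``x`` of the proposals are curated.  ``hypergeom_tail`` returns the
right-tail survival probability P(X >= x) — the probability of doing at
least this well by chance — which is the quantity to report as an
enrichment p-value.  ``hypergeom_point`` returns the point mass P(X = x);
published summary probabilities are sometimes point masses rather than
tails, so both conventions are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from scipy.stats import hypergeom


@dataclass(frozen=True)
class HypergeomTest:
    N: int  # universe size
    K: int  # curated successes in the universe
    n: int  # prediction set size
    x: int  # observed successes among predictions
    p: float  # right-tail probability P(X >= x)


def _check_args(N: int, K: int, n: int, x: int) -> None:
    for name, v in (("N", N), ("K", K), ("n", n), ("x", x)):
        if not isinstance(v, (int,)) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if K > N or n > N:
        raise ValueError(f"K and n must not exceed N (N={N}, K={K}, n={n})")
    if x > min(n, K):
        raise ValueError(f"impossible observation: x={x} > min(n={n}, K={K})")


def hypergeom_tail(N: int, K: int, n: int, x: int) -> float:
    """Exact right-tail P(X >= x) under Hypergeometric(N, K, n).

    Computed via the scipy survival function, which accumulates the log-pmf
    terms stably for large N.
    """
    _check_args(N, K, n, x)
    if x == 0:
        return 1.0
    return float(hypergeom.sf(x - 1, N, K, n))


def hypergeom_point(N: int, K: int, n: int, x: int) -> float:
    """Point probability P(X = x) under Hypergeometric(N, K, n)."""
    _check_args(N, K, n, x)
    return float(hypergeom.pmf(x, N, K, n))


def hypergeom_test(N: int, K: int, predicted: set[str], curated_in_universe: set[str]) -> HypergeomTest:
    """Right-tail test of ``|predicted ∩ curated|`` given set sizes."""
    n = len(predicted)
    x = len(predicted & curated_in_universe)
    return HypergeomTest(N=N, K=K, n=n, x=x, p=hypergeom_tail(N, K, n, x))


def _pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to 2 decimal places."""
    val = Decimal(100 * numerator) / Decimal(denominator)
    return float(val.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def match_rate(predicted: set[str], curated: set[str]) -> tuple[int, float]:
    """Overlap count and percentage of predictions found in the curated set."""
    if not predicted:
        raise ValueError("predicted set must be non-empty")
    x = len(predicted & curated)
    return x, _pct(x, len(predicted))


def expansion_rate(n_candidates: int, n_known: int) -> float:
    """Candidate count as a percentage of the known disease-gene count."""
    if n_known <= 0:
        raise ValueError("n_known must be positive")
    return _pct(n_candidates, n_known)
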