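"""Exact hypergeometric over-representation test and multiplicity corrections.

The P-value for observing ``m`` of ``n`` drawn proteins carrying a term,
when ``K`` of the ``N`` background proteins carry it, is the upper tail of
the hypergeometric distribution:

    P = sum_{x=m}^{min(K, n)} C(K, x) * C(N-K, n-x) / C(N, n)

computed exactly in log space (log-gamma combinatorics) so that
backgrounds of 10^5 proteins and beyond do not overflow.  No normal
approximation is used anywhere.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ptmenrich.errors import ParameterError

__all__ = [
    "CorrectionMethod",
    "HypergeomParams",
    "MIN_PVALUE",
    "bh_adjust",
    "bonferroni_adjust",
    "hypergeom_pvalue",
]

#: Reported floor for P-values that underflow double precision; results are
#: never reported as exactly zero.
MIN_PVALUE = 5e-324


class CorrectionMethod(enum.Enum):
    NONE = "none"
    BONFERRONI = "bonferroni"
    BENJAMINI_HOCHBERG = "bh"


@dataclass(frozen=True)
class HypergeomParams:
    """The (N, K, n, m) of the hypergeometric tail.

    population_size
        N — background protein count.
    success_count
        K — background proteins carrying the term.
    draw_count
        n — resolved query list size.
    observed
        m — query proteins carrying the term.
    """

    population_size: int
    success_count: int
    draw_count: int
    observed: int

    def validate(self) -> None:
        N, K, n, m = (
            self.population_size,
            self.success_count,
            self.draw_count,
            self.observed,
        )
        for name, v in (("N", N), ("K", K), ("n", n), ("m", m)):
            if not isinstance(v, (int, np.integer)):
                raise ParameterError(f"{name} must be an integer, got {v!r}")
        if not 0 <= K <= N:
            raise ParameterError(f"violated 0 <= K <= N (K={K}, N={N})")
        if not 0 <= n <= N:
            raise ParameterError(f"violated 0 <= n <= N (n={n}, N={N})")
        if not 0 <= m <= min(K, n):
            raise ParameterError(
                f"violated 0 <= m <= min(K, n) (m={m}, K={K}, n={n})"
            )


# growing cache of log-factorials; index i holds log(i!)
_LOG_FACT = np.zeros(1)


def _log_factorials(upto: int) -> np.ndarray:
    global _LOG_FACT
    if upto >= len(_LOG_FACT):
        size = max(upto + 1, 2 * len(_LOG_FACT))
        table = np.empty(size)
        table[: len(_LOG_FACT)] = _LOG_FACT
        start = len(_LOG_FACT)
        table[start:] = np.log(np.arange(start, size))
        np.cumsum(table[start - 1 :], out=table[start - 1 :])
        _LOG_FACT = table
    return _LOG_FACT


def hypergeom_pvalue(params: HypergeomParams) -> float:
    """Exact upper-tail hypergeometric probability of the given parameters.

    Returns a value in (0, 1]; ``m == 0`` gives exactly 1.  Probabilities
    below double-precision range are floored at :data:`MIN_PVALUE` rather
    than reported as zero.
    """
    params.validate()
    N, K, n, m = (
        params.population_size,
        params.success_count,
        params.draw_count,
        params.observed,
    )
    if m == 0:
        return 1.0
    lf = _log_factorials(N)
    # x below n-(N-K) would require drawing more failures than exist; those
    # terms are exactly zero and are excluded from the log-space sum
    lo = max(m, n - (N - K))
    xs = np.arange(lo, min(K, n) + 1)
    # log C(K,x) + log C(N-K, n-x) - log C(N, n)
    log_terms = (
        lf[K]
        - lf[xs]
        - lf[K - xs]
        + lf[N - K]
        - lf[n - xs]
        - lf[N - K - (n - xs)]
        - (lf[N] - lf[n] - lf[N - n])
    )
    peak = log_terms.max()
    p = float(np.exp(peak) * np.exp(log_terms - peak).sum())
    if p <= 0.0:
        return MIN_PVALUE
    return min(p, 1.0)


def bonferroni_adjust(
    pvalues: Sequence[float], alpha: float = 0.05
) -> tuple[list[float], float]:
    """Bonferroni FWER control: p*T capped at 1, plus the modified alpha.

    Returns ``(adjusted_pvalues, alpha / T)``.  Comparing adjusted P to
    alpha and raw P to the modified alpha are decision-equivalent.
    """
    pvalues = list(pvalues)
    if not pvalues:
        raise ParameterError("no P-values to adjust")
    _check_pvalues(pvalues)
    T = len(pvalues)
    return [min(1.0, p * T) for p in pvalues], alpha / T


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up FDR-adjusted P-values, in input order.

    Sorted ascending, ``q_(i) = p_(i) * T / i`` with monotonicity enforced
    by a cumulative minimum from the largest rank down, capped at 1.  Tied
    P-values share the adjusted value of their best rank.
    """
    pvalues = list(pvalues)
    if not pvalues:
        raise ParameterError("no P-values to adjust")
    _check_pvalues(pvalues)
    p = np.asarray(pvalues, dtype=float)
    T = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * T / np.arange(1, T + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adjusted = np.empty(T)
    adjusted[order] = adjusted_sorted
    return adjusted.tolist()


def _check_pvalues(pvalues: Sequence[float]) -> None:
    for p in pvalues:
        if not (0.0 < p <= 1.0) or math.isnan(p):
            raise ParameterError(f"P-value {p!r} outside (0, 1]")
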