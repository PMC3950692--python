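"""Small statistical helpers used across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """Percentage rounded half-up to the printed precision.

    ``percent(132, 154) == 86.0`` and ``percent(111, 1260, 1) == 8.8``.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    value = Decimal(100 * numerator) / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (monotone step-up)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def empirical_p(null_values, observed: float) -> float:
    """Permutation p / empirical FDR with the add-one correction.

    ``(1 + #{null >= observed}) / (1 + n_null)`` so the estimate is never 0.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("need at least one permutation replicate")
    return float((1 + np.sum(null_values >= observed)) / (1 + null_values.size))
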