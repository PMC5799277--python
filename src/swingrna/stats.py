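"""Statistical primitives: one-tailed Pearson, tie-corrected Spearman,
Fisher's combined probability, and Benjamini-Hochberg adjustment.

One-tailed p-values are upper-tail throughout (positive association); a
negative correlation therefore reports p > 0.5.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from .errors import ConstantInputError, InputError


@dataclass(frozen=True)
class CombinedTest:
    """Fisher's combined-probability result: chi2 = -2 * sum(ln p_i) on
    2k degrees of freedom."""

    chi_square: float
    df: int
    p_combined: float


def fisher_combine(pvalues: Sequence[float]) -> CombinedTest:
    """Combine independent one-tailed p-values by Fisher's method."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise InputError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return CombinedTest(chi2, df, float(_sps.chi2.sf(chi2, df)))


def _t_upper_p(r: float, df: int) -> float:
    """Upper-tail p of a correlation via the t-transform on ``df``."""
    if r >= 1.0:
        return 0.0
    if r <= -1.0:
        return 1.0
    t = r * math.sqrt(df / (1.0 - r * r))
    return float(_sps.t.sf(t, df))


def pearson_one_tailed(x: Sequence[float], y: Sequence[float]
                       ) -> tuple[float, float]:
    """Product-moment r with an upper-tail p from the t-transform
    (df = n - 2)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InputError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    return r, _t_upper_p(r, x.size - 2)


def spearman_midrank(x: Sequence[float], y: Sequence[float]
                     ) -> tuple[float, float]:
    """Spearman rs on mid-ranks (ties share averaged ranks) with an
    upper-tail t-approximation p (df = n - 2)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InputError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    rs = float(_sps.spearmanr(x, y).statistic)
    return rs, _t_upper_p(rs, x.size - 2)


def spearman_exact(x: Sequence[float], y: Sequence[float]
                   ) -> tuple[float, float]:
    """Exact one-tailed permutation p for mid-rank Spearman (n <= 10).

    Enumerates all n! pairings of the rank vectors; p is the fraction with
    rs at least as large as observed. Intended for small samples and as a
    cross-check of the t approximation.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n = x.size
    if n > 10:
        raise InputError("exact permutation p is limited to n <= 10")
    rs_obs, _ = spearman_midrank(x, y)
    rx = _sps.rankdata(x)
    ry = _sps.rankdata(y)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        rp = ry[list(perm)]
        rs = float(np.corrcoef(rx, rp)[0, 1])
        count += rs >= rs_obs - 1e-12
        total += 1
    return rs_obs, count / total


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-
    preserving, each >= the raw value and <= 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
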