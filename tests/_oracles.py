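"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the clumping oracle
is a from-scratch re-expression of the greedy rule over explicit sets, and
the regression oracle goes through statsmodels WLS.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm


def greedy_clump_ids(
    entries: list[tuple[str, float]],
    r2_lookup: dict[frozenset, float],
    threshold: float,
) -> list[str]:
    """Greedy clumping over (variant_id, pval) entries with an explicit
    pairwise r² lookup (missing pairs count as 0)."""
    pool = sorted(entries, key=lambda e: (e[1], e[0]))
    kept: list[str] = []
    while pool:
        best = pool.pop(0)
        kept.append(best[0])
        pool = [
            e for e in pool
            if r2_lookup.get(frozenset((best[0], e[0])), 0.0) < threshold
        ]
    return kept


def wls_slope_through_origin(bx, by, se_out) -> float:
    w = 1.0 / np.asarray(se_out) ** 2
    fit = sm.WLS(by, np.asarray(bx)[:, None], weights=w).fit()
    return float(fit.params[0])


def wls_with_intercept(bx, by, se_out) -> tuple[float, float]:
    """(intercept, slope) of the weighted regression, instruments oriented
    to non-negative exposure effects as MR-Egger requires."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / np.asarray(se_out) ** 2
    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    return float(fit.params[0]), float(fit.params[1])
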