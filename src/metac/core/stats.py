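"""Shared statistical primitives.

All tests are two-sided.  The Mann-Whitney U statistic follows the
convention U = #{(i, j): x_i > y_j} + (1/2)#ties, i.e. the statistic of
the *first* sample; exact enumeration is used for small untied samples
and a tie- and continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from metac.core.types import TestResult

_MW_MODES = {"exact": "exact", "normal_approx": "asymptotic", "auto": "auto"}


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    ``mode='auto'`` uses exact enumeration when both samples have at
    most 8 observations and there are no ties, and the corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if mode not in _MW_MODES:
        raise ValueError(f"mode must be one of {sorted(_MW_MODES)}")
    res = _sps.mannwhitneyu(
        x, y, alternative="two-sided", method=_MW_MODES[mode], use_continuity=True
    )
    p = float(res.pvalue)
    if np.isnan(p):
        # all observations tied across both samples: no evidence either way
        p = 1.0
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(p, 1.0),
        method=f"mann_whitney_u[{mode}]",
        n_per_group=(x.size, y.size),
    )


def spearman_corr(a, b) -> TestResult:
    """Spearman rank correlation with t-approximation p-value.

    A constant input vector makes the correlation undefined; the result
    is returned with ``undefined=True`` and statistic 0 rather than
    propagating NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return TestResult(0.0, 1.0, "spearman", (a.size,), undefined=True)
    rs, p = _sps.spearmanr(a, b)
    if np.isnan(rs):
        return TestResult(0.0, 1.0, "spearman", (a.size,), undefined=True)
    return TestResult(float(rs), float(min(p, 1.0)), "spearman", (a.size,))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
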