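"""Nonparametric statistics shared by every pipeline stage.

Four procedures: two-sided Mann–Whitney U, Benjamini–Hochberg FDR
adjustment, Spearman rank correlation and trapezoidal area under a
day-indexed curve.  The Mann–Whitney contract: exact enumeration when the
pooled size is at most :data:`EXACT_N_MAX` and the pooled data are
tie-free, otherwise a normal approximation with tie correction and a
continuity correction that returns exactly 1 at the symmetric centre
(U = n1·n2/2) and when the tie-corrected variance vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: pooled-size bound below which the exact null distribution is enumerated
EXACT_N_MAX = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float  # U for the first sample
    p_value: float
    method: str  # "exact" | "normal approximation"
    n1: int
    n2: int


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-based U for sample x (midranks handle ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def mann_whitney(x, y, mode: str = "auto", alternative: str = "two-sided") -> TestResult:
    """Mann–Whitney U test between two independent samples.

    ``mode`` is ``"auto"`` (exact for small tie-free inputs), ``"exact"``
    or ``"asymptotic"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (
        mode == "auto" and n1 + n2 <= EXACT_N_MAX and not has_ties
    )

    if use_exact:
        res = sps.mannwhitneyu(x, y, alternative=alternative, method="exact")
        return TestResult(float(res.statistic), float(res.pvalue), "exact", n1, n2)

    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(float(u), 1.0, "normal approximation", n1, n2)
    if alternative == "two-sided":
        z = max(abs(u - mu) - 0.5, 0.0) / np.sqrt(var)
        p = 2.0 * sps.norm.sf(z)
    elif alternative == "less":
        z = (u - mu + 0.5) / np.sqrt(var)
        p = sps.norm.cdf(z)
    elif alternative == "greater":
        z = (u - mu - 0.5) / np.sqrt(var)
        p = sps.norm.sf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(float(u), float(min(p, 1.0)), "normal approximation", n1, n2)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("spearman_rho requires length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant vector has undefined rank correlation")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def trapezoid_auc(values, days) -> float:
    """Trapezoidal area of ``values`` against strictly increasing ``days``."""
    values = np.asarray(values, dtype=float)
    days = np.asarray(days, dtype=float)
    if values.size != days.size:
        raise ValueError("values and days must have equal length")
    if values.size < 2:
        raise ValueError("need at least two days for an area")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    return float(np.trapezoid(values, days))
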