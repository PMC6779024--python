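"""Descriptive, reliability and nonparametric statistics (SPSS conventions).

The reporting conventions of legacy SPSS are implemented deliberately:
bias-adjusted skewness/kurtosis with their small-sample standard errors,
weighted-average (HAVERAGE) percentiles, midranks for ties, and
zero-difference removal in the Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "DescriptiveSummary",
    "describe",
    "cronbach_alpha",
    "spearman_rho",
    "wilcoxon_signed_rank",
    "skewness_se",
    "kurtosis_se",
]


def skewness_se(n: int) -> float:
    """Standard error of sample skewness: sqrt(6n(n-1)/((n-2)(n+1)(n+3)))."""
    if n < 3:
        raise ValueError(f"skewness SE requires n >= 3, got n={n}")
    return math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))


def kurtosis_se(n: int) -> float:
    """Standard error of sample excess kurtosis: 2*SE_skew*sqrt((n^2-1)/((n-3)(n+5)))."""
    if n < 4:
        raise ValueError(f"kurtosis SE requires n >= 4, got n={n}")
    return 2.0 * skewness_se(n) * math.sqrt((n * n - 1.0) / ((n - 3.0) * (n + 5.0)))


@dataclass(frozen=True)
class DescriptiveSummary:
    n: int
    mean: float
    sd: float
    median: float
    iqr_low: float
    iqr_high: float
    cv: float
    skewness: float
    se_skewness: float
    kurtosis: float
    se_kurtosis: float


def describe(x) -> DescriptiveSummary:
    """Descriptive summary of a numeric vector.

    Percentiles use the weighted-average definition at (n+1)p (SPSS
    HAVERAGE); skewness and excess kurtosis are the bias-adjusted sample
    statistics G1 and G2 with their small-sample standard errors.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError(f"describe requires n >= 5, got n={n}")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("skewness undefined: zero variance")
    mean = float(np.mean(x))
    if mean == 0.0:
        raise ValueError("cv undefined: zero mean")
    q25, q50, q75 = np.percentile(x, [25, 50, 75], method="weibull")
    return DescriptiveSummary(
        n=n,
        mean=mean,
        sd=sd,
        median=float(q50),
        iqr_low=float(q25),
        iqr_high=float(q75),
        cv=sd / mean,
        skewness=float(sps.skew(x, bias=False)),
        se_skewness=skewness_se(n),
        kurtosis=float(sps.kurtosis(x, fisher=True, bias=False)),
        se_kurtosis=kurtosis_se(n),
    )


def cronbach_alpha(item_matrix) -> float:
    """Internal-consistency coefficient alpha.

    alpha = k/(k-1) * (1 - sum_i var(item_i) / var(total)), with n-1
    denominators throughout. Rows are participants, columns items; no
    missing cells allowed.
    """
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("item_matrix must be 2-dimensional (participants x items)")
    n, k = m.shape
    if k < 2 or n < 2:
        raise ValueError(f"cronbach_alpha requires >= 2 items and >= 2 participants, got {m.shape}")
    if np.any(~np.isfinite(m)):
        raise ValueError("item_matrix contains missing or non-finite cells")
    total_var = np.var(m.sum(axis=1), ddof=1)
    if total_var == 0.0:
        raise ValueError("alpha undefined: zero total-score variance")
    item_vars = np.var(m, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman rank correlation with midranks for ties.

    rho is the Pearson correlation of average ranks; the two-sided p-value
    comes from the t approximation on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 3:
        raise ValueError(f"spearman_rho requires n >= 3, got n={n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0.0 or np.std(ry) == 0.0:
        raise ValueError("rank variance is zero in one of the vectors")
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    rho = float(np.dot(dx, dy) / math.sqrt(np.dot(dx, dx) * np.dot(dy, dy)))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p_value=p, n=n)


@dataclass(frozen=True)
class WilcoxonResult:
    w: float  # sum of ranks of positive differences (x - y)
    z: float
    p_value: float
    n: int  # pairs remaining after zero-difference removal
    exact: bool


#: Largest n for which the exact sign-enumeration p-value is used.
WILCOXON_EXACT_N = 12


def _wilcoxon_exact_p(ranks: np.ndarray, w: float) -> float:
    """Two-sided exact p by enumerating all 2^n sign assignments.

    Under H0 the distribution of W+ is symmetric about n(n+1)/4 even with
    midranks, so the two-sided p is P(|W - mu| >= |w - mu|).
    """
    n = len(ranks)
    signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    w_all = signs @ ranks
    mu = ranks.sum() / 2.0
    return float(np.mean(np.abs(w_all - mu) >= abs(w - mu) - 1e-12))


def wilcoxon_signed_rank(x, y) -> WilcoxonResult:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; |d| receives midranks; Z uses the
    tie-corrected normal approximation without continuity correction. For
    n <= 12 remaining pairs the p-value is computed exactly by sign
    enumeration, otherwise from the normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    d = x - y
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero: test undefined")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / 48.0)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0.0:
        raise ValueError("zero variance in signed ranks: test undefined")
    z = (w - mu) / math.sqrt(var)
    exact = n <= WILCOXON_EXACT_N
    if exact:
        p = _wilcoxon_exact_p(ranks, w)
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return WilcoxonResult(w=w, z=z, p_value=p, n=n, exact=exact)
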