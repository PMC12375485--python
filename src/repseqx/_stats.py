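"""Shared statistical helpers: rank tests and the moderated two-sample t."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["mann_whitney", "moderated_ttest"]

#: both group sizes at or below this use the exact Mann-Whitney null
#: distribution (no ties); the cohort sizes of interest (12 vs 8) sit at
#: the exact-feasible boundary
EXACT_MAX_N = 12


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Uses the exact null distribution when both groups have <= 12
    observations and no ties are present, otherwise the normal
    approximation with tie correction.  Returns ``(U, p)`` where U is the
    statistic of the first sample.  Degenerate input (all values identical)
    returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def moderated_ttest(
    X: np.ndarray, labels: np.ndarray, prior_df: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sample t-tests with empirical-Bayes variance shrinkage.

    Each row of ``X`` (features x samples) is tested for a mean difference
    between the two label classes (effect = mean(label 1) - mean(label 0)).
    The per-row pooled variance ``s2`` (residual df d = n1 + n0 - 2) is
    shrunk toward the prior ``s0^2 = mean(s2)`` over rows with df-weighted
    blending::

        s2_post = (d * s2 + d0 * s0^2) / (d + d0)

    and the statistic ``t = effect / sqrt(s2_post * (1/n1 + 1/n0))`` is
    referred to a t distribution with ``d + d0`` degrees of freedom.

    ``prior_df`` (d0) defaults to the residual df d; ``prior_df=0`` recovers
    the ordinary two-sample pooled t-test exactly.

    Returns ``(effect, t, p)`` arrays.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).astype(int)
    if X.ndim != 2 or X.shape[1] != labels.size:
        raise ValueError("X must be features x samples matching labels")
    g1 = X[:, labels == 1]
    g0 = X[:, labels == 0]
    n1, n0 = g1.shape[1], g0.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs at least two samples")
    d = n1 + n0 - 2
    effect = g1.mean(axis=1) - g0.mean(axis=1)
    ss = g1.var(axis=1, ddof=1) * (n1 - 1) + g0.var(axis=1, ddof=1) * (n0 - 1)
    s2 = ss / d
    d0 = float(d) if prior_df is None else float(prior_df)
    s0_sq = s2.mean()
    s2_post = (d * s2 + d0 * s0_sq) / (d + d0)
    denom = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, effect / denom, np.sign(effect) * np.inf)
    t = np.where((denom == 0) & (effect == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=d + d0)
    return effect, t, p
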