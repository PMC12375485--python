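"""Repertoire diversity statistics and their group/age comparisons.

Three complementary indices summarise a clone-abundance vector:

* **Gini coefficient** — evenness.  With relative abundances x_i,
  ``G = sum_ij |x_i - x_j| / (2 n^2 xbar)``; 0 for a perfectly even
  repertoire, approaching 1 when a few clones dominate.
* **Chao1** — richness including unseen clones:
  ``S_chao1 = S_obs + a1 (a1 - 1) / (2 (a2 + 1))`` with singleton count a1
  and doubleton count a2 (bias-corrected form, defined for a2 = 0).
* **Inverse Simpson** — effective number of equally abundant clones,
  ``1 / sum p_i^2``; ranges from 1 (monoclonal) to S (uniform).

Group contrasts use the two-sided Wilcoxon-Mann-Whitney test; age trends use
the Pearson correlation, fitted per clinical group and overall.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import mann_whitney
from .core import AbundanceVector, RepertoireSample, RepertoireSet

__all__ = [
    "gini_coefficient",
    "chao1_index",
    "inverse_simpson",
    "diversity_result",
    "diversity_table",
    "age_correlation",
]

#: per-sample metrics emitted by :func:`diversity_table`
DIVERSITY_METRICS = ["unique_clonotypes", "gini", "chao1", "inv_simpson"]


def _as_proportions(v) -> np.ndarray:
    if isinstance(v, AbundanceVector):
        return v.proportions
    arr = np.asarray(v, dtype=float)
    if arr.size == 0:
        raise ValueError("empty abundance vector")
    return arr / arr.sum()


def gini_coefficient(v) -> float:
    """Gini coefficient of a clone-abundance vector, in [0, 1).

    Evaluates the mean-absolute-difference definition through its sorted
    closed form ``sum_i (2i - n - 1) x_(i) / (n sum_i x_i)`` (i = 1..n over
    ascending x), which is algebraically identical to the double sum.
    """
    x = np.sort(_as_proportions(v))
    n = x.size
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * x.sum()))


def chao1_index(v) -> float:
    """Bias-corrected Chao1 richness estimate, >= the observed clone count.

    Requires integer counts (singletons/doubletons are undefined otherwise);
    equals S_obs when at most one singleton exists.
    """
    if not isinstance(v, AbundanceVector):
        v = AbundanceVector.from_counts(v)
    if v.counts.size == 0:
        raise ValueError("Chao1 requires integer counts")
    a1, a2 = v.a1, v.a2
    return float(v.s_obs + a1 * (a1 - 1) / (2.0 * (a2 + 1)))


def inverse_simpson(v) -> float:
    """Inverse Simpson diversity ``1 / sum p_i^2`` in [1, S]."""
    p = _as_proportions(v)
    return float(1.0 / np.sum(p * p))


def diversity_result(sample: RepertoireSample) -> dict:
    """All per-sample indices for one repertoire."""
    v = AbundanceVector.from_sample(sample)
    return {
        "sample_id": sample.sample_id,
        "group": sample.group,
        "age": sample.age,
        "unique_clonotypes": v.s_obs,
        "gini": gini_coefficient(v),
        "chao1": chao1_index(v),
        "inv_simpson": inverse_simpson(v),
    }


def diversity_table(rep_set: RepertoireSet) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-sample diversity indices plus malignant-vs-benign Wilcoxon p-values.

    Returns ``(table, p_values)`` where ``p_values`` maps each metric in
    ``unique_clonotypes, gini, chao1, inv_simpson`` to its two-sided
    Mann-Whitney p-value between the two groups.
    """
    table = pd.DataFrame([diversity_result(s) for s in rep_set])
    groups = table["group"]
    malignant = table[groups == "malignant"]
    benign = table[groups == "benign"]
    if len(malignant) == 0 or len(benign) == 0:
        raise ValueError("both benign and malignant groups must be non-empty")
    p_values = {
        metric: mann_whitney(malignant[metric], benign[metric])[1]
        for metric in DIVERSITY_METRICS
    }
    return table, p_values


def age_correlation(
    rep_set: RepertoireSet, metric: str = "unique_clonotypes"
) -> pd.DataFrame:
    """Pearson correlation of a diversity metric with age, overall and per group.

    ``metric`` is one of ``unique_clonotypes, gini, chao1, inv_simpson``.
    Each fitted subset needs >= 3 samples and non-constant ages.  Returns a
    DataFrame indexed by ``overall / benign / malignant`` with columns
    ``r, p, n``.
    """
    if metric not in DIVERSITY_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    table = pd.DataFrame([diversity_result(s) for s in rep_set])
    if table["age"].isna().any():
        raise ValueError("all samples need an age for age correlations")
    rows = {}
    subsets = {"overall": table}
    for g, sub in table.groupby("group"):
        subsets[str(g)] = sub
    for name, sub in subsets.items():
        if len(sub) < 3:
            continue
        ages = sub["age"].to_numpy(dtype=float)
        if np.ptp(ages) == 0:
            raise ValueError(f"{name}: zero age variance")
        r, p = stats.pearsonr(ages, sub[metric].to_numpy(dtype=float))
        rows[name] = {"r": float(r), "p": float(p), "n": len(sub)}
    return pd.DataFrame.from_dict(rows, orient="index")
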