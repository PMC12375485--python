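"""V / J / V-J gene-segment usage matrices and their group statistics.

Usage is the fraction of a sample's repertoire attributed to each germline
segment (or V-J pair), under read weighting (clone-frequency weighted,
default) or clonotype weighting (each unique clone counts once).  Segments
absent from a sample get usage 0, so every sample shares a fixed-length
vector over the cohort-wide segment universe.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import mann_whitney
from .core import RepertoireSet

__all__ = ["usage_matrix", "differential_usage", "usage_correlation"]


def _segment_series(sample, axis: str) -> pd.Series:
    t = sample.table
    if axis == "V":
        seg = t["v_gene"]
    elif axis == "J":
        seg = t["j_gene"]
    elif axis == "VJ":
        seg = t["v_gene"] + "_" + t["j_gene"]
    else:
        raise ValueError(f"axis must be V, J or VJ, got {axis!r}")
    return seg


def usage_matrix(
    rep_set: RepertoireSet, axis: str = "VJ", weighting: str = "reads"
) -> pd.DataFrame:
    """Samples x segments usage-fraction matrix; rows sum to 1."""
    rows = {}
    for s in rep_set:
        seg = _segment_series(s, axis)
        if weighting == "reads":
            frac = s.table.groupby(seg)["read_count"].sum() / s.total_reads
        elif weighting == "clonotypes":
            frac = seg.value_counts() / len(seg)
        else:
            raise ValueError(f"weighting must be 'reads' or 'clonotypes', got {weighting!r}")
        rows[s.sample_id] = frac
    m = pd.DataFrame(rows).T.fillna(0.0)
    m = m[sorted(m.columns)]
    m.attrs["axis"] = axis
    m.attrs["weighting"] = weighting
    return m


def differential_usage(
    matrix: pd.DataFrame, groups: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Uncorrected two-sided Mann-Whitney per segment between groups.

    Returns a DataFrame (segment, p, direction, significant) where
    ``direction`` is the group with the larger mean usage.  Constant
    segments get p = 1 and a tie warning.
    """
    groups = groups.reindex(matrix.index)
    mal = matrix[groups == "malignant"]
    ben = matrix[groups == "benign"]
    if len(mal) < 2 or len(ben) < 2:
        raise ValueError("need >= 2 samples per group")
    records = []
    for seg in matrix.columns:
        x, y = mal[seg].to_numpy(), ben[seg].to_numpy()
        if np.ptp(np.concatenate([x, y])) == 0:
            warnings.warn(f"segment {seg}: constant usage, tie")
            p = 1.0
        else:
            p = mann_whitney(x, y)[1]
        records.append(
            {
                "segment": seg,
                "p": p,
                "direction": "malignant" if x.mean() > y.mean() else "benign",
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(records)


def usage_correlation(
    matrix: pd.DataFrame, groups: pd.Series
) -> dict[str, np.ndarray]:
    """Pairwise Spearman correlations of usage vectors, partitioned into
    within-malignant / within-benign / between pairs."""
    groups = groups.reindex(matrix.index)
    if (groups == "malignant").sum() < 2 or (groups == "benign").sum() < 2:
        raise ValueError("need >= 2 samples per group")
    parts: dict[str, list[float]] = {
        "within_malignant": [],
        "within_benign": [],
        "between": [],
    }
    for i, j in combinations(range(len(matrix)), 2):
        xi, xj = matrix.iloc[i].to_numpy(), matrix.iloc[j].to_numpy()
        if np.ptp(xi) == 0 or np.ptp(xj) == 0:
            warnings.warn(
                f"zero-variance usage vector ({matrix.index[i]} / {matrix.index[j]}), pair skipped"
            )
            continue
        rho = stats.spearmanr(xi, xj).statistic
        gi, gj = groups.iloc[i], groups.iloc[j]
        if gi == gj == "malignant":
            parts["within_malignant"].append(rho)
        elif gi == gj == "benign":
            parts["within_benign"].append(rho)
        else:
            parts["between"].append(rho)
    return {k: np.asarray(v) for k, v in parts.items()}
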