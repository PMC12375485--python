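"""Public-clonotype sharing, differential clonotypes and CDR3 motif matrices.

Sharing is counted at the CDR3 amino-acid level by default (configurable to
the full V + CDR3 nt + J key).  Differential clonotype calling follows a
count-based pipeline: presence filter, log2 counts-per-million with a 0.5
pseudocount, then a per-clone moderated two-sample t-test
(empirical-Bayes variance shrinkage; see :func:`repseqx._stats.moderated_ttest`),
reporting clones at p < 0.01 and |log2 fold change| >= 2, uncorrected for
multiple testing.
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd

from ._stats import mann_whitney, moderated_ttest
from .core import RepertoireSample, RepertoireSet

__all__ = [
    "shared_cdr3_matrix",
    "overlap_group_comparison",
    "differential_clonotypes",
    "motif_matrix",
    "position_frequency_matrix",
    "top_window_kmer",
]

AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")


def _key_set(sample: RepertoireSample, level: str) -> set:
    t = sample.table
    if level == "cdr3_aa":
        return set(t["cdr3_aa"])
    if level == "v_cdr3nt_j":
        return set(zip(t["v_gene"], t["cdr3_nt"], t["j_gene"]))
    raise ValueError(f"unknown sharing level {level!r}")


def shared_cdr3_matrix(rep_set: RepertoireSet, level: str = "cdr3_aa") -> pd.DataFrame:
    """Symmetric samples x samples matrix of shared-clonotype counts.

    Off-diagonal entry (i, j) is the size of the intersection of the two
    samples' key sets at the chosen level; the diagonal holds per-sample
    unique counts.
    """
    if len(rep_set) < 2:
        raise ValueError("need at least two samples")
    ids = rep_set.sample_ids
    sets = [_key_set(s, level) for s in rep_set]
    n = len(sets)
    m = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        m[i, i] = len(sets[i])
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = len(sets[i] & sets[j])
    return pd.DataFrame(m, index=ids, columns=ids)


def overlap_group_comparison(
    matrix: pd.DataFrame, groups: pd.Series
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Partition pairwise sharing counts and test partitions against each other.

    Off-diagonal entries split into ``within_malignant``, ``within_benign``
    and ``between``; each pair of partitions gets a two-sided Mann-Whitney
    p-value.  A group with fewer than two samples yields an empty partition
    (flagged by a warning).
    """
    groups = groups.reindex(matrix.index)
    parts: dict[str, list] = {"within_malignant": [], "within_benign": [], "between": []}
    ids = list(matrix.index)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            gi, gj = groups.iloc[i], groups.iloc[j]
            if gi == gj == "malignant":
                parts["within_malignant"].append(matrix.iloc[i, j])
            elif gi == gj == "benign":
                parts["within_benign"].append(matrix.iloc[i, j])
            else:
                parts["between"].append(matrix.iloc[i, j])
    arrays = {k: np.asarray(v, dtype=float) for k, v in parts.items()}
    for k, v in arrays.items():
        if v.size == 0:
            warnings.warn(f"overlap partition {k} is empty (group too small)")
    p_values: dict[str, float] = {}
    names = list(arrays)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ka, kb = names[a], names[b]
            if arrays[ka].size and arrays[kb].size:
                p_values[f"{ka}_vs_{kb}"] = mann_whitney(arrays[ka], arrays[kb])[1]
    return arrays, p_values


def _clone_count_matrix(rep_set: RepertoireSet, key: str) -> tuple[pd.DataFrame, pd.Series]:
    """clones x samples raw count matrix (zero where absent) and library sizes."""
    cols = {}
    for s in rep_set:
        t = s.table
        if key == "cdr3_aa":
            cols[s.sample_id] = t.groupby("cdr3_aa")["read_count"].sum()
        else:
            grouped = t.set_index(["v_gene", "cdr3_nt", "j_gene"])["read_count"]
            cols[s.sample_id] = grouped
    X = pd.DataFrame(cols).fillna(0).astype(np.int64)
    lib = pd.Series({s.sample_id: s.total_reads for s in rep_set})
    return X, lib


def differential_clonotypes(
    rep_set: RepertoireSet,
    p_threshold: float = 0.01,
    lfc_threshold: float = 2.0,
    min_presence: int = 3,
    prior_df: float | None = None,
    key: str = "cdr3_aa",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call clonotypes differentially abundant between malignant and benign.

    Pipeline: (i) keep clones present (count > 0) in >= ``min_presence``
    samples; (ii) log2 CPM with pseudocount 0.5 against full library sizes;
    (iii) moderated two-sample t per clone (malignant minus benign);
    (iv) report clones with p < ``p_threshold`` and |logFC| >=
    ``lfc_threshold``, labelled by direction.

    Returns ``(hits, full_table)`` where ``full_table`` covers every tested
    clone.  P-values are uncorrected.
    """
    groups = rep_set.groups
    labels = (groups == "malignant").astype(int).to_numpy()
    if labels.sum() < 2 or (1 - labels).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    X, lib = _clone_count_matrix(rep_set, key)
    present = (X > 0).sum(axis=1) >= min_presence
    X = X[present]
    if len(X) == 0:
        warnings.warn("no clonotype passes the presence filter")
        empty = pd.DataFrame(columns=["clone", "logFC", "p", "direction"])
        return empty, empty
    logcpm = np.log2(
        (X.to_numpy(dtype=float) + 0.5) / (lib.to_numpy(dtype=float) + 1.0) * 1e6
    )
    effect, t, p = moderated_ttest(logcpm, labels, prior_df=prior_df)
    full = pd.DataFrame(
        {
            "clone": X.index.to_list(),
            "logFC": effect,
            "t": t,
            "p": p,
            "n_present": (X > 0).sum(axis=1).to_numpy(),
        }
    )
    full["direction"] = np.where(full["logFC"] > 0, "malignant", "benign")
    hits = full[
        (full["p"] < p_threshold) & (full["logFC"].abs() >= lfc_threshold)
    ].reset_index(drop=True)
    return hits, full


# ---------------------------------------------------------------------------
# CDR3 positional motifs


def position_frequency_matrix(sequences: list[str]) -> pd.DataFrame:
    """Amino-acid x position frequency matrix (1-based positions from the
    CDR3 N-terminus).

    Position *k* is tallied over the sequences long enough to cover it, and
    each column is normalised to sum to 1.
    """
    sequences = [s for s in sequences if s]
    if not sequences:
        raise ValueError("no sequences")
    max_len = max(len(s) for s in sequences)
    counts = np.zeros((len(AMINO_ACIDS), max_len), dtype=float)
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for s in sequences:
        for pos, aa in enumerate(s):
            i = aa_index.get(aa)
            if i is not None:
                counts[i, pos] += 1
    col_sums = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(col_sums > 0, counts / col_sums, 0.0)
    return pd.DataFrame(
        freqs, index=AMINO_ACIDS, columns=range(1, max_len + 1)
    )


def top_window_kmer(
    sequences: list[str], window: tuple[int, int] = (6, 9)
) -> tuple[str, float]:
    """Most frequent contiguous k-mer spanning 1-based positions
    ``window[0]..window[1]`` among sequences covering the window.

    Ties break lexicographically for determinism.  Returns
    ``(kmer, frequency among eligible sequences)``.
    """
    start, end = window
    if start < 1 or end < start:
        raise ValueError("invalid window")
    eligible = [s[start - 1 : end] for s in sequences if len(s) >= end]
    if not eligible:
        raise ValueError(f"no sequence covers positions {start}-{end}")
    counts = Counter(eligible)
    best = min(counts, key=lambda k: (-counts[k], k))
    return best, counts[best] / len(eligible)


def motif_matrix(
    sequences: list[str], window: tuple[int, int] = (6, 9)
) -> tuple[pd.DataFrame, str, float]:
    """Positional frequency matrix plus the dominant k-mer over ``window``."""
    pfm = position_frequency_matrix(sequences)
    kmer, freq = top_window_kmer(sequences, window)
    return pfm, kmer, freq
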