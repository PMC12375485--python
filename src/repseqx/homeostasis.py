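"""Clonal-space homeostasis: partition repertoire frequency mass into
clone-size bins.

Each clone falls into one of five expansion classes by its relative
frequency — Rare (<1e-5), Small (1e-5..1e-4), Medium (1e-4..1e-3), Large
(1e-3..1e-2), Hyperexpanded (>1e-2) — and the bin mass is the summed
frequency of its clones, so the five masses partition the clonal space
(sum to 1).  Bins are [lower, upper): a clone at exactly 1e-4 is Medium;
the last bin is closed at 1.  Which bins are populated depends on
sequencing depth: frequencies below 1/depth are unobservable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import mann_whitney
from .core import RepertoireSample, RepertoireSet

__all__ = [
    "DEFAULT_EDGES",
    "BIN_NAMES",
    "clonal_space_bins",
    "homeostasis_profiles",
    "homeostasis_group_test",
]

DEFAULT_EDGES = (0.0, 1e-5, 1e-4, 1e-3, 1e-2, 1.0)
BIN_NAMES = ("Rare", "Small", "Medium", "Large", "Hyperexpanded")


def _bin_names(edges) -> list[str]:
    if len(edges) == len(DEFAULT_EDGES):
        return list(BIN_NAMES)
    return [f"({edges[i]:g}, {edges[i+1]:g})" for i in range(len(edges) - 1)]


def clonal_space_bins(
    sample: RepertoireSample, edges=DEFAULT_EDGES
) -> pd.Series:
    """Frequency mass per clone-size bin for one sample.

    ``edges`` are strictly increasing frequency breakpoints spanning (0, 1];
    bin *k* collects clones with ``edges[k] <= f < edges[k+1]`` (last bin
    closed above).  Returns a Series named by the sample id whose values sum
    to 1.
    """
    edges = np.asarray(edges, dtype=float)
    if (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    f = sample.table["frequency"].to_numpy(dtype=float)
    idx = np.searchsorted(edges, f, side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    masses = np.bincount(idx, weights=f, minlength=len(edges) - 1)
    return pd.Series(masses, index=_bin_names(edges), name=sample.sample_id)


def homeostasis_profiles(
    rep_set: RepertoireSet, edges=DEFAULT_EDGES
) -> pd.DataFrame:
    """Samples x bins mass matrix."""
    return pd.DataFrame([clonal_space_bins(s, edges) for s in rep_set])


def homeostasis_group_test(
    profiles: pd.DataFrame, groups: pd.Series, bin_name: str | list[str]
) -> tuple[float, str]:
    """Two-sided Mann-Whitney on a bin's mass (or a sum of bins) between
    malignant and benign; returns ``(p, direction of larger mean)``."""
    names = [bin_name] if isinstance(bin_name, str) else list(bin_name)
    unknown = [n for n in names if n not in profiles.columns]
    if unknown:
        raise ValueError(f"unknown bin name(s): {unknown}")
    mass = profiles[names].sum(axis=1)
    groups = groups.reindex(profiles.index)
    x = mass[groups == "malignant"].to_numpy()
    y = mass[groups == "benign"].to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    p = mann_whitney(x, y)[1]
    direction = "malignant" if x.mean() > y.mean() else "benign"
    return p, direction
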