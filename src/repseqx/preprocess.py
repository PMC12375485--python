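"""Clonotype-table refinement: Correct, Decontaminate, FilterNonFunction, DownSample.

The four steps run in that fixed order:

1. **Correct** — merge putative sequencing-error clonotypes into their parent:
   a child is absorbed when it shares V and J gene assignments, has an
   equal-length CDR3 within Hamming distance ``max_mismatch`` (default 2) of
   the parent, and its abundance ratio is strictly below ``merge_ratio``
   (default 0.05) evaluated on pre-merge counts.  Children attach to the
   single highest-count eligible parent (ties broken lexicographically by
   CDR3); merging is not transitive within a pass — chains resolve over
   repeated passes until a fixpoint.
2. **Decontaminate** — drop a clonotype from a sample when the identical key
   occurs in any other sample at >= ``contamination_fold`` (default 20) times
   its relative frequency.  Frequencies are compared, not raw counts, because
   depths differ before downsampling; the comparison is done in exact integer
   arithmetic so the 20-fold boundary is inclusive without float artifacts.
3. **FilterNonFunction** — drop clones whose CDR3 amino-acid sequence
   contains a stop codon ('*') or whose nucleotide length is not divisible
   by 3 (frameshift).
4. **DownSample** — rarefy every sample to a common read depth by sampling
   reads without replacement (multivariate hypergeometric), with a fixed
   seed; clones reduced to zero reads are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .core import RepertoireSample, RepertoireSet, recompute_frequencies

__all__ = [
    "PreprocessConfig",
    "correct_clonotypes",
    "decontaminate",
    "filter_nonfunctional",
    "downsample",
    "preprocess_set",
]


@dataclass
class PreprocessConfig:
    max_mismatch: int = 2
    merge_ratio: float = 0.05
    contamination_fold: float = 20.0
    downsample_depth: int | str = "auto-min"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if not 0.0 < self.merge_ratio < 1.0:
            raise ValueError("merge_ratio must lie in (0, 1)")
        if self.contamination_fold <= 1.0:
            raise ValueError("contamination_fold must exceed 1")


def _hamming_within(a: str, b: str, limit: int) -> bool:
    """True when equal-length a and b differ at <= limit positions."""
    if len(a) != len(b):
        return False
    mism = 0
    for ca, cb in zip(a, b):
        if ca != cb:
            mism += 1
            if mism > limit:
                return False
    return True


def correct_clonotypes(
    sample: RepertoireSample, config: PreprocessConfig | None = None
) -> tuple[RepertoireSample, list[dict]]:
    """Merge low-abundance near-duplicate clonotypes into their parents.

    Returns ``(sample, merge_log)``; the log records one entry per absorbed
    child with its parent key and transferred count.  Total reads are
    conserved and the unique-clonotype count never increases.
    """
    config = config or PreprocessConfig()
    sample = sample.copy()
    sample.table = sample.table.reset_index(drop=True)
    ratio = Fraction(str(config.merge_ratio))
    log: list[dict] = []

    while True:
        t = sample.table
        counts = t["read_count"].to_numpy()
        nts = t["cdr3_nt"].to_numpy()
        # candidate parents/children can only pair within identical
        # (V, J, CDR3 length) strata
        lengths = t["cdr3_nt"].str.len()
        strata = t.groupby(
            [t["v_gene"], t["j_gene"], lengths], sort=False
        ).indices

        assignments: dict[int, int] = {}  # child row position -> parent row position
        for idx in strata.values():
            if len(idx) < 2:
                continue
            # descending count, ties lexicographic by cdr3_nt
            order = sorted(idx, key=lambda i: (-counts[i], nts[i]))
            for child in order:
                c_count = int(counts[child])
                for parent in order:
                    if parent == child:
                        continue
                    p_count = int(counts[parent])
                    # strict ratio < merge_ratio on pre-merge counts, exact
                    # rational comparison; parents are in descending count
                    # order, so once the ratio test fails it fails for all
                    # remaining candidates
                    if c_count * ratio.denominator >= ratio.numerator * p_count:
                        break
                    if _hamming_within(nts[child], nts[parent], config.max_mismatch):
                        assignments[child] = parent
                        break

        # defer children whose chosen parent is itself a child this pass
        assignments = {c: p for c, p in assignments.items() if p not in assignments}
        if not assignments:
            break

        gains: dict[int, int] = {}
        for child, parent in assignments.items():
            gains[parent] = gains.get(parent, 0) + int(counts[child])
            log.append(
                {
                    "child": (t.iloc[child]["v_gene"], nts[child], t.iloc[child]["j_gene"]),
                    "parent": (t.iloc[parent]["v_gene"], nts[parent], t.iloc[parent]["j_gene"]),
                    "count": int(counts[child]),
                }
            )
        new_counts = counts.copy()
        for parent, gain in gains.items():
            new_counts[parent] += gain
        keep = np.ones(len(t), dtype=bool)
        keep[list(assignments)] = False
        t = t.assign(read_count=new_counts)[keep].reset_index(drop=True)
        sample.table = t

    recompute_frequencies(sample)
    return sample, log


def decontaminate(
    rep_set: RepertoireSet, config: PreprocessConfig | None = None
) -> tuple[RepertoireSet, list[dict]]:
    """Remove cross-sample contaminant clonotypes.

    A clonotype is removed from sample *s* iff some other sample carries the
    identical (V, CDR3 nt, J) key at a relative frequency >=
    ``contamination_fold`` times its frequency in *s* (boundary inclusive).
    Returns ``(set, removal_log)``.
    """
    config = config or PreprocessConfig()
    if len(rep_set) < 2:
        warnings.warn("decontaminate: single-sample set, nothing to compare against")
        return rep_set.copy(), []
    fold = Fraction(str(config.contamination_fold))

    rep_set = rep_set.copy()
    totals = [s.total_reads for s in rep_set]
    # key -> list of (sample position, count)
    occurrences: dict[tuple, list[tuple[int, int]]] = {}
    for pos, s in enumerate(rep_set):
        t = s.table
        for key, count in zip(
            zip(t["v_gene"], t["cdr3_nt"], t["j_gene"]), t["read_count"]
        ):
            occurrences.setdefault(key, []).append((pos, int(count)))

    removals: dict[int, set[tuple]] = {pos: set() for pos in range(len(rep_set))}
    log: list[dict] = []
    for key, occ in occurrences.items():
        if len(occ) < 2:
            continue
        for pos, count in occ:
            for other_pos, other_count in occ:
                if other_pos == pos:
                    continue
                # other_count/T_other >= fold * count/T_pos, cross-multiplied
                lhs = other_count * totals[pos] * fold.denominator
                rhs = fold.numerator * count * totals[other_pos]
                if lhs >= rhs:
                    removals[pos].add(key)
                    log.append(
                        {
                            "sample_id": rep_set.samples[pos].sample_id,
                            "key": key,
                            "donor_id": rep_set.samples[other_pos].sample_id,
                        }
                    )
                    break

    for pos, s in enumerate(rep_set.samples):
        if not removals[pos]:
            continue
        t = s.table
        keys = list(zip(t["v_gene"], t["cdr3_nt"], t["j_gene"]))
        keep = np.array([k not in removals[pos] for k in keys])
        if not keep.any():
            raise ValueError(
                f"sample {s.sample_id}: decontamination removed every clonotype"
            )
        s.table = t[keep].reset_index(drop=True)
        recompute_frequencies(s)
    return rep_set, log


def filter_nonfunctional(
    sample: RepertoireSample,
) -> tuple[RepertoireSample, list[dict]]:
    """Drop stop-codon and frameshifted (out-of-frame) clonotypes."""
    sample = sample.copy()
    t = sample.table
    nonfunctional = t["cdr3_aa"].str.contains(r"\*", regex=True) | (
        t["cdr3_nt"].str.len() % 3 != 0
    )
    log = [
        {"key": (row.v_gene, row.cdr3_nt, row.j_gene), "count": int(row.read_count)}
        for row in t[nonfunctional].itertuples(index=False)
    ]
    if nonfunctional.all():
        raise ValueError(
            f"sample {sample.sample_id}: no functional clonotypes remain"
        )
    sample.table = t[~nonfunctional].reset_index(drop=True)
    recompute_frequencies(sample)
    return sample, log


def downsample(
    rep_set: RepertoireSet, config: PreprocessConfig | None = None
) -> RepertoireSet:
    """Rarefy all samples to a common depth without replacement.

    ``downsample_depth`` is an explicit read count or ``"auto-min"`` (the
    minimum per-sample total).  Per-clone subsampled counts follow the
    multivariate hypergeometric distribution; zero-count clones are dropped;
    the draw is deterministic given ``config.seed``.
    """
    config = config or PreprocessConfig()
    totals = {s.sample_id: s.total_reads for s in rep_set}
    if config.downsample_depth == "auto-min":
        depth = min(totals.values())
    else:
        depth = int(config.downsample_depth)
        for sid, total in totals.items():
            if depth > total:
                raise ValueError(
                    f"downsample depth {depth} exceeds total reads of sample {sid} ({total})"
                )
    rng = np.random.default_rng(config.seed)
    out = []
    for s in rep_set:
        s = s.copy()
        if s.total_reads > depth:
            counts = s.table["read_count"].to_numpy(dtype=np.int64)
            new = rng.multivariate_hypergeometric(counts, depth, method="marginals")
            s.table = s.table.assign(read_count=new)
            s.table = s.table[s.table["read_count"] > 0].reset_index(drop=True)
        recompute_frequencies(s)
        out.append(s)
    return RepertoireSet(out)


@dataclass
class PreprocessLogs:
    merges: dict[str, list] = field(default_factory=dict)
    contaminants: list = field(default_factory=list)
    nonfunctional: dict[str, list] = field(default_factory=dict)
    depth: int | None = None


def preprocess_set(
    rep_set: RepertoireSet, config: PreprocessConfig | None = None
) -> tuple[RepertoireSet, PreprocessLogs]:
    """Run the full Correct -> Decontaminate -> FilterNonFunction -> DownSample
    pipeline, returning the refined set and per-step logs."""
    config = config or PreprocessConfig()
    logs = PreprocessLogs()
    corrected = []
    for s in rep_set:
        c, merge_log = correct_clonotypes(s, config)
        logs.merges[s.sample_id] = merge_log
        corrected.append(c)
    current = RepertoireSet(corrected)
    current, logs.contaminants = decontaminate(current, config)
    filtered = []
    for s in current:
        f, nf_log = filter_nonfunctional(s)
        logs.nonfunctional[s.sample_id] = nf_log
        filtered.append(f)
    current = RepertoireSet(filtered)
    current = downsample(current, config)
    logs.depth = current.samples[0].total_reads if len(current) else None
    return current, logs
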