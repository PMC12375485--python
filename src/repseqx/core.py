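"""Domain types and AIRR Rearrangement TSV I/O shared by every pipeline stage.

A clonotype is a unique receptor rearrangement keyed by ``(v_gene, cdr3_nt,
j_gene)``; a :class:`RepertoireSample` is one subject's clonotype table plus
clinical metadata; a :class:`RepertoireSet` is a cohort of samples of the same
receptor chain (TCR beta or BCR heavy).

Clonotype tables are carried as pandas DataFrames with the canonical columns
``v_gene, cdr3_nt, cdr3_aa, j_gene, read_count, frequency``.  Frequencies are
always recomputed from read counts, never trusted from file, because
correction, decontamination and downsampling all invalidate stored values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "TABLE_COLUMNS",
    "AIRR_COLUMNS",
    "ClonotypeRecord",
    "RepertoireSample",
    "RepertoireSet",
    "AbundanceVector",
    "FormatError",
    "clone_key",
    "strip_allele",
    "translate_cdr3",
    "read_airr_tsv",
    "write_airr_tsv",
    "read_metadata",
    "read_repertoire_set",
    "write_repertoire_set",
    "recompute_frequencies",
    "table_from_records",
]

#: canonical in-memory clonotype-table columns
TABLE_COLUMNS = ["v_gene", "cdr3_nt", "cdr3_aa", "j_gene", "read_count", "frequency"]

#: required columns of an AIRR Rearrangement TSV carrier file
AIRR_COLUMNS = ["junction", "junction_aa", "v_call", "j_call", "duplicate_count"]

_NT_ALPHABET = frozenset("ACGT")


class FormatError(ValueError):
    """A malformed clonotype table or metadata file."""


def strip_allele(call: str) -> str:
    """Reduce an allele-level gene call (``TRBV11-3*01``) to the gene name."""
    return call.split("*", 1)[0].strip()


def translate_cdr3(nt: str) -> str:
    """Translate the complete codons of a CDR3 nucleotide sequence.

    Trailing bases of an out-of-frame (frameshifted) junction are ignored;
    stop codons appear as ``'*'``.
    """
    trimmed = nt[: 3 * (len(nt) // 3)]
    if not trimmed:
        return ""
    return str(Seq(trimmed).translate())


def clone_key(v_gene: str, cdr3_nt: str, j_gene: str) -> tuple[str, str, str]:
    """Clonotype identity key (V + CDR3 nucleotide + J)."""
    return (v_gene, cdr3_nt, j_gene)


@dataclass(frozen=True)
class ClonotypeRecord:
    """One clone: CDR3 at nucleotide and amino-acid level, gene calls, abundance."""

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    read_count: int
    frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must lie in [0, 1]")
        if set(self.cdr3_nt) - _NT_ALPHABET:
            raise ValueError(f"cdr3_nt contains non-ACGT characters: {self.cdr3_nt!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return clone_key(self.v_gene, self.cdr3_nt, self.j_gene)

    @property
    def is_functional(self) -> bool:
        """In-frame junction with no stop codon."""
        return "*" not in self.cdr3_aa and len(self.cdr3_nt) % 3 == 0


def table_from_records(records: Iterable[ClonotypeRecord]) -> pd.DataFrame:
    rows = [
        (r.v_gene, r.cdr3_nt, r.cdr3_aa, r.j_gene, r.read_count, r.frequency)
        for r in records
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


@dataclass
class RepertoireSample:
    """One subject's clonotype table plus clinical metadata.

    Invariants (checked by :meth:`validate`): clonotype keys unique, counts
    non-negative, frequencies sum to 1 within 1e-9 of the counts they derive
    from.
    """

    sample_id: str
    table: pd.DataFrame
    group: str | None = None
    age: float | None = None
    receptor: str = "TCR"
    gravida: int | None = None
    para: int | None = None
    abortus: int | None = None

    @property
    def total_reads(self) -> int:
        return int(self.table["read_count"].sum())

    @property
    def n_clonotypes(self) -> int:
        return len(self.table)

    def keys(self) -> pd.Index:
        t = self.table
        return pd.MultiIndex.from_arrays([t["v_gene"], t["cdr3_nt"], t["j_gene"]])

    def records(self) -> Iterator[ClonotypeRecord]:
        for row in self.table.itertuples(index=False):
            yield ClonotypeRecord(
                cdr3_nt=row.cdr3_nt,
                cdr3_aa=row.cdr3_aa,
                v_gene=row.v_gene,
                j_gene=row.j_gene,
                read_count=int(row.read_count),
                frequency=float(row.frequency),
            )

    def copy(self) -> "RepertoireSample":
        return dataclasses.replace(self, table=self.table.copy())

    def validate(self) -> None:
        t = self.table
        if list(t.columns) != TABLE_COLUMNS:
            raise FormatError(f"unexpected table columns: {list(t.columns)}")
        if len(t) == 0:
            raise FormatError(f"sample {self.sample_id}: empty clonotype table")
        if (t["read_count"] < 0).any():
            raise ValueError(f"sample {self.sample_id}: negative read counts")
        if t.duplicated(subset=["v_gene", "cdr3_nt", "j_gene"]).any():
            raise ValueError(f"sample {self.sample_id}: duplicate clonotype keys")
        total = self.total_reads
        if total <= 0:
            raise ValueError(f"sample {self.sample_id}: total_reads must be positive")
        if abs(t["frequency"].sum() - 1.0) > 1e-9:
            raise ValueError(f"sample {self.sample_id}: frequencies do not sum to 1")


@dataclass
class RepertoireSet:
    """A cohort of repertoire samples sharing one receptor chain."""

    samples: list[RepertoireSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique within a RepertoireSet")
        receptors = {s.receptor for s in self.samples}
        if len(receptors) > 1:
            raise ValueError(f"mixed receptor types in one set: {sorted(receptors)}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[RepertoireSample]:
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> RepertoireSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def groups(self) -> pd.Series:
        return pd.Series(
            [s.group for s in self.samples], index=self.sample_ids, name="group"
        )

    def group_sizes(self) -> dict[str, int]:
        return self.groups.value_counts().to_dict()

    def copy(self) -> "RepertoireSet":
        return RepertoireSet([s.copy() for s in self.samples])


@dataclass(frozen=True)
class AbundanceVector:
    """Clone-abundance vector: the raw material of all three diversity indices.

    ``counts`` are integer clone read counts (all positive); ``proportions``
    are the relative abundances p_i (sum to 1); ``s_obs`` the observed clone
    count; ``a1``/``a2`` the singleton/doubleton counts used by Chao1.
    """

    counts: np.ndarray
    proportions: np.ndarray

    @classmethod
    def from_counts(cls, counts: Sequence[int] | np.ndarray) -> "AbundanceVector":
        arr = np.asarray(counts)
        if arr.size == 0:
            raise ValueError("empty abundance vector")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("abundance counts must be integers")
            arr = np.round(arr).astype(np.int64)
        if (arr <= 0).any():
            raise ValueError("abundance counts must be positive")
        total = arr.sum()
        return cls(counts=arr.astype(np.int64), proportions=arr / total)

    @classmethod
    def from_proportions(cls, p: Sequence[float] | np.ndarray) -> "AbundanceVector":
        """Build from relative abundances only (Chao1 unavailable: no counts)."""
        arr = np.asarray(p, dtype=float)
        if arr.size == 0:
            raise ValueError("empty abundance vector")
        if (arr <= 0).any():
            raise ValueError("proportions must be positive")
        if abs(arr.sum() - 1.0) > 1e-6:
            raise ValueError("proportions must sum to 1")
        return cls(counts=np.array([], dtype=np.int64), proportions=arr / arr.sum())

    @classmethod
    def from_sample(cls, sample: RepertoireSample) -> "AbundanceVector":
        return cls.from_counts(sample.table["read_count"].to_numpy())

    @property
    def n(self) -> int:
        return int(self.proportions.size)

    @property
    def s_obs(self) -> int:
        return self.n

    @property
    def a1(self) -> int:
        return int((self.counts == 1).sum())

    @property
    def a2(self) -> int:
        return int((self.counts == 2).sum())


# ---------------------------------------------------------------------------
# I/O


def recompute_frequencies(sample: RepertoireSample) -> RepertoireSample:
    """Set ``frequency = read_count / total_reads`` in place; returns the sample."""
    total = sample.table["read_count"].sum()
    if total <= 0:
        raise ValueError(f"sample {sample.sample_id}: total read count is zero")
    sample.table["frequency"] = sample.table["read_count"] / total
    return sample


def _aggregate_by_key(table: pd.DataFrame) -> pd.DataFrame:
    """Sum read counts over duplicate (v_gene, cdr3_nt, j_gene) keys."""
    grouped = (
        table.groupby(["v_gene", "cdr3_nt", "j_gene"], sort=False, as_index=False)
        .agg(cdr3_aa=("cdr3_aa", "first"), read_count=("read_count", "sum"))
    )
    grouped["frequency"] = 0.0
    return grouped[TABLE_COLUMNS]


def read_airr_tsv(
    path: str | Path, metadata: Mapping[str, object] | None = None
) -> RepertoireSample:
    """Read one sample's clonotype table from an AIRR Rearrangement TSV.

    Requires the columns ``junction, junction_aa, v_call, j_call,
    duplicate_count``.  Allele suffixes on gene calls are stripped to
    gene-level names, duplicate identity keys are aggregated by summing
    counts, and frequencies are recomputed from counts.

    ``metadata`` may carry ``sample_id, group, age, receptor, gravida, para,
    abortus``; absent fields default to None.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"junction": str, "junction_aa": str})
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: empty clonotype table")
    table = pd.DataFrame(
        {
            "v_gene": df["v_call"].astype(str).map(strip_allele),
            "cdr3_nt": df["junction"].astype(str),
            "cdr3_aa": df["junction_aa"].astype(str),
            "j_gene": df["j_call"].astype(str).map(strip_allele),
            "read_count": df["duplicate_count"].astype(np.int64),
            "frequency": 0.0,
        }
    )
    table = _aggregate_by_key(table)
    meta = dict(metadata or {})
    sample = RepertoireSample(
        sample_id=str(meta.get("sample_id", path.stem)),
        table=table,
        group=meta.get("group"),
        age=None if meta.get("age") is None else float(meta["age"]),
        receptor=str(meta.get("receptor", "TCR")),
        gravida=_opt_int(meta.get("gravida")),
        para=_opt_int(meta.get("para")),
        abortus=_opt_int(meta.get("abortus")),
    )
    recompute_frequencies(sample)
    sample.validate()
    return sample


def _opt_int(value: object) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return int(value)


def write_airr_tsv(sample: RepertoireSample, path: str | Path) -> None:
    """Write a sample as an AIRR Rearrangement TSV (lossless round trip on
    gene calls, CDR3 sequences and read counts)."""
    if len(sample.table) == 0:
        raise ValueError(f"sample {sample.sample_id}: refusing to write empty table")
    out = pd.DataFrame(
        {
            "junction": sample.table["cdr3_nt"],
            "junction_aa": sample.table["cdr3_aa"],
            "v_call": sample.table["v_gene"],
            "j_call": sample.table["j_gene"],
            "duplicate_count": sample.table["read_count"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


METADATA_COLUMNS = ["sample_id", "group", "age", "gravida", "para", "abortus"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample-metadata CSV: sample_id, group, age, gravida, para, abortus."""
    meta = pd.read_csv(path)
    missing = [c for c in ("sample_id", "group") if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing column(s) {missing}")
    return meta


def read_repertoire_set(
    directory: str | Path, metadata_path: str | Path, receptor: str = "TCR"
) -> RepertoireSet:
    """Load ``<sample_id>.tsv`` per metadata row from ``directory``."""
    directory = Path(directory)
    meta = read_metadata(metadata_path)
    samples = []
    for row in meta.to_dict("records"):
        row.setdefault("receptor", receptor)
        samples.append(read_airr_tsv(directory / f"{row['sample_id']}.tsv", row))
    return RepertoireSet(samples)


def write_repertoire_set(
    rep_set: RepertoireSet, directory: str | Path, metadata_name: str = "metadata.csv"
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in rep_set:
        write_airr_tsv(s, directory / f"{s.sample_id}.tsv")
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "age": s.age,
                "gravida": s.gravida,
                "para": s.para,
                "abortus": s.abortus,
                "receptor": s.receptor,
            }
        )
    meta_path = directory / metadata_name
    pd.DataFrame(rows).to_csv(meta_path, index=False)
    return meta_path
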