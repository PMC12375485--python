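"""Synthetic AIRR-seq cohort generator with a ground-truth ledger.

Emulates the statistical structure a benign-vs-malignant ovarian-tumour
repertoire comparison rests on, so every downstream stage is testable
without patient data:

* heavy-tailed (discrete power-law) clone abundances, with the malignant
  group given lower richness, a steeper tail and a handful of forced
  hyper-expanded clones (frequency > 1%);
* group-shifted V-J usage: per-group joint V-J profiles with selected pairs
  multiplied up or down in the malignant group, plus per-sample Dirichlet
  dispersion (larger in the malignant group, so inter-sample usage
  correlations are lower there);
* a shared pool of public clonotypes drawn more heavily by benign samples;
* low-frequency sequencing-error variants (1-2 nt from a parent, same V/J,
  abundance ratio < 0.05) for the Correct step to recover;
* cross-sample contaminants planted at a known fold-ratio for the
  Decontaminate step;
* stop-codon / frameshift clones for the FilterNonFunction step;
* an age covariate: sample richness scales as ``exp(slope * (age - 45))``
  and malignant patients are drawn older.

One global RNG is seeded per run and all sub-steps draw from it in a fixed,
documented order (pool, then samples in benign-before-malignant order, then
per-sample error injection and non-functional injection, then set-level
contamination), so runs are byte-reproducible.  Every injected truth is
recorded in the returned ledger.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    TABLE_COLUMNS,
    RepertoireSample,
    RepertoireSet,
    recompute_frequencies,
)

__all__ = [
    "SimulationConfig",
    "simulate_repertoire_set",
    "inject_sequencing_errors",
    "inject_contamination",
    "inject_nonfunctional",
    "random_cdr3_set",
    "DEFAULT_TRBV",
    "DEFAULT_TRBJ",
    "DEFAULT_USAGE_SHIFT",
]

DEFAULT_TRBV = [
    "TRBV2", "TRBV4-1", "TRBV5-1", "TRBV5-4", "TRBV6-1", "TRBV6-2", "TRBV6-4",
    "TRBV7-2", "TRBV7-7", "TRBV7-9", "TRBV9", "TRBV10-3", "TRBV11-2",
    "TRBV11-3", "TRBV12-3", "TRBV15", "TRBV18", "TRBV19", "TRBV20-1",
    "TRBV24-1", "TRBV25-1", "TRBV27", "TRBV28", "TRBV29-1", "TRBV30",
]
DEFAULT_TRBJ = [
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6",
    "TRBJ2-7",
]

#: V-J pairs shifted in the malignant group (multiplier on the joint
#: probability; >1 = malignant-enriched, <1 = benign-enriched).  Pair names
#: follow segments recurrently reported as tumour-associated.
DEFAULT_USAGE_SHIFT: dict[tuple[str, str], float] = {
    ("TRBV11-3", "TRBJ1-2"): 5.0,
    ("TRBV12-3", "TRBJ2-5"): 5.0,
    ("TRBV6-1", "TRBJ1-3"): 5.0,
    ("TRBV7-9", "TRBJ1-1"): 5.0,
    ("TRBV27", "TRBJ1-3"): 0.2,
    ("TRBV28", "TRBJ1-6"): 0.2,
}

# sense codons (the 61 non-stop codons) and their amino acids
_BASES = "TCAG"
_AA_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
_ALL_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
SENSE_CODONS = np.array(
    [c for c, aa in zip(_ALL_CODONS, _AA_TABLE) if aa != "*"]
)
SENSE_AAS = np.array(
    [aa for aa in _AA_TABLE if aa != "*"]
)
STOP_CODONS = ["TAA", "TAG", "TGA"]
CODON_TO_AA = dict(zip(_ALL_CODONS, _AA_TABLE))


def _translate_fast(nt: str) -> str:
    return "".join(
        CODON_TO_AA[nt[i : i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3)
    )


@dataclass
class SimulationConfig:
    """Study conditions of the emulated cohort.

    Defaults mirror the comparison of interest: 12 benign vs 8 malignant
    samples, malignant repertoires with ~3x lower richness, a steeper
    abundance tail and forced hyper-expanded clones, six planted V-J usage
    shifts, and ~2% of reads emitted as sequencing-error variants.
    """

    seed: int = 0
    n_benign: int = 12
    n_malignant: int = 8
    receptor: str = "TCR"
    richness_benign: int = 5000
    richness_malignant: int = 1500
    zipf_exponent_benign: float = 0.8
    zipf_exponent_malignant: float = 1.2
    exponent_jitter: float = 0.05
    n_hyperexpanded_malignant: int = 5
    hyper_freq_range: tuple[float, float] = (0.012, 0.05)
    depth_range: tuple[int, int] = (30_000, 60_000)
    v_genes: list[str] = field(default_factory=lambda: list(DEFAULT_TRBV))
    j_genes: list[str] = field(default_factory=lambda: list(DEFAULT_TRBJ))
    usage_shift: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_USAGE_SHIFT)
    )
    usage_concentration_benign: float = 1500.0
    usage_concentration_malignant: float = 400.0
    public_pool_size: int = 800
    public_frac_benign: float = 0.08
    public_frac_malignant: float = 0.03
    error_rate: float = 0.02
    contamination_rate: float = 0.002
    contamination_fold_range: tuple[float, float] = (20.0, 80.0)
    nonfunctional_rate: float = 0.05
    age_range_benign: tuple[float, float] = (25.0, 60.0)
    age_range_malignant: tuple[float, float] = (40.0, 70.0)
    age_richness_slope: float = -0.02
    cdr3_codon_range: tuple[int, int] = (8, 20)  # 24-60 nt in multiples of 3

    def __post_init__(self) -> None:
        for rate in (
            self.error_rate,
            self.contamination_rate,
            self.nonfunctional_rate,
            self.public_frac_benign,
            self.public_frac_malignant,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_benign < 1 or self.n_malignant < 1:
            raise ValueError("sample counts must be >= 1")
        if self.zipf_exponent_benign <= 0 or self.zipf_exponent_malignant <= 0:
            raise ValueError("abundance exponents must be positive")
        capacity = 4 ** (3 * self.cdr3_codon_range[0])
        if max(self.richness_benign, self.richness_malignant) > 0.01 * capacity:
            raise ValueError("requested richness exceeds CDR3 sequence capacity")


def _key(v: str, nt: str, j: str) -> str:
    return f"{v}|{nt}|{j}"


def random_cdr3_set(
    n: int,
    rng: np.random.Generator,
    codon_range: tuple[int, int] = (8, 20),
    exclude: set[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Generate ``n`` distinct functional CDR3s (nt, aa) from sense codons."""
    exclude = set(exclude or ())
    nts: list[str] = []
    aas: list[str] = []
    seen = set(exclude)
    while len(nts) < n:
        batch = n - len(nts)
        lengths = rng.integers(codon_range[0], codon_range[1] + 1, size=batch)
        # vectorised join: draw an (m, L) codon-index matrix per length class
        # and reinterpret the fixed-width unicode block as one string per row
        for L in np.unique(lengths):
            m = int((lengths == L).sum())
            idx = rng.integers(0, len(SENSE_CODONS), size=(m, int(L)))
            nt_batch = np.ascontiguousarray(SENSE_CODONS[idx]).view(f"U{3 * L}").ravel()
            aa_batch = np.ascontiguousarray(SENSE_AAS[idx]).view(f"U{L}").ravel()
            for nt, aa in zip(nt_batch, aa_batch):
                if nt in seen:
                    continue
                seen.add(nt)
                nts.append(nt)
                aas.append(aa)
    return nts, aas


def _group_profiles(config: SimulationConfig, rng: np.random.Generator):
    """Joint V-J usage probability vectors for each group."""
    n_v, n_j = len(config.v_genes), len(config.j_genes)
    p_v = rng.dirichlet(np.full(n_v, 5.0))
    p_j = rng.dirichlet(np.full(n_j, 5.0))
    joint_benign = np.outer(p_v, p_j).ravel()
    joint_malignant = joint_benign.copy()
    pair_index = {
        (v, j): i * n_j + k
        for i, v in enumerate(config.v_genes)
        for k, j in enumerate(config.j_genes)
    }
    for pair, mult in config.usage_shift.items():
        if pair not in pair_index:
            raise ValueError(f"usage_shift pair {pair} not in gene lists")
        joint_malignant[pair_index[pair]] *= mult
    joint_benign /= joint_benign.sum()
    joint_malignant /= joint_malignant.sum()
    return joint_benign, joint_malignant


def _make_sample(
    sample_id: str,
    group: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    pool: pd.DataFrame,
    joint_prob: np.ndarray,
    concentration: float,
) -> tuple[RepertoireSample, dict]:
    n_v, n_j = len(config.v_genes), len(config.j_genes)
    if group == "benign":
        age = float(rng.uniform(*config.age_range_benign))
        base_richness = config.richness_benign
        exponent = config.zipf_exponent_benign
        public_frac = config.public_frac_benign
        n_hyper = 0
    else:
        age = float(rng.uniform(*config.age_range_malignant))
        base_richness = config.richness_malignant
        exponent = config.zipf_exponent_malignant
        public_frac = config.public_frac_malignant
        n_hyper = config.n_hyperexpanded_malignant

    richness = max(
        50, int(round(base_richness * np.exp(config.age_richness_slope * (age - 45.0))))
    )
    n_public = min(int(round(public_frac * richness)), len(pool))
    n_private = richness - n_public

    pub_idx = rng.choice(len(pool), size=n_public, replace=False)
    pub = pool.iloc[pub_idx]
    nts, aas = random_cdr3_set(
        n_private, rng, config.cdr3_codon_range, exclude=set(pub["cdr3_nt"])
    )
    # per-sample V-J usage with group-level mean and Dirichlet dispersion
    sample_vj = rng.dirichlet(np.maximum(concentration * joint_prob, 1e-6))
    vj_idx = rng.choice(n_v * n_j, size=n_private, p=sample_vj)
    v = [config.v_genes[i // n_j] for i in vj_idx] + list(pub["v_gene"])
    j = [config.j_genes[i % n_j] for i in vj_idx] + list(pub["j_gene"])
    nt = nts + list(pub["cdr3_nt"])
    aa = aas + list(pub["cdr3_aa"])

    # Zipf abundance profile, randomly assigned to clones
    s_i = exponent + float(rng.uniform(-config.exponent_jitter, config.exponent_jitter))
    ranks = np.arange(1, richness + 1, dtype=float)
    zipf = ranks ** (-s_i)
    zipf /= zipf.sum()
    probs = zipf[rng.permutation(richness)]
    if n_hyper > 0:
        # forced hyper-expanded clones model tumour-antigen-driven
        # expansions: they carry the malignant-enriched V-J pairs
        # (round-robin), so clonal dominance and the usage shift coincide
        hyper_idx = rng.choice(n_private, size=min(n_hyper, n_private), replace=False)
        hyper = rng.uniform(*config.hyper_freq_range, size=hyper_idx.size)
        probs[hyper_idx] = 0.0
        probs *= (1.0 - hyper.sum()) / probs.sum()
        probs[hyper_idx] = hyper
        up_pairs = [pair for pair, mult in config.usage_shift.items() if mult > 1]
        for k, ci in enumerate(hyper_idx):
            if up_pairs:
                v[ci], j[ci] = up_pairs[k % len(up_pairs)]

    depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
    counts = rng.multinomial(depth, probs)
    observed = counts > 0

    table = pd.DataFrame(
        {
            "v_gene": np.array(v)[observed],
            "cdr3_nt": np.array(nt)[observed],
            "cdr3_aa": np.array(aa)[observed],
            "j_gene": np.array(j)[observed],
            "read_count": counts[observed].astype(np.int64),
            "frequency": 0.0,
        }
    )[TABLE_COLUMNS]
    sample = RepertoireSample(
        sample_id=sample_id,
        table=table,
        group=group,
        age=age,
        receptor=config.receptor,
        gravida=int(rng.integers(0, 5)),
        para=int(rng.integers(0, 4)),
        abortus=int(rng.integers(0, 3)),
    )
    recompute_frequencies(sample)
    info = {
        "group": group,
        "age": age,
        "target_richness": richness,
        "depth": depth,
        "zipf_exponent": s_i,
        "n_public": int(observed[n_private:].sum()),
    }
    return sample, info


def inject_sequencing_errors(
    sample: RepertoireSample, rate: float, seed: int
) -> tuple[RepertoireSample, dict[str, str]]:
    """Move ~``rate`` of a sample's reads into 1-2 nt error variants.

    Each variant shares V/J with its parent, differs by 1-2 substitutions at
    equal length, and carries strictly less than 5% of the parent's
    post-injection count.  Total reads are conserved.  Returns the modified
    sample and a ``variant key -> parent key`` map.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("error rate must lie in [0, 1)")
    sample = sample.copy()
    if rate == 0.0:
        return sample, {}
    rng = np.random.default_rng(seed)
    t = sample.table.reset_index(drop=True)
    budget = int(round(rate * t["read_count"].sum()))
    existing = set(t["cdr3_nt"])
    counts = t["read_count"].to_numpy().copy()
    nt_arr = t["cdr3_nt"].to_numpy(dtype=object)
    v_arr = t["v_gene"].to_numpy(dtype=object)
    j_arr = t["j_gene"].to_numpy(dtype=object)
    order = np.argsort(-counts, kind="stable")
    new_rows = []
    variant_map: dict[str, str] = {}
    bases = "ACGT"
    for idx in order:
        if budget <= 0:
            break
        parent_count = int(counts[idx])
        if parent_count < 22:  # no admissible variant count below this
            break
        u = float(rng.uniform(0.01, 0.045))
        v_count = int(u * parent_count)
        # keep ratio strictly < 0.05 against the parent's remaining count
        v_count = min(v_count, (parent_count - 1) // 21, budget)
        if v_count < 1:
            continue
        parent_nt = nt_arr[idx]
        variant_nt = None
        for _ in range(8):
            n_mut = int(rng.integers(1, 3))
            positions = rng.choice(len(parent_nt), size=n_mut, replace=False)
            chars = list(parent_nt)
            for p in positions:
                choices = [b for b in bases if b != chars[p]]
                chars[p] = choices[rng.integers(0, 3)]
            cand = "".join(chars)
            if cand not in existing:
                variant_nt = cand
                break
        if variant_nt is None:
            continue
        existing.add(variant_nt)
        counts[idx] = parent_count - v_count
        budget -= v_count
        vg, jg = v_arr[idx], j_arr[idx]
        new_rows.append(
            {
                "v_gene": vg,
                "cdr3_nt": variant_nt,
                "cdr3_aa": _translate_fast(variant_nt),
                "j_gene": jg,
                "read_count": v_count,
                "frequency": 0.0,
            }
        )
        variant_map[_key(vg, variant_nt, jg)] = _key(vg, parent_nt, jg)
    t = t.assign(read_count=counts)
    if new_rows:
        t = pd.concat([t, pd.DataFrame(new_rows)], ignore_index=True)
    sample.table = t[TABLE_COLUMNS]
    recompute_frequencies(sample)
    return sample, variant_map


def inject_contamination(
    rep_set: RepertoireSet,
    rate: float,
    seed: int,
    fold_range: tuple[float, float] = (20.0, 80.0),
    exclude_donor_keys: set[str] | None = None,
) -> tuple[RepertoireSet, list[dict]]:
    """Copy high-frequency clones across samples at a >= ``fold_range[0]``
    frequency ratio (donor over recipient).

    ``exclude_donor_keys`` bars clones (e.g. planted error variants, which
    an error-correction step would absorb) from acting as donors.  Returns
    the modified set and a contaminant list with realized ratios.
    """
    if len(rep_set) < 2:
        raise ValueError("contamination needs at least two samples")
    rep_set = rep_set.copy()
    if rate == 0.0:
        return rep_set, []
    rng = np.random.default_rng(seed)
    exclude_donor_keys = exclude_donor_keys or set()
    samples = rep_set.samples
    additions: list[list[dict]] = [[] for _ in samples]
    ledger: list[dict] = []
    donor_tops = []
    for s in samples:
        top = s.table.nlargest(60, "read_count")
        if exclude_donor_keys:
            keep = [
                _key(v, nt, j) not in exclude_donor_keys
                for v, nt, j in zip(top["v_gene"], top["cdr3_nt"], top["j_gene"])
            ]
            top = top[np.asarray(keep)]
        donor_tops.append(
            list(
                zip(
                    top["v_gene"],
                    top["cdr3_nt"],
                    top["cdr3_aa"],
                    top["j_gene"],
                    top["read_count"] / s.total_reads,
                )
            )
        )
    for r_pos, recipient in enumerate(samples):
        n_contam = max(1, int(round(rate * recipient.n_clonotypes)))
        recip_keys = set(
            zip(
                recipient.table["v_gene"],
                recipient.table["cdr3_nt"],
                recipient.table["j_gene"],
            )
        )
        t_recip = recipient.total_reads
        placed = 0
        attempts = 0
        while placed < n_contam and attempts < 10 * n_contam:
            attempts += 1
            d_pos = int(rng.integers(0, len(samples)))
            if d_pos == r_pos:
                continue
            vg, nt, aa, jg, f_d = donor_tops[d_pos][
                int(rng.integers(0, len(donor_tops[d_pos])))
            ]
            if (vg, nt, jg) in recip_keys:
                continue
            target_ratio = float(rng.uniform(*fold_range))
            c = int(f_d * t_recip / target_ratio)
            if c < 1:
                continue
            recip_keys.add((vg, nt, jg))
            additions[r_pos].append(
                {
                    "v_gene": vg,
                    "cdr3_nt": nt,
                    "cdr3_aa": aa,
                    "j_gene": jg,
                    "read_count": c,
                    "frequency": 0.0,
                }
            )
            ledger.append(
                {
                    "sample_id": recipient.sample_id,
                    "donor_id": samples[d_pos].sample_id,
                    "key": _key(vg, nt, jg),
                    "donor_frequency": f_d,
                    "injected_count": c,
                }
            )
            placed += 1
    for s, rows in zip(samples, additions):
        if rows:
            s.table = pd.concat(
                [s.table, pd.DataFrame(rows)[TABLE_COLUMNS]], ignore_index=True
            )
            recompute_frequencies(s)
    # realized ratio with final totals (injection only grows recipient totals,
    # so ratios can only exceed the targets)
    totals = {s.sample_id: s.total_reads for s in samples}
    for entry in ledger:
        entry["ratio"] = entry["donor_frequency"] / (
            entry["injected_count"] / totals[entry["sample_id"]]
        )
    return rep_set, ledger


def inject_nonfunctional(
    sample: RepertoireSample,
    rate: float,
    seed: int,
    protect: set[str] | None = None,
) -> tuple[RepertoireSample, list[str]]:
    """Convert ~``rate`` of clonotypes into stop-codon or frameshift clones."""
    sample = sample.copy()
    if rate == 0.0:
        return sample, []
    rng = np.random.default_rng(seed)
    t = sample.table.reset_index(drop=True)
    protect = protect or set()
    keys = [
        _key(v, nt, j)
        for v, nt, j in zip(t["v_gene"], t["cdr3_nt"], t["j_gene"])
    ]
    # leave the dominant clones functional: the group-level expansion signal
    # should not be eroded by the non-functional filter
    top = set(t.nlargest(20, "read_count").index)
    eligible = [
        i for i, k in enumerate(keys) if k not in protect and i not in top
    ]
    n_pick = min(int(round(rate * len(t))), len(eligible))
    if n_pick == 0:
        return sample, []
    picks = rng.choice(len(eligible), size=n_pick, replace=False)
    existing = set(t["cdr3_nt"])
    converted: list[str] = []
    nts = t["cdr3_nt"].to_numpy(dtype=object)
    aas = t["cdr3_aa"].to_numpy(dtype=object)
    v_arr = t["v_gene"].to_numpy(dtype=object)
    j_arr = t["j_gene"].to_numpy(dtype=object)
    for e in picks:
        i = eligible[int(e)]
        nt = nts[i]
        for _ in range(8):
            if rng.random() < 0.5:  # internal stop codon
                codon_pos = int(rng.integers(0, len(nt) // 3))
                stop = STOP_CODONS[int(rng.integers(0, 3))]
                cand = nt[: 3 * codon_pos] + stop + nt[3 * codon_pos + 3 :]
            else:  # frameshift: delete one nucleotide
                p = int(rng.integers(0, len(nt)))
                cand = nt[:p] + nt[p + 1 :]
            if cand not in existing:
                existing.add(cand)
                nts[i] = cand
                aas[i] = _translate_fast(cand)
                converted.append(_key(v_arr[i], cand, j_arr[i]))
                break
    t = t.assign(cdr3_nt=nts, cdr3_aa=aas)
    sample.table = t
    recompute_frequencies(sample)
    return sample, converted


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A no-group-effect configuration for calibration runs.

    Both groups share every parameter (richness, abundance tail, usage
    profile dispersion, ages) with no forced expansions, no usage shifts
    and no age-richness slope, at a reduced scale suited to replicated
    null studies.  Any field can still be overridden.
    """
    base: dict = dict(
        n_benign=12,
        n_malignant=8,
        richness_benign=1000,
        richness_malignant=1000,
        zipf_exponent_benign=1.0,
        zipf_exponent_malignant=1.0,
        n_hyperexpanded_malignant=0,
        usage_shift={},
        usage_concentration_benign=800.0,
        usage_concentration_malignant=800.0,
        public_pool_size=400,
        public_frac_benign=0.05,
        public_frac_malignant=0.05,
        age_range_benign=(25.0, 70.0),
        age_range_malignant=(25.0, 70.0),
        age_richness_slope=0.0,
        depth_range=(8000, 15000),
    )
    base.update(overrides)
    return SimulationConfig(seed=seed, **base)


def simulate_repertoire_set(
    config: SimulationConfig | None = None,
) -> tuple[RepertoireSet, dict]:
    """Generate a full synthetic cohort plus its ground-truth ledger.

    The ledger records, per sample, the injected error-variant parent map
    and non-functional keys, plus the set-level contaminant list, group
    labels/ages and the group V-J usage profiles.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    joint_benign, joint_malignant = _group_profiles(config, rng)

    pool_nts, pool_aas = random_cdr3_set(
        config.public_pool_size, rng, config.cdr3_codon_range
    )
    n_j = len(config.j_genes)
    pool_vj = rng.choice(
        len(config.v_genes) * n_j, size=config.public_pool_size, p=joint_benign
    )
    pool = pd.DataFrame(
        {
            "v_gene": [config.v_genes[i // n_j] for i in pool_vj],
            "cdr3_nt": pool_nts,
            "cdr3_aa": pool_aas,
            "j_gene": [config.j_genes[i % n_j] for i in pool_vj],
        }
    )

    samples: list[RepertoireSample] = []
    cfg = asdict(config)
    cfg["usage_shift"] = {f"{v}_{j}": m for (v, j), m in config.usage_shift.items()}
    ledger: dict = {
        "config": cfg,
        "samples": {},
        "contaminants": [],
        "usage_shift": {f"{v}_{j}": m for (v, j), m in config.usage_shift.items()},
        "group_profiles": {
            "benign": joint_benign.tolist(),
            "malignant": joint_malignant.tolist(),
        },
    }
    plan = [("B", "benign", i) for i in range(config.n_benign)] + [
        ("M", "malignant", i) for i in range(config.n_malignant)
    ]
    for prefix, group, i in plan:
        sid = f"{prefix}{i + 1:02d}"
        joint = joint_benign if group == "benign" else joint_malignant
        conc = (
            config.usage_concentration_benign
            if group == "benign"
            else config.usage_concentration_malignant
        )
        sample, info = _make_sample(sid, group, config, rng, pool, joint, conc)

        err_seed = int(rng.integers(0, 2**31))
        sample, variant_map = inject_sequencing_errors(
            sample, config.error_rate, err_seed
        )
        protect = set(variant_map) | set(variant_map.values())
        nf_seed = int(rng.integers(0, 2**31))
        sample, nonfunctional = inject_nonfunctional(
            sample, config.nonfunctional_rate, nf_seed, protect=protect
        )
        info["variant_map"] = variant_map
        info["nonfunctional"] = nonfunctional
        ledger["samples"][sid] = info
        samples.append(sample)

    rep_set = RepertoireSet(samples)
    if config.contamination_rate > 0 and len(rep_set) > 1:
        contam_seed = int(rng.integers(0, 2**31))
        all_variants = {
            k for info in ledger["samples"].values() for k in info["variant_map"]
        }
        rep_set, contaminants = inject_contamination(
            rep_set,
            config.contamination_rate,
            contam_seed,
            config.contamination_fold_range,
            exclude_donor_keys=all_variants,
        )
        ledger["contaminants"] = contaminants
    for s in rep_set:
        s.validate()
    return rep_set, ledger
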