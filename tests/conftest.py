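import pandas as pd
import pytest

from repseqx.core import TABLE_COLUMNS, RepertoireSample, RepertoireSet, recompute_frequencies
from repseqx.preprocess import PreprocessConfig, preprocess_set
from repseqx.simulate import SimulationConfig, simulate_repertoire_set


def make_sample(
    counts,
    cdr3_nts=None,
    cdr3_aas=None,
    v_genes=None,
    j_genes=None,
    sample_id="S1",
    group=None,
    age=None,
):
    """Build a small RepertoireSample by hand; defaults give distinct functional clones."""
    n = len(counts)
    if cdr3_nts is None:
        base = "TGTGCCAGCAGC"  # CASS
        tails = ["GAA", "GAC", "GAG", "GAT", "GCA", "GCC", "GCG", "GCT", "GGA", "GGC"]
        cdr3_nts = [base + tails[i % 10] * (1 + i // 10) + "TTT" for i in range(n)]
    if cdr3_aas is None:
        from repseqx.core import translate_cdr3

        cdr3_aas = [translate_cdr3(nt) for nt in cdr3_nts]
    if v_genes is None:
        v_genes = ["TRBV19"] * n
    if j_genes is None:
        j_genes = ["TRBJ1-1"] * n
    table = pd.DataFrame(
        {
            "v_gene": v_genes,
            "cdr3_nt": cdr3_nts,
            "cdr3_aa": cdr3_aas,
            "j_gene": j_genes,
            "read_count": list(counts),
            "frequency": 0.0,
        }
    )[TABLE_COLUMNS]
    sample = RepertoireSample(
        sample_id=sample_id, table=table, group=group, age=age
    )
    recompute_frequencies(sample)
    return sample


def make_group_set(benign_values, malignant_values, builder):
    """RepertoireSet from per-sample specs via ``builder(spec, sid, group)``."""
    samples = []
    for i, spec in enumerate(benign_values):
        samples.append(builder(spec, f"B{i + 1:02d}", "benign"))
    for i, spec in enumerate(malignant_values):
        samples.append(builder(spec, f"M{i + 1:02d}", "malignant"))
    return RepertoireSet(samples)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort plus its ground-truth ledger (seed 7)."""
    return simulate_repertoire_set(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def preprocessed_cohort(default_cohort):
    rep_set, ledger = default_cohort
    out, logs = preprocess_set(rep_set, PreprocessConfig(seed=7))
    return out, ledger, logs


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, reduced-scale cohort retaining all group effects (seed 11)."""
    config = SimulationConfig(
        seed=11,
        richness_benign=800,
        richness_malignant=300,
        depth_range=(6000, 10000),
        public_pool_size=300,
    )
    return simulate_repertoire_set(config)
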