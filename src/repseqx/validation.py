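"""Replicated recovery and calibration studies on synthetic cohorts.

Every routine here builds cohorts with :mod:`repseqx.simulate`, runs the
production pipeline on them, and measures how reliably the known injected
structure is recovered: formula parity against brute-force oracles,
preprocessing recovery of ledgered injections, direction-of-effect rejection
rates, null calibration, permutation false-positive rates, screening-model
performance and motif recovery.  They back the package's self-validation
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import RepertoireSet
from .diversity import (
    chao1_index,
    diversity_table,
    gini_coefficient,
    inverse_simpson,
)
from .homeostasis import homeostasis_group_test, homeostasis_profiles
from .overlap import differential_clonotypes, motif_matrix
from .preprocess import PreprocessConfig, decontaminate, downsample, preprocess_set
from .screening import split_and_cv, train_evaluate
from .simulate import (
    SimulationConfig,
    inject_contamination,
    null_config,
    simulate_repertoire_set,
)
from .usage import differential_usage, usage_matrix

__all__ = [
    "formula_parity_errors",
    "preprocessing_recovery",
    "downsample_expectation_z",
    "replicate_effect_study",
    "replicate_null_study",
    "permutation_calibration",
    "permuted_auc_study",
    "screening_checks",
    "motif_recovery",
]


# ---------------------------------------------------------------------------
# formula parity


def formula_parity_errors(n_vectors: int = 1000, seed: int = 0) -> dict[str, float]:
    """Max |implementation - brute force| over random abundance vectors.

    The oracles are the literal formulas: the Gini double sum over all
    ordered pairs, direct singleton/doubleton tallies for Chao1, and the
    direct sum of squares for inverse Simpson.
    """
    rng = np.random.default_rng(seed)
    g_err = c_err = s_err = 0.0
    for _ in range(n_vectors):
        n = int(rng.integers(1, 200))
        counts = rng.integers(1, 50, size=n)
        p = counts / counts.sum()
        gini_bf = np.abs(p[:, None] - p[None, :]).sum() / (2 * n**2 * p.mean())
        chao_bf = (
            n
            + (counts == 1).sum() * ((counts == 1).sum() - 1)
            / (2.0 * ((counts == 2).sum() + 1))
        )
        simpson_bf = 1.0 / float(sum(pi * pi for pi in p))
        g_err = max(g_err, abs(gini_coefficient(p) - gini_bf))
        c_err = max(c_err, abs(chao1_index(counts) - chao_bf))
        s_err = max(s_err, abs(inverse_simpson(p) - simpson_bf))
    # closed-form limits
    uniform = np.full(100, 0.01)
    g_err = max(g_err, abs(gini_coefficient(uniform)))
    s_err = max(s_err, abs(inverse_simpson(uniform) - 100.0))
    c_err = max(c_err, abs(chao1_index(np.arange(2, 12)) - 10.0))
    return {"gini": g_err, "chao1": c_err, "inv_simpson": s_err}


# ---------------------------------------------------------------------------
# preprocessing recovery


def preprocessing_recovery(
    n_cohorts: int = 5, seed: int = 0, config: SimulationConfig | None = None
) -> dict[str, float]:
    """Recovery of ledgered injections by the four preprocessing steps.

    Over ``n_cohorts`` simulated cohorts: the fraction of planted error
    variants merged into their true parents, the number of merges not
    corresponding to a planted variant (false merges), the fraction of
    planted >= 20-fold contaminants removed, the removal rate of
    deliberately sub-threshold contaminants (fold < 20; should be 0), the
    fraction of planted non-functional clones absent from the output, and
    whether every sample ends at the common depth.
    """
    merged_true = planted_total = false_merges = 0
    contam_removed = contam_total = 0
    nf_removed = nf_total = 0
    depth_exact = True
    sub_removed = sub_total = 0
    for i in range(n_cohorts):
        cohort_seed = seed + i
        sim = (
            SimulationConfig(seed=cohort_seed)
            if config is None
            else _reseed(config, cohort_seed)
        )
        rep, ledger = simulate_repertoire_set(sim)
        out, logs = preprocess_set(rep, PreprocessConfig(seed=cohort_seed))

        planted = {}
        for info in ledger["samples"].values():
            planted.update(info["variant_map"])
        merged = {}
        for sample_log in logs.merges.values():
            for e in sample_log:
                merged["|".join(e["child"])] = "|".join(e["parent"])
        planted_total += len(planted)
        merged_true += sum(
            1 for child, parent in planted.items() if merged.get(child) == parent
        )
        false_merges += len(set(merged) - set(planted))

        removed = {(e["sample_id"], "|".join(e["key"])) for e in logs.contaminants}
        for c in ledger["contaminants"]:
            contam_total += 1
            contam_removed += (c["sample_id"], c["key"]) in removed

        final_keys = {
            s.sample_id: set(
                zip(s.table["v_gene"], s.table["cdr3_nt"], s.table["j_gene"])
            )
            for s in out
        }
        for sid, info in ledger["samples"].items():
            for key in info["nonfunctional"]:
                nf_total += 1
                nf_removed += tuple(key.split("|")) not in final_keys[sid]

        depth_exact &= len({s.total_reads for s in out}) == 1

        # sub-threshold contaminants on a clean companion cohort with no
        # public clones, so each planted pair is the only cross-sample
        # occurrence of its clonotype and the fold ratio is unambiguous
        clean, _ = simulate_repertoire_set(
            SimulationConfig(
                seed=cohort_seed + 90_000,
                richness_benign=600,
                richness_malignant=300,
                depth_range=(6000, 9000),
                error_rate=0.0,
                contamination_rate=0.0,
                nonfunctional_rate=0.0,
                public_frac_benign=0.0,
                public_frac_malignant=0.0,
            )
        )
        clean, below = inject_contamination(
            clean, 0.01, seed=cohort_seed, fold_range=(5.0, 15.0)
        )
        below = [c for c in below if c["ratio"] < 20.0]
        _, sub_log = decontaminate(clean, PreprocessConfig())
        sub_rm = {(e["sample_id"], "|".join(e["key"])) for e in sub_log}
        for c in below:
            sub_total += 1
            sub_removed += (c["sample_id"], c["key"]) in sub_rm

    return {
        "variant_merge_sensitivity": merged_true / planted_total,
        "false_merges": float(false_merges),
        "contaminant_recall": contam_removed / contam_total,
        "subthreshold_contaminant_removal_rate": sub_removed / max(sub_total, 1),
        "nonfunctional_recall": nf_removed / nf_total,
        "depth_exact": float(depth_exact),
        "n_planted_variants": float(planted_total),
        "n_planted_contaminants": float(contam_total),
    }


def _reseed(config: SimulationConfig, seed: int) -> SimulationConfig:
    import dataclasses

    return dataclasses.replace(config, seed=seed)


def downsample_expectation_z(n_draws: int = 2000, seed: int = 0) -> float:
    """Z-score of the mean subsampled count of a 600-read clone at depth 100
    from counts (600, 300, 100) against the hypergeometric expectation 60."""
    from .core import RepertoireSample, recompute_frequencies, table_from_records
    from .core import ClonotypeRecord

    records = [
        ClonotypeRecord("TGTGCAGCA", "CAA", "TRBV19", "TRBJ1-1", 600),
        ClonotypeRecord("TGTGCCGCA", "CAA", "TRBV19", "TRBJ1-1", 300),
        ClonotypeRecord("TGTGCGGCA", "CAA", "TRBV19", "TRBJ1-1", 100),
    ]
    sample = RepertoireSample(sample_id="S", table=table_from_records(records))
    recompute_frequencies(sample)
    rep = RepertoireSet([sample])
    draws = []
    for i in range(n_draws):
        out = downsample(
            rep, PreprocessConfig(downsample_depth=100, seed=seed + i)
        )
        t = out.samples[0].table
        hit = t[t["cdr3_nt"] == "TGTGCAGCA"]
        draws.append(int(hit["read_count"].iloc[0]) if len(hit) else 0)
    mean = float(np.mean(draws))
    # exact marginal-hypergeometric moments: n p (1-p) (N-n)/(N-1)
    se = np.sqrt(100 * 0.6 * 0.4 * (900 / 999) / n_draws)
    return (mean - 60.0) / se


# ---------------------------------------------------------------------------
# replicated group-effect and null studies


def replicate_effect_study(
    n_replicates: int = 50,
    seed: int = 1000,
    config: SimulationConfig | None = None,
    with_screening: bool = True,
) -> pd.DataFrame:
    """Per-replicate recovery summary on default-condition cohorts.

    Each replicate simulates a fresh cohort (seeds ``seed + i``), runs full
    preprocessing, and records: Wilcoxon p and group direction for the three
    diversity indices and unique-clonotype counts; the hyper-expanded-bin
    test; the overall age-richness Pearson r; the fraction of planted V-J
    shift pairs flagged by differential usage; and (optionally) the
    screening model's feature recovery and mean test AUC.
    """
    rows = []
    for i in range(n_replicates):
        cohort_seed = seed + i
        sim = (
            SimulationConfig(seed=cohort_seed)
            if config is None
            else _reseed(config, cohort_seed)
        )
        rep, ledger = simulate_repertoire_set(sim)
        rep, _ = preprocess_set(rep, PreprocessConfig(seed=cohort_seed))

        table, pvals = diversity_table(rep)
        mal = table[table["group"] == "malignant"]
        ben = table[table["group"] == "benign"]
        row = {
            "seed": cohort_seed,
            "p_inv_simpson": pvals["inv_simpson"],
            "p_chao1": pvals["chao1"],
            "p_gini": pvals["gini"],
            "p_unique": pvals["unique_clonotypes"],
            "gini_up_in_malignant": mal["gini"].mean() > ben["gini"].mean(),
            "inv_simpson_down_in_malignant": mal["inv_simpson"].mean()
            < ben["inv_simpson"].mean(),
            "chao1_down_in_malignant": mal["chao1"].mean() < ben["chao1"].mean(),
            "age_r_overall": stats.pearsonr(
                table["age"], table["unique_clonotypes"]
            ).statistic,
        }

        profiles = homeostasis_profiles(rep)
        p_hyper, direction = homeostasis_group_test(
            profiles, rep.groups, "Hyperexpanded"
        )
        row["p_hyperexpanded"] = p_hyper
        row["hyper_up_in_malignant"] = direction == "malignant"

        m = usage_matrix(rep, "VJ", "reads")
        du = differential_usage(m, rep.groups)
        flagged = set(du.loc[du["significant"], "segment"])
        planted = set(ledger["usage_shift"])
        row["usage_shift_sensitivity"] = len(planted & flagged) / len(planted)

        if with_screening:
            y = (rep.groups == "malignant").astype(int).to_numpy()
            plan = split_and_cv(y, seed=cohort_seed)
            try:
                reports, fs = train_evaluate(
                    m, rep.groups, plan, p_threshold=0.01, seed=cohort_seed
                )
                row["mean_test_auc"] = float(
                    np.mean([r.test_auc for r in reports])
                )
                row["feature_recovery"] = len(planted & set(fs.features)) / len(
                    planted
                )
            except ValueError:  # no feature passed selection
                row["mean_test_auc"] = np.nan
                row["feature_recovery"] = 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def replicate_null_study(
    n_replicates: int = 200, seed: int = 5000
) -> pd.DataFrame:
    """No-group-effect calibration: per-replicate inverse-Simpson Wilcoxon p
    and overall age-richness Pearson r under :func:`null_config` conditions
    (identical group parameters, age independent of richness)."""
    rows = []
    for i in range(n_replicates):
        cohort_seed = seed + i
        rep, _ = simulate_repertoire_set(null_config(cohort_seed))
        rep, _ = preprocess_set(rep, PreprocessConfig(seed=cohort_seed))
        table, pvals = diversity_table(rep)
        rows.append(
            {
                "seed": cohort_seed,
                "p_inv_simpson": pvals["inv_simpson"],
                "age_r_overall": stats.pearsonr(
                    table["age"], table["unique_clonotypes"]
                ).statistic,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation calibration


def permutation_calibration(
    rep_set: RepertoireSet, n_permutations: int = 100, seed: int = 0
) -> dict[str, float]:
    """Label-permutation false-positive rates for the two differential tests.

    Returns the mean fraction of clonotypes reported at (p < 0.01,
    |logFC| >= 2) and the mean fraction of V-J segments flagged at p < 0.05,
    over random group-label permutations of one cohort, with Monte-Carlo
    standard errors.
    """
    rng = np.random.default_rng(seed)
    groups = [s.group for s in rep_set]
    m = usage_matrix(rep_set, "VJ", "reads")
    clone_rates, usage_rates = [], []
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        shuffled = rep_set.copy()
        for s, g in zip(shuffled, perm):
            s.group = g
        hits, full = differential_clonotypes(shuffled)
        clone_rates.append(len(hits) / max(len(full), 1))
        du = differential_usage(m, shuffled.groups)
        usage_rates.append(du["significant"].mean())
    clone_rates = np.asarray(clone_rates)
    usage_rates = np.asarray(usage_rates)
    return {
        "clonotype_fp_rate": float(clone_rates.mean()),
        "clonotype_fp_se": float(clone_rates.std(ddof=1) / np.sqrt(n_permutations)),
        "usage_fp_rate": float(usage_rates.mean()),
        "usage_fp_se": float(usage_rates.std(ddof=1) / np.sqrt(n_permutations)),
        "n_permutations": float(n_permutations),
    }


# ---------------------------------------------------------------------------
# screening spot checks


def screening_checks(seed: int = 0) -> dict[str, float]:
    """Split arithmetic, the AUC = U/(n1 n0) identity, and the leakage probe.

    The identity is checked on 100 random score vectors; the leakage probe
    perturbs held-out samples and verifies the fitted models and selected
    features are unchanged.
    """
    from sklearn.metrics import roc_auc_score

    y = np.array([0] * 12 + [1] * 8)
    plan = split_and_cv(y, train_prop=0.7, folds=3, seed=seed)
    train_mal = int(y[plan.train_idx].sum())
    test_mal = int(y[plan.test_idx].sum())

    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(100):
        labels = rng.integers(0, 2, size=40)
        if labels.sum() in (0, 40):
            continue
        scores = rng.normal(size=40)
        u = stats.mannwhitneyu(
            scores[labels == 1], scores[labels == 0], alternative="two-sided"
        ).statistic
        auc = roc_auc_score(labels, scores)
        max_err = max(max_err, abs(auc - u / (labels.sum() * (40 - labels.sum()))))

    # leakage probe on a small synthetic feature matrix
    rng = np.random.default_rng(seed + 1)
    X = rng.uniform(0, 0.02, size=(20, 12))
    X[12:, :4] += 0.05
    m = pd.DataFrame(
        X, index=[f"S{i}" for i in range(20)], columns=[f"V{i}_J{i}" for i in range(12)]
    )
    groups = pd.Series(
        ["benign"] * 12 + ["malignant"] * 8, index=m.index
    )
    reports, fs = train_evaluate(m, groups, plan, seed=seed)
    m2 = m.copy()
    m2.iloc[plan.test_idx, :] += 77.0
    reports2, fs2 = train_evaluate(m2, groups, plan, seed=seed)
    leak_free = fs.features == fs2.features and all(
        r.cv_aucs == r2.cv_aucs for r, r2 in zip(reports, reports2)
    )
    return {
        "train_size": float(len(plan.train_idx)),
        "test_size": float(len(plan.test_idx)),
        "train_benign": float(len(plan.train_idx) - train_mal),
        "train_malignant": float(train_mal),
        "test_benign": float(len(plan.test_idx) - test_mal),
        "test_malignant": float(test_mal),
        "auc_u_identity_max_err": max_err,
        "leakage_free": float(leak_free),
    }


def permuted_auc_study(
    n_permutations: int = 25, seed: int = 0, models: tuple[str, ...] = ("LR", "RF", "SVM")
) -> dict[str, float]:
    """Mean test AUC under label permutation on a signal-free usage matrix.

    With no class signal the expected ROC-AUC is 0.5; feature selection is
    run at threshold 1 so a model is always fit.
    """
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 0.02, size=(20, 20))
    m = pd.DataFrame(
        X, index=[f"S{i}" for i in range(20)], columns=[f"V{i}_J{i}" for i in range(20)]
    )
    base = np.array(["benign"] * 12 + ["malignant"] * 8)
    aucs = []
    for i in range(n_permutations):
        groups = pd.Series(rng.permutation(base), index=m.index)
        y = (groups == "malignant").astype(int).to_numpy()
        plan = split_and_cv(y, seed=seed + i)
        try:
            reports, _ = train_evaluate(
                m, groups, plan, p_threshold=1.0, models=models, seed=seed + i
            )
        except ValueError:
            continue
        aucs.extend(r.test_auc for r in reports)
    aucs = np.asarray(aucs)
    return {
        "mean_auc": float(aucs.mean()),
        "se": float(aucs.std(ddof=1) / np.sqrt(aucs.size)),
        "n_fits": float(aucs.size),
    }


# ---------------------------------------------------------------------------
# motif recovery


def motif_recovery(
    seed: int = 0,
    n_sequences: int = 500,
    plant_frac: float = 0.6,
    motif: str = "LRGS",
    window: tuple[int, int] = (6, 9),
) -> dict[str, object]:
    """Plant a 4-mer at the window positions in a fraction of random CDR3
    amino-acid sequences and report the recovered top window k-mer."""
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    n_plant = int(round(plant_frac * n_sequences))
    seqs = []
    for i in range(n_sequences):
        length = int(rng.integers(max(12, window[1] + 3), 19))
        s = "".join(rng.choice(aas, size=length))
        if i < n_plant:
            s = s[: window[0] - 1] + motif + s[window[1] :]
        seqs.append(s)
    _, kmer, freq = motif_matrix(seqs, window)
    return {"top_kmer": kmer, "top_kmer_frequency": freq, "recovered": kmer == motif}
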