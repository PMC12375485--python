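import numpy as np
import pytest

from repseqx.core import RepertoireSet
from repseqx.preprocess import (
    PreprocessConfig,
    correct_clonotypes,
    decontaminate,
    downsample,
    filter_nonfunctional,
    preprocess_set,
)

from conftest import make_sample


def keyset(sample):
    t = sample.table
    return set(zip(t["v_gene"], t["cdr3_nt"], t["j_gene"]))


class TestCorrect:
    PARENT = "TGTGCCAGCAGCGAAGAAGAAGAATTT"  # 27 nt

    def _variant(self, n_mut):
        nt = list(self.PARENT)
        nt[5] = "T"
        if n_mut == 2:
            nt[8] = "T"
        if n_mut == 3:
            nt[8] = "T"
            nt[11] = "T"
        return "".join(nt)

    def _pair(self, parent_count, child_count, n_mut=1, child_j=None):
        return make_sample(
            [parent_count, child_count],
            cdr3_nts=[self.PARENT, self._variant(n_mut)],
            j_genes=["TRBJ1-1", child_j or "TRBJ1-1"],
        )

    def test_low_ratio_variant_merged_into_parent(self):
        s = self._pair(1000, 40)  # ratio 0.04 < 0.05
        out, log = correct_clonotypes(s)
        assert len(out.table) == 1
        assert out.table["read_count"].iloc[0] == 1040
        assert len(log) == 1 and log[0]["count"] == 40

    def test_ratio_at_or_above_threshold_kept_separate(self):
        for child in (60, 50):  # 0.06 and exactly 0.05
            out, log = correct_clonotypes(self._pair(1000, child))
            assert len(out.table) == 2 and not log

    def test_different_j_gene_never_merged(self):
        out, log = correct_clonotypes(self._pair(1000, 40, child_j="TRBJ2-1"))
        assert len(out.table) == 2 and not log

    def test_three_mismatches_kept_separate(self):
        out, _ = correct_clonotypes(self._pair(1000, 40, n_mut=3))
        assert len(out.table) == 2

    def test_length_mismatch_never_merged(self):
        s = make_sample(
            [1000, 10], cdr3_nts=[self.PARENT, self.PARENT + "GAA"]
        )
        out, _ = correct_clonotypes(s)
        assert len(out.table) == 2

    def test_conserves_reads_and_never_increases_clonotypes(self):
        rng = np.random.default_rng(1)
        s = make_sample(rng.integers(1, 2000, size=60))
        out, _ = correct_clonotypes(s)
        assert out.total_reads == s.total_reads
        assert len(out.table) <= len(s.table)

    def test_child_attaches_to_highest_count_parent(self):
        # two eligible parents; child must pick the larger
        p2 = list(self.PARENT)
        p2[5] = "A" if p2[5] != "A" else "C"
        p2 = "".join(p2)
        s = make_sample(
            [500, 2000, 20],
            cdr3_nts=[p2, self.PARENT, self._variant(1)],
        )
        out, log = correct_clonotypes(s)
        assert log and log[0]["parent"][1] == self.PARENT

    def test_direct_grandchild_merges_in_one_sweep(self):
        # variant(2) is within distance 2 of the parent itself
        s = make_sample(
            [10000, 400, 21],
            cdr3_nts=[self.PARENT, self._variant(1), self._variant(2)],
        )
        out, _ = correct_clonotypes(s)
        assert len(out.table) == 1
        assert out.table["read_count"].iloc[0] == 10421

    def test_no_transitive_merge_within_a_pass(self):
        # c3 is eligible only toward c2 (distance 3 from the parent); c2 is
        # itself a child, so c3 is deferred and, once c2 is absorbed, has no
        # remaining parent within reach
        s = make_sample(
            [10000, 400, 19],
            cdr3_nts=[self.PARENT, self._variant(1), self._variant(3)],
        )
        out, _ = correct_clonotypes(s)
        assert sorted(out.table["read_count"]) == [19, 10400]

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        s = make_sample(rng.integers(1, 3000, size=40))
        once, _ = correct_clonotypes(s)
        twice, log = correct_clonotypes(once)
        assert not log
        assert list(once.table["read_count"]) == list(twice.table["read_count"])


class TestDecontaminate:
    def _two_samples(self, count_a, total_a, count_b, total_b):
        shared = "TGTGCCAGCAGCGAAGAAGAAGAATTT"
        a = make_sample(
            [count_a, total_a - count_a],
            cdr3_nts=[shared, "TGTGCCAGCAGCGACGACGACGACTTT"],
            sample_id="A",
            group="benign",
        )
        b = make_sample(
            [count_b, total_b - count_b],
            cdr3_nts=[shared, "TGTGCCAGCAGCGAGGAGGAGGAGTTT"],
            sample_id="B",
            group="benign",
        )
        return RepertoireSet([a, b])

    def test_twenty_fold_boundary_inclusive(self):
        # freq 1e-5 in A vs exactly 2e-4 in B -> removed from A
        rep = self._two_samples(1, 100_000, 20, 100_000)
        out, log = decontaminate(rep)
        assert {e["sample_id"] for e in log} == {"A"}
        assert len(out["A"].table) == 1
        assert len(out["B"].table) == 2

    def test_nineteen_fold_retained(self):
        rep = self._two_samples(1, 100_000, 19, 100_000)
        out, log = decontaminate(rep)
        assert not log
        assert len(out["A"].table) == 2

    def test_unique_clone_retained(self):
        rep = self._two_samples(5, 100, 5, 100)
        # make the shared clone unshared
        rep["B"].table.loc[0, "cdr3_nt"] = "TGTGCCAGCAGCTTTTTTTTTTTTAAA"
        out, log = decontaminate(rep)
        assert not log

    def test_compares_frequencies_not_counts(self):
        # same counts, very different depths: 10/1000 vs 10/400000
        rep = self._two_samples(10, 400_000, 10, 1_000)
        out, log = decontaminate(rep)
        assert {e["sample_id"] for e in log} == {"A"}

    def test_single_sample_noop_with_warning(self):
        s = make_sample([5, 5], sample_id="solo")
        with pytest.warns(UserWarning):
            out, log = decontaminate(RepertoireSet([s]))
        assert not log


class TestFilterNonFunctional:
    def test_stop_codon_removed(self):
        s = make_sample([10, 5])
        s.table.loc[1, "cdr3_aa"] = "CASS*GELFF"
        out, log = filter_nonfunctional(s)
        assert len(out.table) == 1 and len(log) == 1
        assert abs(out.table["frequency"].sum() - 1) < 1e-9

    def test_frameshift_removed(self):
        s = make_sample([10, 5])
        s.table.loc[1, "cdr3_nt"] = s.table.loc[1, "cdr3_nt"][:-1]  # len % 3 != 0
        out, log = filter_nonfunctional(s)
        assert len(out.table) == 1
        assert log[0]["count"] == 5

    def test_in_frame_no_stop_retained(self):
        s = make_sample([10, 5])
        out, log = filter_nonfunctional(s)
        assert len(out.table) == 2 and not log


class TestDownsample:
    def _set(self, *counts_lists):
        samples = [
            make_sample(c, sample_id=f"S{i}") for i, c in enumerate(counts_lists)
        ]
        return RepertoireSet(samples)

    def test_already_at_depth_unchanged(self):
        rep = self._set([600, 300, 100])
        out = downsample(rep, PreprocessConfig(downsample_depth=1000))
        assert list(out.samples[0].table["read_count"]) == [600, 300, 100]

    def test_exact_target_depth_and_auto_min(self):
        rep = self._set([600, 300, 100], [50, 30], [400, 200])
        out = downsample(rep, PreprocessConfig(downsample_depth="auto-min", seed=3))
        assert all(s.total_reads == 80 for s in out)

    def test_depth_above_total_names_sample(self):
        rep = self._set([600, 300, 100], [5, 5])
        with pytest.raises(ValueError, match="S1"):
            downsample(rep, PreprocessConfig(downsample_depth=100))

    def test_deterministic_given_seed(self):
        rep = self._set([600, 300, 100])
        a = downsample(rep, PreprocessConfig(downsample_depth=50, seed=9))
        b = downsample(rep, PreprocessConfig(downsample_depth=50, seed=9))
        assert list(a.samples[0].table["read_count"]) == list(
            b.samples[0].table["read_count"]
        )

    def test_hypergeometric_expectation(self):
        # mean subsampled count of the 600-read clone at depth 100 from 1000
        # reads is 60 (multivariate hypergeometric marginal)
        rep = self._set([600, 300, 100])
        draws = []
        for seed in range(500):
            out = downsample(rep, PreprocessConfig(downsample_depth=100, seed=seed))
            t = out.samples[0].table
            row = t[t["cdr3_nt"] == rep.samples[0].table["cdr3_nt"].iloc[0]]
            draws.append(int(row["read_count"].iloc[0]) if len(row) else 0)
        mean = np.mean(draws)
        # exact hypergeometric variance: n p (1-p) (N-n)/(N-1)
        se = np.sqrt(100 * 0.6 * 0.4 * (900 / 999) / len(draws))
        assert abs(mean - 60.0) < 3 * se


class TestLedgeredPipeline:
    def test_planted_variants_merged_into_true_parents(self, preprocessed_cohort):
        _, ledger, logs = preprocessed_cohort
        planted = {}
        for info in ledger["samples"].values():
            planted.update(info["variant_map"])
        merged = {}
        for sample_log in logs.merges.values():
            for entry in sample_log:
                merged["|".join(entry["child"])] = "|".join(entry["parent"])
        recovered = sum(
            1 for child, parent in planted.items() if merged.get(child) == parent
        )
        assert recovered / len(planted) >= 0.95
        # no merge may cross V/J boundaries or involve non-variant clones
        false_merges = set(merged) - set(planted)
        assert not false_merges

    def test_planted_contaminants_all_removed(self, preprocessed_cohort):
        _, ledger, logs = preprocessed_cohort
        removed = {(e["sample_id"], "|".join(e["key"])) for e in logs.contaminants}
        planted = {(c["sample_id"], c["key"]) for c in ledger["contaminants"]}
        assert planted <= removed

    def test_subthreshold_contaminants_retained(self):
        from repseqx.simulate import SimulationConfig, simulate_repertoire_set, inject_contamination

        config = SimulationConfig(
            seed=13,
            richness_benign=500,
            richness_malignant=300,
            depth_range=(5000, 8000),
            contamination_rate=0.0,
            error_rate=0.0,
            nonfunctional_rate=0.0,
        )
        rep, _ = simulate_repertoire_set(config)
        rep, planted = inject_contamination(rep, 0.01, seed=13, fold_range=(5.0, 15.0))
        below = [c for c in planted if c["ratio"] < 20.0]
        assert below, "construction must plant sub-threshold contaminants"
        out, log = decontaminate(rep)
        removed = {(e["sample_id"], "|".join(e["key"])) for e in log}
        for c in below:
            assert (c["sample_id"], c["key"]) not in removed

    def test_nonfunctional_clones_all_removed(self, preprocessed_cohort):
        out_set, ledger, logs = preprocessed_cohort
        for sid, info in ledger["samples"].items():
            removed = {"|".join(e["key"]) for e in logs.nonfunctional[sid]}
            # planted non-functional clones are removed unless an upstream
            # step (decontamination) already dropped them
            survivors = set(info["nonfunctional"]) - removed
            final_keys = {
                "|".join(k) for k in zip(
                    out_set[sid].table["v_gene"],
                    out_set[sid].table["cdr3_nt"],
                    out_set[sid].table["j_gene"],
                )
            }
            assert not (survivors & final_keys)

    def test_every_sample_at_common_depth(self, preprocessed_cohort):
        out_set, _, _ = preprocessed_cohort
        depths = {s.total_reads for s in out_set}
        assert len(depths) == 1

    def test_pipeline_deterministic(self, small_cohort):
        rep, _ = small_cohort
        a, _ = preprocess_set(rep, PreprocessConfig(seed=2))
        b, _ = preprocess_set(rep, PreprocessConfig(seed=2))
        for sa, sb in zip(a, b):
            assert sa.table.equals(sb.table)
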