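import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repseqx.core import AbundanceVector
from repseqx.diversity import (
    age_correlation,
    chao1_index,
    diversity_table,
    gini_coefficient,
    inverse_simpson,
)
from repseqx._stats import mann_whitney

from conftest import make_group_set, make_sample


def gini_bruteforce(x):
    """Independent oracle: the literal double sum over all ordered pairs."""
    x = np.asarray(x, dtype=float)
    n = x.size
    return np.abs(x[:, None] - x[None, :]).sum() / (2 * n**2 * x.mean())


def chao1_bruteforce(counts):
    counts = np.asarray(counts)
    s = int((counts > 0).sum())
    a1 = int((counts == 1).sum())
    a2 = int((counts == 2).sum())
    return s + a1 * (a1 - 1) / (2 * (a2 + 1))


class TestGini:
    def test_uniform_is_zero(self):
        assert gini_coefficient([0.25] * 4) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize(
        "x,expected",
        [((0.8, 0.2), 0.3), ((0.5, 0.3, 0.2), 0.2)],
    )
    def test_worked_examples(self, x, expected):
        # expected values frozen from the double-sum oracle
        assert gini_bruteforce(x) == pytest.approx(expected, abs=1e-12)
        assert gini_coefficient(x) == pytest.approx(expected, abs=1e-12)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(1, 200)
            x = rng.dirichlet(np.full(n, 0.5))
            assert gini_coefficient(x) == pytest.approx(gini_bruteforce(x), abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gini_coefficient([])

    @given(
        st.lists(st.integers(1, 1000), min_size=2, max_size=30),
        st.data(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_transfer_to_larger_clone_never_decreases_gini(self, counts, data):
        # Pigou-Dalton transfer principle: moving reads from a smaller to a
        # larger clone makes the distribution more unequal
        v = np.asarray(sorted(counts), dtype=float)
        i = data.draw(st.integers(0, len(v) - 2))
        j = data.draw(st.integers(i + 1, len(v) - 1))
        before = gini_coefficient(v / v.sum())
        moved = v.copy()
        transfer = moved[i] / 2
        moved[i] -= transfer
        moved[j] += transfer
        after = gini_coefficient(moved / moved.sum())
        assert after >= before - 1e-12


class TestChao1:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (list(range(3, 13)), 10.0),  # S_obs=10, a1=0
            ([1, 1, 1, 1, 2, 2, 3, 3, 3, 3], 12.0),  # 10 + 4*3/(2*3)
            ([1, 1, 1, 1, 1], 15.0),  # 5 + 5*4/(2*1)
        ],
    )
    def test_worked_examples(self, counts, expected):
        assert chao1_bruteforce(counts) == pytest.approx(expected)
        assert chao1_index(counts) == pytest.approx(expected)

    def test_single_singleton_collapses_to_s_obs(self):
        assert chao1_index([1, 2, 3]) == 3.0

    def test_never_below_observed_richness(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            counts = rng.integers(1, 20, size=rng.integers(1, 100))
            v = AbundanceVector.from_counts(counts)
            assert chao1_index(v) >= v.s_obs
            assert chao1_index(v) == pytest.approx(chao1_bruteforce(counts), abs=1e-12)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            chao1_index([1.5, 2.2])


class TestInverseSimpson:
    def test_closed_forms(self):
        assert inverse_simpson([0.01] * 100) == pytest.approx(100.0)
        assert inverse_simpson([1.0]) == pytest.approx(1.0)
        assert inverse_simpson([0.9, 0.1]) == pytest.approx(1 / 0.82, abs=1e-12)

    def test_matches_bruteforce_and_bounds(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            p = rng.dirichlet(np.full(rng.integers(1, 150), 0.7))
            expected = 1.0 / sum(pi * pi for pi in p)
            d = inverse_simpson(p)
            assert d == pytest.approx(expected, abs=1e-12)
            assert 1.0 - 1e-12 <= d <= p.size + 1e-9

    @given(st.lists(st.integers(1, 500), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_splitting_a_clone_in_half_never_decreases_diversity(self, counts):
        v = np.asarray(counts, dtype=float)
        before = inverse_simpson(v / v.sum())
        split = np.concatenate([[v[0] / 2, v[0] / 2], v[1:]])
        after = inverse_simpson(split / split.sum())
        assert after >= before - 1e-9


class TestAgainstScikitBio:
    """Independent cross-check against another implementation."""

    def test_chao1_and_simpson_agree_with_skbio(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        rng = np.random.default_rng(5)
        for _ in range(50):
            counts = rng.integers(1, 30, size=60)
            assert chao1_index(counts) == pytest.approx(
                float(skbio_alpha.chao1(counts, bias_corrected=True)), rel=1e-12
            )
            assert inverse_simpson(counts / counts.sum()) == pytest.approx(
                float(skbio_alpha.enspie(counts)), rel=1e-12
            )


class TestDiversityTable:
    def _metric_set(self, benign_vals, malignant_vals):
        def builder(val, sid, group):
            # geometric counts give distinct index values scaled by `val`
            counts = [int(val * f) for f in (600, 250, 100, 40, 10)]
            return make_sample(counts, sample_id=sid, group=group, age=30.0)

        return make_group_set(benign_vals, malignant_vals, builder)

    def test_mann_whitney_exact_small_groups(self):
        # groups (1,2,3) vs (4,5,6): all 3 ranks at the bottom; exact
        # two-sided p = 2 / C(6,3) = 0.1 (frozen from full enumeration)
        _, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_give_p_one(self):
        rep = self._metric_set([1, 1, 1], [1, 1, 1])
        _, pvals = diversity_table(rep)
        assert all(p == 1.0 for p in pvals.values())

    def test_simulated_malignant_expansion_directions(self, preprocessed_cohort):
        rep_set, _, _ = preprocessed_cohort
        table, pvals = diversity_table(rep_set)
        mal = table[table["group"] == "malignant"]
        ben = table[table["group"] == "benign"]
        assert mal["gini"].mean() > ben["gini"].mean()
        assert mal["inv_simpson"].mean() < ben["inv_simpson"].mean()
        assert mal["chao1"].mean() < ben["chao1"].mean()
        assert mal["unique_clonotypes"].mean() < ben["unique_clonotypes"].mean()

    def test_empty_group_errors(self):
        rep = self._metric_set([1, 2], [])
        with pytest.raises(ValueError):
            diversity_table(rep)


class TestAgeCorrelation:
    def _aged_set(self, ages_benign, ages_malignant, richness_fn):
        def builder(age, sid, group):
            n = richness_fn(age)
            return make_sample([2] * n, sample_id=sid, group=group, age=float(age))

        return make_group_set(ages_benign, ages_malignant, builder)

    def test_exact_linear_decline_gives_minus_one(self):
        rep = self._aged_set([30, 40, 50], [35, 45, 55], lambda a: 200 - 2 * int(a))
        res = age_correlation(rep, "unique_clonotypes")
        assert res.loc["overall", "r"] == pytest.approx(-1.0)
        assert res.loc["benign", "r"] == pytest.approx(-1.0)

    def test_simulator_negative_slope_recovered(self, preprocessed_cohort):
        rep_set, ledger, _ = preprocessed_cohort
        assert ledger["config"]["age_richness_slope"] < 0
        res = age_correlation(rep_set, "unique_clonotypes")
        assert res.loc["overall", "r"] < 0

    def test_zero_age_variance_errors(self):
        rep = self._aged_set([40, 40, 40], [40, 40, 40], lambda a: 50)
        with pytest.raises(ValueError, match="age variance"):
            age_correlation(rep)

    def test_independent_ages_center_near_zero(self):
        # fresh cohorts with age independent of richness: E[r] = 0
        rng = np.random.default_rng(21)
        rs = []
        for _ in range(100):
            rep = self._aged_set(
                rng.uniform(25, 70, size=6),
                rng.uniform(25, 70, size=4),
                lambda a: int(rng.integers(50, 150)),
            )
            rs.append(age_correlation(rep, "unique_clonotypes").loc["overall", "r"])
        rs = np.asarray(rs)
        assert abs(rs.mean()) < 3 * rs.std(ddof=1) / np.sqrt(rs.size)
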