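import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import spearmanr

from phaselock import (
    AngleSample,
    InvalidInputError,
    VonMisesParams,
    circular_ranks,
    permutation_pvalue,
    plv,
    ust_statistic,
    ustpl_test,
    vonmises_sample,
)

TWO_PI = 2.0 * np.pi


def exact_enumeration_pvalue(pop1, pop2, tie_seed=0):
    """Independent oracle: enumerate every label assignment by brute force."""
    ranked = circular_ranks(pop1, pop2, tie_seed=tie_seed)
    scores = np.concatenate([ranked.scores_1, ranked.scores_2])
    n, n1, n2 = ranked.n, ranked.n1, ranked.n2

    def rstar(subset):
        b = scores[list(subset)]
        r2 = np.cos(b).sum() ** 2 + np.sin(b).sum() ** 2
        return 2 * (n - 1) * r2 / (n1 * n2)

    observed = rstar(range(n1))
    null = [rstar(c) for c in combinations(range(n), n1)]
    return np.mean([v >= observed - 1e-9 for v in null])


class TestCircularRanks:
    def test_interleaved_example(self):
        ranked = circular_ranks(AngleSample([0.1, 0.3]), AngleSample([0.2, 0.4]), tie_seed=0)
        np.testing.assert_allclose(ranked.scores_1, [np.pi / 2, 3 * np.pi / 2])
        np.testing.assert_allclose(ranked.scores_2, [np.pi, 2 * np.pi])

    def test_scores_exactly_equally_spaced(self, rng):
        pop1 = AngleSample(rng.uniform(0, TWO_PI, 7))
        pop2 = AngleSample(rng.uniform(0, TWO_PI, 12))
        ranked = circular_ranks(pop1, pop2, tie_seed=1)
        pooled = np.sort(np.concatenate([ranked.scores_1, ranked.scores_2]))
        np.testing.assert_allclose(pooled, TWO_PI * np.arange(1, 20) / 19, atol=1e-12)

    def test_within_population_order_preserved(self, rng):
        # ranking is monotone: angles sorted from 0 keep their relative order
        pop1 = AngleSample(rng.uniform(0, TWO_PI, 9))
        pop2 = AngleSample(rng.uniform(0, TWO_PI, 9))
        ranked = circular_ranks(pop1, pop2, tie_seed=2)
        assert np.all(np.argsort(pop1.angles) == np.argsort(ranked.scores_1))
        assert np.all(np.argsort(pop2.angles) == np.argsort(ranked.scores_2))

    def test_tie_break_preserves_spacing(self):
        pop1 = AngleSample([1.0, 1.0, 1.0])
        pop2 = AngleSample([1.0, 2.0])
        ranked = circular_ranks(pop1, pop2, tie_seed=3)
        pooled = np.sort(np.concatenate([ranked.scores_1, ranked.scores_2]))
        np.testing.assert_allclose(pooled, TWO_PI * np.arange(1, 6) / 5, atol=1e-12)


class TestUstStatistic:
    def test_alternating_ranks_cancel(self):
        # populations occupying strictly alternating ranks -> evenly spaced scores
        m = 6
        pop1 = AngleSample(np.linspace(0.05, 6.0, 2 * m)[0::2])
        pop2 = AngleSample(np.linspace(0.05, 6.0, 2 * m)[1::2])
        ranked = circular_ranks(pop1, pop2, tie_seed=0)
        r2, _ = ust_statistic(ranked)
        assert r2 == pytest.approx(0.0, abs=1e-10)

    def test_group_symmetry(self, rng):
        for _ in range(20):
            ranked = circular_ranks(
                AngleSample(rng.uniform(0, TWO_PI, rng.integers(2, 15))),
                AngleSample(rng.uniform(0, TWO_PI, rng.integers(2, 15))),
                tie_seed=0,
            )
            r2_1, _ = ust_statistic(ranked, k=1)
            r2_2, _ = ust_statistic(ranked, k=2)
            assert r2_1 == pytest.approx(r2_2, abs=1e-10)

    def test_hand_computed_oracle(self):
        # n1=n2=3; fix the rank assignment by choosing non-tied angles
        pop1 = AngleSample([0.1, 0.5, 0.9])  # ranks 1, 3, 5
        pop2 = AngleSample([0.3, 0.7, 1.1])  # ranks 2, 4, 6
        ranked = circular_ranks(pop1, pop2, tie_seed=0)
        beta = TWO_PI * np.array([1, 3, 5]) / 6
        r2_expected = math.fsum(np.cos(beta)) ** 2 + math.fsum(np.sin(beta)) ** 2
        rstar_expected = 2 * (6 - 1) * r2_expected / (3 * 3)
        r2, rstar = ust_statistic(ranked)
        assert r2 == pytest.approx(r2_expected, abs=1e-10)
        assert rstar == pytest.approx(rstar_expected, abs=1e-10)

    def test_root_normalization_option(self, uniform_pair):
        ranked = circular_ranks(*uniform_pair, tie_seed=0)
        r2, rstar_sq = ust_statistic(ranked)
        _, rstar_root = ust_statistic(ranked, root_normalization=True)
        assert rstar_root == pytest.approx(rstar_sq * math.sqrt(r2) / r2)


class TestUstplTest:
    def test_separated_populations_significant(self):
        pop1 = vonmises_sample(VonMisesParams(0.0, 50.0), 25, seed=1)
        pop2 = vonmises_sample(VonMisesParams(np.pi, 50.0), 25, seed=2)
        res = ustpl_test(pop1, pop2, mode="permutation", n_permutations=10_000, seed=0)
        assert res.p_value < 0.001

    def test_auto_mode_selection(self, rng):
        big1 = AngleSample(rng.uniform(0, TWO_PI, 30))
        big2 = AngleSample(rng.uniform(0, TWO_PI, 30))
        assert ustpl_test(big1, big2, mode="auto").mode == "asymptotic"
        small1 = AngleSample(rng.uniform(0, TWO_PI, 6))
        small2 = AngleSample(rng.uniform(0, TWO_PI, 6))
        # choose(12, 6) = 924 <= cap -> silently upgrades to exact enumeration
        assert ustpl_test(small1, small2, mode="auto", seed=0).mode == "exact"

    def test_label_symmetry(self, uniform_pair):
        a, b = uniform_pair
        r1 = ustpl_test(a, b, mode="asymptotic")
        r2 = ustpl_test(b, a, mode="asymptotic")
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-10)

    def test_rotation_invariance(self, concentrated_pair):
        a, b = concentrated_pair
        base = ustpl_test(a, b, mode="asymptotic")
        rot = ustpl_test(a.rotated(1.234), b.rotated(1.234), mode="asymptotic")
        assert rot.statistic == pytest.approx(base.statistic, abs=1e-10)
        assert rot.p_value == pytest.approx(base.p_value, abs=1e-10)

    def test_null_pvalues_roughly_uniform(self, rng):
        pvals = [
            ustpl_test(
                AngleSample(rng.uniform(0, TWO_PI, 25)),
                AngleSample(rng.uniform(0, TWO_PI, 25)),
                mode="asymptotic",
            ).p_value
            for _ in range(400)
        ]
        pvals = np.sort(pvals)
        # crude uniformity: empirical CDF within 0.1 of the diagonal
        assert np.max(np.abs(pvals - (np.arange(1, 401) / 400))) < 0.1

    def test_exact_matches_bruteforce_oracle(self, rng):
        pop1 = AngleSample(rng.uniform(0, TWO_PI, 5))
        pop2 = AngleSample(rng.uniform(0, TWO_PI, 5))
        res = ustpl_test(pop1, pop2, mode="permutation", seed=0)
        assert res.mode == "exact"
        assert res.p_value == pytest.approx(exact_enumeration_pvalue(pop1, pop2, tie_seed=0))

    def test_asymptotic_tracks_exact_over_instances(self, rng):
        # Spearman correlation between exact and asymptotic p across
        # random instances at n1 = n2 in {4, 5, 6}
        exact_ps, asym_ps = [], []
        for m in (4, 5, 6):
            for _ in range(17):
                pop1 = AngleSample(rng.uniform(0, TWO_PI, m))
                pop2 = AngleSample(rng.uniform(0, TWO_PI, m))
                exact_ps.append(ustpl_test(pop1, pop2, mode="permutation", seed=1).p_value)
                asym_ps.append(ustpl_test(pop1, pop2, mode="asymptotic", seed=1).p_value)
        rho = spearmanr(exact_ps, asym_ps).statistic
        assert rho > 0.95

    def test_power_monotone_in_concentration(self):
        # rejection rate against a uniform baseline grows with kappa
        rng = np.random.default_rng(5)
        rates = []
        for kappa in (1.0, 4.0, 20.0, 50.0):
            rej = 0
            for _ in range(500):
                pop1 = AngleSample(rng.vonmises(0.0, kappa, 30))
                pop2 = AngleSample(rng.uniform(0, TWO_PI, 30))
                rej += ustpl_test(pop1, pop2, mode="asymptotic").p_value < 0.05
            rates.append(rej / 500)
        assert all(a <= b + 0.03 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]

    def test_input_validation(self, uniform_pair):
        a, b = uniform_pair
        with pytest.raises(InvalidInputError):
            ustpl_test(AngleSample([0.1]), b)
        with pytest.raises(InvalidInputError):
            ustpl_test(a, b, mode="permutation", n_permutations=0, exact_cap=0)
        with pytest.raises(InvalidInputError):
            ustpl_test(a, b, mode="bogus")


class TestPermutationPvalue:
    def test_constant_statistic_gives_one(self, uniform_pair):
        p, null = permutation_pvalue(lambda a, b: 1.0, *uniform_pair, n_permutations=50, seed=0)
        assert p == 1.0
        assert len(null) == 50

    def test_identical_samples_tie_to_one(self):
        s = AngleSample([0.2, 1.1, 2.5, 4.0])
        p, _ = permutation_pvalue(
            lambda a, b: abs(plv(a) - plv(b)), s, s, n_permutations=200, seed=0
        )
        assert p == 1.0

    def test_montecarlo_agrees_with_exact_enumeration(self, rng):
        pop1 = AngleSample(rng.uniform(0, TWO_PI, 5))
        pop2 = AngleSample(rng.uniform(0, TWO_PI, 5))

        def rstar_stat(a, b):
            return ust_statistic(circular_ranks(a, b, tie_seed=0))[1]

        p_mc, _ = permutation_pvalue(rstar_stat, pop1, pop2, n_permutations=2000, seed=3)
        p_exact = exact_enumeration_pvalue(pop1, pop2, tie_seed=0)
        se = np.sqrt(p_exact * (1 - p_exact) / 2000)
        assert abs(p_mc - p_exact) <= 2 * se + 1 / 2001

    def test_reproducible_under_seed(self, uniform_pair):
        stat = lambda a, b: abs(plv(a) - plv(b))
        p1, n1 = permutation_pvalue(stat, *uniform_pair, n_permutations=100, seed=4)
        p2, n2 = permutation_pvalue(stat, *uniform_pair, n_permutations=100, seed=4)
        assert p1 == p2
        np.testing.assert_array_equal(n1, n2)
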