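import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from scipy.spatial.distance import pdist, squareform

from phycobycatch import (
    DistanceMatrix,
    Grouping,
    beta_dispersion,
    fisher_exact_2x2,
    goodman_kruskal_tau,
    indicator_species,
    pairwise_permanova,
    permanova,
    spearman,
)
from phycobycatch.community_stats import _permanova_f


def euclidean_dm(coords, labels):
    return DistanceMatrix(labels, squareform(pdist(np.atleast_2d(coords))))


def exhaustive_two_group_p(d2, labels):
    """Enumerate every equal-size split of 6 samples (20 splits)."""
    n = len(labels)
    group_a = [i for i, g in enumerate(labels) if g == labels[0]]
    observed = _permanova_f(d2, np.array([0 if i in group_a else 1
                                          for i in range(n)]), 2)
    count = total = 0
    for combo in combinations(range(n), len(group_a)):
        codes = np.array([0 if i in combo else 1 for i in range(n)])
        f = _permanova_f(d2, codes, 2)
        total += 1
        if f >= observed - 1e-12:
            count += 1
    return count / total


class TestPermanova:
    def test_degenerate_zero_within_group_variation(self):
        # duplicated identical points per group: SS_within = 0
        d = euclidean_dm(np.array([[0.0], [0.0], [5.0], [5.0]]),
                         ["a1", "a2", "b1", "b2"])
        g = Grouping({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        res = permanova(d, g, n_perm=9, seed=0)
        assert math.isnan(res.statistic) and "degenerate" in res.status

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(6, 2))
        coords[:3] += 1.0  # modest planted separation
        labels = ["A"] * 3 + ["B"] * 3
        samples = [f"s{i}" for i in range(6)]
        d = euclidean_dm(coords, samples)
        g = Grouping(dict(zip(samples, labels)))
        exact = exhaustive_two_group_p(d.values**2, labels)
        n_perm = 2000
        res = permanova(d, g, n_perm=n_perm, seed=1)
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.p_value - exact) <= 3 * se + 2 / n_perm

    def test_pseudo_f_equals_anova_f_for_1d_euclidean(self):
        rng = np.random.default_rng(4)
        y = [rng.normal(loc=m, size=5) for m in (0.0, 1.0, 3.0)]
        data = np.concatenate(y)
        labels = ["g1"] * 5 + ["g2"] * 5 + ["g3"] * 5
        samples = [f"s{i}" for i in range(15)]
        d = euclidean_dm(data[:, None], samples)
        res = permanova(d, Grouping(dict(zip(samples, labels))),
                        n_perm=9, seed=0)
        f_ref = sps.f_oneway(*y).statistic
        assert res.statistic == pytest.approx(f_ref, abs=1e-8)

    def test_invariant_to_sample_and_group_relabeling(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(8, 2))
        samples = [f"s{i}" for i in range(8)]
        labels = ["A", "A", "A", "A", "B", "B", "B", "B"]
        d = euclidean_dm(coords, samples)
        base = permanova(d, Grouping(dict(zip(samples, labels))),
                         n_perm=99, seed=7)
        renamed = permanova(d, Grouping(dict(zip(samples,
                                                 [{"A": "x", "B": "y"}[l]
                                                  for l in labels]))),
                            n_perm=99, seed=7)
        assert base.statistic == pytest.approx(renamed.statistic)
        perm = rng.permutation(8)
        d_shuf = DistanceMatrix([samples[i] for i in perm],
                                d.values[np.ix_(perm, perm)])
        shuffled = permanova(d_shuf, Grouping(dict(zip(samples, labels))),
                             n_perm=99, seed=7)
        assert base.statistic == pytest.approx(shuffled.statistic)

    def test_pairwise_bonferroni_adjustment(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(16, 2))
        samples = [f"s{i}" for i in range(16)]
        labels = np.repeat(["a", "b", "c", "d"], 4)
        d = euclidean_dm(coords, samples)
        table = pairwise_permanova(d, Grouping(dict(zip(samples, labels))),
                                   n_perm=99, seed=0)
        assert len(table) == 6
        np.testing.assert_allclose(
            table["p_adjusted"], np.minimum(1.0, table["p_value"] * 6))

    def test_two_groups_single_pair_unadjusted(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(8, 2))
        samples = [f"s{i}" for i in range(8)]
        labels = ["a"] * 4 + ["b"] * 4
        table = pairwise_permanova(euclidean_dm(coords, samples),
                                   Grouping(dict(zip(samples, labels))),
                                   n_perm=99, seed=0)
        assert len(table) == 1
        assert table["p_adjusted"].iloc[0] == table["p_value"].iloc[0]


class TestBetaDispersion:
    def test_rigid_copy_groups_have_equal_dispersion(self):
        rng = np.random.default_rng(8)
        blob = rng.normal(size=(10, 2))
        coords = np.vstack([blob, blob + 50.0])  # same shape, translated
        samples = [f"s{i}" for i in range(20)]
        labels = ["A"] * 10 + ["B"] * 10
        z, res = beta_dispersion(euclidean_dm(coords, samples),
                                 Grouping(dict(zip(samples, labels))),
                                 n_perm=199, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p_value > 0.5

    def test_inflated_group_detected(self):
        rng = np.random.default_rng(9)
        blob = rng.normal(size=(20, 2))
        coords = np.vstack([blob, 5.0 * rng.normal(size=(20, 2)) + 50.0])
        samples = [f"s{i}" for i in range(40)]
        labels = ["tight"] * 20 + ["loose"] * 20
        _, res = beta_dispersion(euclidean_dm(coords, samples),
                                 Grouping(dict(zip(samples, labels))),
                                 n_perm=199, seed=1)
        assert res.p_value < 0.05

    def test_distances_match_direct_coordinates_for_euclidean_input(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(size=(12, 3))
        samples = [f"s{i}" for i in range(12)]
        labels = ["A"] * 6 + ["B"] * 6
        z, _ = beta_dispersion(euclidean_dm(coords, samples),
                               Grouping(dict(zip(samples, labels))),
                               n_perm=9, seed=0)
        for grp, idx in (("A", range(6)), ("B", range(6, 12))):
            centroid = coords[list(idx)].mean(axis=0)
            for i in idx:
                direct = np.linalg.norm(coords[i] - centroid)
                assert z[f"s{i}"] == pytest.approx(direct, abs=1e-8)

    def test_singleton_group_named_in_error(self):
        d = euclidean_dm(np.arange(3.0)[:, None], ["a", "b", "c"])
        with pytest.raises(ValueError, match="B"):
            beta_dispersion(d, Grouping({"a": "A", "b": "A", "c": "B"}))


class TestIndicatorSpecies:
    def _presence(self, rows, samples, features):
        return pd.DataFrame(rows, index=samples, columns=features, dtype=bool)

    def test_perfect_indicator_scores_one(self):
        pres = self._presence(
            [[1], [1], [1], [0], [0], [0]],
            [f"s{i}" for i in range(6)], ["f"])
        g = Grouping({f"s{i}": ("G1" if i < 3 else "G2") for i in range(6)})
        res = indicator_species(pres, g, n_perm=99, seed=0)
        assert res.loc["f", ["A", "B", "stat"]].tolist() == [1.0, 1.0, 1.0]
        assert res.loc["f", "best_group"] == "G1"

    def test_ubiquitous_feature_scores_sqrt_half(self):
        pres = self._presence(np.ones((6, 1)), [f"s{i}" for i in range(6)],
                              ["f"])
        g = Grouping({f"s{i}": ("G1" if i < 3 else "G2") for i in range(6)})
        res = indicator_species(pres, g, n_perm=99, seed=0)
        assert res.loc["f", "A"] == pytest.approx(0.5)
        assert res.loc["f", "B"] == pytest.approx(1.0)
        assert res.loc["f", "stat"] == pytest.approx(math.sqrt(0.5))

    def test_permutation_p_matches_exhaustive_enumeration(self):
        pres = self._presence(
            [[1], [1], [1], [1], [0], [0]],
            [f"s{i}" for i in range(6)], ["f"])
        labels = ["G1"] * 3 + ["G2"] * 3
        g = Grouping(dict(zip(pres.index, labels)))
        inc = pres["f"].to_numpy()
        observed_stats = []
        for combo in combinations(range(6), 3):
            codes = np.array([0 if i in combo else 1 for i in range(6)])
            from phycobycatch.community_stats import _indval_stats
            _, _, stat = _indval_stats(inc[:, None], codes, 2)
            observed_stats.append(stat.max())
        obs = observed_stats[0]  # (0,1,2) is the true grouping
        exact = np.mean([s >= obs - 1e-12 for s in observed_stats])
        n_perm = 4000
        res = indicator_species(pres, g, n_perm=n_perm, seed=2)
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.loc["f", "p_value"] - exact) <= 3 * se + 2 / n_perm

    def test_absent_feature_emitted_missing(self):
        pres = self._presence([[1, 0], [1, 0], [0, 0], [0, 0]],
                              [f"s{i}" for i in range(4)], ["f", "ghost"])
        g = Grouping({f"s{i}": ("G1" if i < 2 else "G2") for i in range(4)})
        res = indicator_species(pres, g, n_perm=19, seed=0)
        assert np.isnan(res.loc["ghost", "stat"])
        assert res.loc["f", "stat"] == 1.0

    def test_size_equalized_a_invariant_to_group_duplication(self):
        pres = self._presence(
            [[1], [0], [1], [1], [0], [0]],
            [f"s{i}" for i in range(6)], ["f"])
        labels = {"s0": "G1", "s1": "G1", "s2": "G2", "s3": "G2",
                  "s4": "G2", "s5": "G2"}
        res1 = indicator_species(pres, Grouping(labels), n_perm=9, seed=0)
        doubled = pd.concat([pres, pres.set_axis(
            [f"d{i}" for i in range(6)])])
        labels2 = dict(labels) | {f"d{i}": labels[f"s{i}"] for i in range(6)}
        res2 = indicator_species(doubled, Grouping(labels2), n_perm=9, seed=0)
        assert res1.loc["f", "A"] == pytest.approx(res2.loc["f", "A"])


def fisher_oracle(a, b, c, d):
    """Exact rational two-sided Fisher p by direct table enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(k):
        return (Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k),
                         math.comb(n, c1)))

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        if prob(k) <= p_obs:
            total += prob(k)
    return float(total)


class TestFisherExact:
    def test_single_count_diagonal_p_one(self):
        p, _ = fisher_exact_2x2([[1, 0], [0, 1]])
        assert p == pytest.approx(1.0)

    def test_five_five_diagonal(self):
        p, odds = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / math.comb(10, 5), abs=1e-12)
        assert math.isinf(odds)

    def test_matches_rational_enumeration_on_small_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            p, _ = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)

    def test_matches_scipy(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            t = rng.integers(0, 20, size=(2, 2))
            if t.sum() == 0:
                continue
            p, odds = fisher_exact_2x2(t)
            ref = sps.fisher_exact(t, alternative="two-sided")
            assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)

    def test_invariances(self):
        t = np.array([[7, 2], [3, 9]])
        p0, _ = fisher_exact_2x2(t)
        assert fisher_exact_2x2(t.T)[0] == pytest.approx(p0)
        assert fisher_exact_2x2(t[::-1, ::-1])[0] == pytest.approx(p0)

    def test_rejects_negative_cells(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestSpearman:
    def test_monotone_sequences(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_ties_match_midrank_pearson(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0, 9.0, 10.0, 11.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 4.0, 6.0, 7.0, 8.0, 8.0, 10.0, 12.0])
        rho, _ = spearman(x, y)
        ref = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho == pytest.approx(ref, abs=1e-12)

    def test_t_approximation_matches_scipy_at_large_n(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_small_n_p_is_permutation_fraction(self):
        x = [1, 2, 3, 4, 5]
        y = [1, 2, 3, 5, 4]
        _, p = spearman(x, y)
        # rho = 0.9; |rho| >= 0.9 for rho in {±1, ±0.9}: 1+4+4+1 = 10 of 120
        assert p == pytest.approx(10 / 120)

    def test_constant_input_undefined(self):
        rho, p = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)


class TestGoodmanKruskalTau:
    def test_perfect_nesting_gives_one(self):
        clade = ["c1", "c1", "c2", "c2", "c3", "c3"]
        ecotype = ["HL", "HL", "HL", "HL", "LL", "LL"]
        assert goodman_kruskal_tau(clade, ecotype) == pytest.approx(1.0)
        # the reverse direction only constrains, does not determine
        rev = goodman_kruskal_tau(ecotype, clade)
        assert 0 < rev < 1

    def test_independent_balanced_design_gives_zero(self):
        x = ["a", "a", "b", "b"]
        y = ["u", "v", "u", "v"]
        assert goodman_kruskal_tau(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_3x2_table(self):
        # contingency [[3,1],[0,2],[1,3]]: tau computed from the definition
        x = ["r1"] * 4 + ["r2"] * 2 + ["r3"] * 4
        y = ["c1"] * 3 + ["c2"] + ["c2"] * 2 + ["c1"] + ["c2"] * 3
        n = 10.0
        cond = (9 + 1) / 4 + (0 + 4) / 2 + (1 + 9) / 4
        marg = (16 + 36) / n
        expected = (cond - marg) / (n - marg)
        assert goodman_kruskal_tau(x, y) == pytest.approx(expected, abs=1e-12)

    def test_asymmetry(self):
        x = ["a", "a", "b", "b", "c", "c"]
        y = ["u", "u", "u", "u", "v", "v"]
        assert goodman_kruskal_tau(x, y) != pytest.approx(
            goodman_kruskal_tau(y, x))
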