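"""Change classification: probabilities, thresholds, community labels."""

import numpy as np
import pytest
from scipy import stats

from stepps.change import (
    ChangeThresholds,
    classify_community,
    classify_taxon,
    directional_probability,
    pairwise_diff,
    summarize_domain,
)
from stepps.prediction import PosteriorEnsemble


def _toy_ensemble(r):
    r = np.asarray(r, dtype=float)
    T = r.shape[2]
    edges = np.arange(150.0 + 100 * T, 149.0, -100.0)
    return PosteriorEnsemble(r=r, r_mean=r, bin_edges=edges,
                             taxa=tuple(f"t{k}" for k in range(r.shape[3])))


class TestPairwiseDiff:
    @pytest.fixture(scope="class")
    def ens(self):
        rng = np.random.default_rng(0)
        g = rng.dirichlet(np.ones(3), size=(5, 4, 2))  # (D, N, T=2) wrong order
        r = np.transpose(g, (0, 1, 2, 3))  # (D=5, N=4, T=2, K=3)
        return _toy_ensemble(r)

    def test_identical_times_rejected(self, ens):
        with pytest.raises(ValueError):
            pairwise_diff(ens, 1, 1)

    def test_antisymmetry_per_draw(self, ens):
        d12 = pairwise_diff(ens, 0, 1)
        d21 = pairwise_diff(ens, 1, 0)
        np.testing.assert_array_equal(d12, -d21)

    def test_hand_subtraction_on_three_draw_toy(self):
        r = np.zeros((3, 1, 2, 2))
        r[:, 0, 0, 0] = [0.2, 0.3, 0.4]
        r[:, 0, 1, 0] = [0.5, 0.1, 0.4]
        r[..., 1] = 1 - r[..., 0]
        d = pairwise_diff(_toy_ensemble(r), 0, 1)
        np.testing.assert_allclose(d[:, 0, 0], [0.3, -0.2, 0.0], atol=1e-15)

    def test_missing_bin_rejected(self, ens):
        with pytest.raises(ValueError, match="outside"):
            pairwise_diff(ens, 0, 9)


class TestDirectionalProbability:
    def test_all_positive(self):
        p_up, p_down = directional_probability(np.ones((10, 2)))
        assert np.all(p_up == 1.0) and np.all(p_down == 0.0)

    def test_symmetric_two_draws(self):
        p_up, p_down = directional_probability(np.array([[0.1], [-0.1]]))
        assert p_up[0] == 0.5 and p_down[0] == 0.5

    def test_counting_870_of_1000(self):
        d = np.concatenate([np.full(870, 0.01), np.full(130, -0.01)])[:, None]
        p_up, _ = directional_probability(d)
        assert p_up[0] == pytest.approx(0.87)
        assert p_up[0] >= 0.85  # significant at the published cutoff

    def test_ties_count_toward_neither(self):
        d = np.array([[0.0], [1.0], [-1.0], [0.0]])
        p_up, p_down = directional_probability(d)
        assert p_up[0] + p_down[0] == pytest.approx(0.5)

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError):
            directional_probability(np.ones((1, 3)))


class TestClassifyTaxon:
    def _flags(self, diffs, ab1, ab2):
        return classify_taxon(np.asarray(diffs, dtype=float)[:, None, None],
                              np.array([[ab1]]), np.array([[ab2]]))

    def test_large_and_significant_change(self):
        f = self._flags(np.full(100, 0.10), 0.20, 0.30)
        assert f.significant[0, 0] and f.large_change[0, 0] and not f.stable[0, 0]

    def test_ecological_filter_suppresses_rare_taxa(self):
        f = self._flags(np.full(100, 0.10), 0.01, 0.01)
        assert not f.significant[0, 0] and not f.large_change[0, 0]

    def test_small_changes_are_stable(self):
        f = self._flags(np.full(100, 0.01), 0.2, 0.21)
        assert f.stable[0, 0] and not f.large_change[0, 0]

    def test_large_and_stable_mutually_exclusive(self):
        rng = np.random.default_rng(0)
        diffs = rng.normal(0, 0.05, size=(400, 10, 3))
        f = classify_taxon(diffs, np.full((10, 3), 0.2), np.full((10, 3), 0.2))
        assert not np.any(f.large_change & f.stable)

    def test_montecarlo_tail_matches_closed_form(self):
        """Empirical P(|diff| > 0.05) on Normal draws matches the Normal tail
        within 3 Monte-Carlo standard errors at 10^4 draws."""
        rng = np.random.default_rng(1)
        mu, sd, n = 0.04, 0.03, 10_000
        draws = rng.normal(mu, sd, size=(n, 1, 1))
        p_emp = np.mean(np.abs(draws) > 0.05)
        p_true = stats.norm(mu, sd).sf(0.05) + stats.norm(mu, sd).cdf(-0.05)
        mc_se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(p_emp - p_true) < 3 * mc_se

    def test_invariant_to_draw_and_taxon_order(self):
        rng = np.random.default_rng(2)
        diffs = rng.normal(0.02, 0.04, size=(500, 4, 3))
        ab = np.full((4, 3), 0.2)
        f1 = classify_taxon(diffs, ab, ab)
        f2 = classify_taxon(diffs[::-1], ab, ab)
        np.testing.assert_array_equal(f1.significant, f2.significant)
        perm = [2, 0, 1]
        f3 = classify_taxon(diffs[:, :, perm], ab, ab)
        np.testing.assert_array_equal(f1.large_change[:, perm], f3.large_change)


class TestCommunity:
    def _flags_from(self, large, stable, mean_diff):
        from stepps.change import TaxonChangeFlags

        large = np.asarray(large, dtype=bool)[None, :]
        return TaxonChangeFlags(
            p_change=np.ones_like(large, dtype=float),
            direction=np.ones_like(large, dtype=int),
            significant=large,
            large_change=large,
            stable=np.asarray(stable, dtype=bool)[None, :],
            mean_diff=np.asarray(mean_diff, dtype=float)[None, :],
        )

    def test_single_large_taxon_dominates(self):
        f = self._flags_from([True, False, False], [False, True, True], [0.08, 0.0, 0.0])
        labels, dom = classify_community(f)
        assert labels[0] == "large_change" and dom[0] == 0

    def test_all_stable(self):
        f = self._flags_from([False] * 5, [True] * 5, [0.0] * 5)
        labels, dom = classify_community(f)
        assert labels[0] == "stable_all" and dom[0] == -1

    def test_dominant_by_absolute_mean_change(self):
        f = self._flags_from([True, True], [False, False], [0.06, -0.07])
        labels, dom = classify_community(f)
        assert labels[0] == "large_change" and dom[0] == 1

    def test_neither_when_mixed(self):
        f = self._flags_from([False, False], [True, False], [0.0, 0.02])
        labels, _ = classify_community(f)
        assert labels[0] == "neither"


class TestDomainSummary:
    def test_all_stable_grid(self):
        s = summarize_domain(np.array(["stable_all"] * 10))
        assert s == {"percent_unstable": 0.0, "percent_stable": 100.0}

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(["large_change", "stable_all", "neither"], size=100)
        s = summarize_domain(labels)
        brute_us = 100.0 * sum(1 for x in labels if x == "large_change") / 100
        brute_s = 100.0 * sum(1 for x in labels if x == "stable_all") / 100
        assert s["percent_unstable"] == brute_us
        assert s["percent_stable"] == brute_s

    def test_nine_of_hundred(self):
        labels = np.array(["large_change"] * 9 + ["neither"] * 91)
        s = summarize_domain(labels)
        assert s["percent_unstable"] == 9.0 and s["percent_stable"] == 0.0


class TestThreeWayRecount:
    def test_classification_matches_per_draw_brute_force(self):
        """Vectorized classification equals an explicit per-draw recount."""
        rng = np.random.default_rng(4)
        D, N, K = 800, 6, 4
        diffs = rng.normal(0.0, 0.06, size=(D, N, K)) + rng.normal(0, 0.04, size=(1, N, K))
        ab = np.full((N, K), 0.2)
        th = ChangeThresholds()
        f = classify_taxon(diffs, ab, ab, th)
        for s in range(N):
            for k in range(K):
                col = diffs[:, s, k]
                p_dir = max(np.mean(col > 0), np.mean(col < 0))
                sig = p_dir >= th.prob_cut
                large = np.mean(np.abs(col) > th.large_cut) >= th.prob_cut
                stable = np.mean(np.abs(col) < th.stability_cut) >= th.prob_cut
                assert f.significant[s, k] == sig
                assert f.large_change[s, k] == large
                assert f.stable[s, k] == stable
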