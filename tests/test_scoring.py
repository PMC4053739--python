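"""Hypergeometric tails, density z-scores, and the four enrichment criteria."""

import math

import numpy as np
import pytest

import motifdens as md
from motifdens.expression import NeighborGraph, Partition
from motifdens.motifs import PresenceMatrix
from motifdens.scoring import (DensityProfile, hyper_continuous_from_counts,
                               mi_continuous_from_counts,
                               neglog_hypergeom_upper_tail)


def exact_upper_tail(x, n, n_m, draw):
    """Binomial-coefficient enumeration oracle for P(X >= x)."""
    total = math.comb(n, draw)
    return sum(math.comb(n_m, j) * math.comb(n - n_m, draw - j)
               for j in range(max(x, 0), min(n_m, draw) + 1)) / total


class TestHypergeomTail:
    @pytest.mark.parametrize("x,n,n_m,draw,expect", [
        (0, 10, 4, 3, 1.0),
        (4, 10, 4, 3, 0.0),      # x > min(draw, n_m)
        (2, 10, 4, 3, 1 / 3),    # C(4,2)C(6,1)+C(4,3)C(6,0) over C(10,3)
    ])
    def test_examples(self, x, n, n_m, draw, expect):
        assert md.hypergeom_upper_tail(x, n, n_m, draw) == pytest.approx(expect)

    def test_matches_enumeration_small_n(self):
        rng = np.random.default_rng(0)
        for _ in range(400):
            n = int(rng.integers(1, 26))
            n_m = int(rng.integers(0, n + 1))
            draw = int(rng.integers(0, n + 1))
            x = int(rng.integers(0, draw + 2))
            assert md.hypergeom_upper_tail(x, n, n_m, draw) == pytest.approx(
                exact_upper_tail(x, n, n_m, draw), abs=1e-12)

    def test_neglog_safe_under_underflow(self):
        # linear-space tail underflows; log-space value must stay finite
        v = neglog_hypergeom_upper_tail(np.array([500]), 10000, 500, 500)
        assert np.isfinite(v).all() and v[0] > 700


class TestDensityZscore:
    def test_zero_at_expectation(self):
        assert md.density_zscore(2, 20, 10, 100) == pytest.approx(0.0)

    def test_worked_value(self):
        assert md.density_zscore(6, 20, 10, 100) == pytest.approx(3.3166, abs=1e-4)

    def test_sign_flips_around_expectation(self):
        assert md.density_zscore(1, 20, 10, 100) < 0 < md.density_zscore(3, 20, 10, 100)

    @pytest.mark.parametrize("n_m", [0, 100])
    def test_degenerate_presence_signalled(self, n_m):
        with pytest.raises(ValueError):
            md.density_zscore(5, 20, n_m, 100)


def _graph(neighbors, ids, k):
    return NeighborGraph(ids, [np.array(nb) for nb in neighbors], k, "balanced")


class TestDensityProfile:
    def test_hand_enumerated_counts(self):
        ids = ["a", "b", "c", "d"]
        g = _graph([[1, 2], [0, 3], [0, 1], [1, 2]], ids, 2)
        pm = PresenceMatrix(ids, np.array([True, True, False, False]))
        dp = md.density_profile(pm, g)
        assert list(dp.counts) == [1, 1, 2, 1]

    @pytest.mark.parametrize("presence,expect", [([True] * 4, 1.0), ([False] * 4, 0.0)])
    def test_saturated_presence(self, presence, expect):
        ids = list("abcd")
        g = _graph([[1, 2], [0, 3], [0, 1], [1, 2]], ids, 2)
        dp = md.density_profile(PresenceMatrix(ids, np.array(presence)), g)
        assert (dp.densities == expect).all()

    def test_universe_mismatch_rejected(self):
        g = _graph([[1], [0]], ["a", "b"], 1)
        pm = PresenceMatrix(["a", "x"], np.array([True, False]))
        with pytest.raises(ValueError):
            md.density_profile(pm, g)


class TestDiscreteScores:
    def test_hypergeometric_perfect_cluster(self):
        ids = [f"g{i}" for i in range(6)]
        pm = PresenceMatrix(ids, np.array([1, 1, 1, 0, 0, 0], dtype=bool))
        part = Partition(np.array([0, 0, 0, 1, 1, 1]), 2)
        sv = md.score_discrete(pm, part, "hypergeometric")
        assert sv.value == pytest.approx(-math.log(1 / 20))

    def test_mi_zero_when_motif_everywhere(self):
        ids = list("abcdef")
        pm = PresenceMatrix(ids, np.ones(6, dtype=bool))
        part = Partition(np.array([0, 0, 0, 1, 1, 1]), 2)
        assert md.score_discrete(pm, part, "mutual_information").value == 0.0

    def test_mi_one_bit_perfect_dependence(self):
        ids = list("abcdef")
        pm = PresenceMatrix(ids, np.array([1, 1, 1, 0, 0, 0], dtype=bool))
        part = Partition(np.array([0, 0, 0, 1, 1, 1]), 2)
        assert md.score_discrete(pm, part, "mutual_information").value == \
            pytest.approx(1.0)

    def test_empty_cluster_rejected(self):
        pm = PresenceMatrix(list("ab"), np.array([True, False]))
        with pytest.raises(ValueError):
            md.score_discrete(pm, Partition(np.array([0, 0]), 2), "hypergeometric")


class TestContinuousScores:
    def test_hypergeometric_worked_example(self):
        # n=6, k=2, one gene with both neighbors positive, n_m=2
        dp = DensityProfile(list("abcdef"), np.array([2, 0, 0, 1, 1, 0]), 2)
        sv = md.score_continuous(dp, n_m=2, n=6, criterion="hypergeometric")
        assert sv.value == pytest.approx(-math.log(1 / 15), abs=1e-9)

    def test_mi_one_bit_two_genes(self):
        dp = DensityProfile(["a", "b"], np.array([1, 0]), 1)
        sv = md.score_continuous(dp, n_m=1, n=2, criterion="mutual_information")
        assert sv.value == pytest.approx(1.0)

    def test_mi_zero_at_uniform_density(self):
        # every density equals the global frequency n_m/n
        dp = DensityProfile(list("abcd"), np.array([1, 1, 1, 1]), 2)
        sv = md.score_continuous(dp, n_m=2, n=4, criterion="mutual_information")
        assert sv.value == pytest.approx(0.0, abs=1e-12)

    def test_mi_nonnegative_random(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n, k = 30, 6
            counts = rng.integers(0, k + 1, size=n)
            n_m = int(rng.integers(1, n))
            v = mi_continuous_from_counts(counts, k, n_m, n)
            assert v >= 0

    def test_mi_degenerate_presence_scores_zero(self):
        dp = DensityProfile(list("abcd"), np.array([2, 2, 2, 2]), 2)
        assert md.score_continuous(dp, 4, 4, "mutual_information").value == 0.0

    def test_hyper_monotone_in_counts(self):
        base = np.array([3, 1, 0, 2, 1])
        lo = hyper_continuous_from_counts(base, 4, 6, 20)
        hi = hyper_continuous_from_counts(base + np.eye(5, dtype=int)[0], 4, 6, 20)
        assert hi >= lo

    def test_invariance_under_joint_permutation(self):
        rng = np.random.default_rng(2)
        n, k = 40, 5
        nb = [rng.choice([j for j in range(n) if j != i], k, replace=False)
              for i in range(n)]
        ids = [f"g{i}" for i in range(n)]
        g = _graph(nb, ids, k)
        pres = rng.random(n) < 0.3
        pm = PresenceMatrix(ids, pres)
        v0 = md.score_continuous(md.density_profile(pm, g), pm.n_m, n,
                                 "mutual_information").value
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        ids_p = [ids[i] for i in perm]
        g_p = _graph([inv[nb[i]] for i in perm], ids_p, k)
        pm_p = PresenceMatrix(ids_p, pres[perm])
        v1 = md.score_continuous(md.density_profile(pm_p, g_p), pm_p.n_m, n,
                                 "mutual_information").value
        assert v0 == pytest.approx(v1)
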