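"""Sign test, strand bias, positional histograms, heatmap, ranked genes."""

import math

import numpy as np
import pytest

import motifdens as md
from motifdens.motifs import Occurrence, PresenceMatrix
from motifdens.reports import (expression_heatmap, occurrence_distance,
                               position_histogram, ranked_gene_list, sign_test,
                               strand_bias)
from motifdens.scoring import DensityProfile


def exact_sign_test(wins, losses):
    """Exhaustive-outcome oracle: sum binomial pmf over both tails."""
    n = wins + losses
    pmf = [math.comb(n, j) / 2**n for j in range(n + 1)]
    up = sum(pmf[wins:])
    down = sum(pmf[: wins + 1])
    return min(1.0, 2 * min(up, down))


class TestSignTest:
    @pytest.mark.parametrize("wins,losses,expect,tol", [
        (18, 2, 0.0004, 5e-5),
        (17, 3, 0.003, 5e-4),
        (21, 3, 0.0003, 5e-5),
        (22, 0, 4.77e-7, 5e-9),
        (1, 1, 1.0, 0),
    ])
    def test_printed_values(self, wins, losses, expect, tol):
        assert sign_test(wins, losses) == pytest.approx(expect, abs=tol)

    def test_matches_exhaustive_enumeration(self):
        for n in range(1, 21):
            for wins in range(n + 1):
                assert sign_test(wins, n - wins) == pytest.approx(
                    exact_sign_test(wins, n - wins), abs=1e-12)

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            sign_test(0, 0)


def _occ(gene, start, end, strand):
    return Occurrence(gene, start, end, strand, "X" * (end - start), "")


class TestStrandBias:
    def test_balanced_counts(self):
        occs = [_occ("g", i, i + 2, "+") for i in range(10)] + \
               [_occ("g", i, i + 2, "-") for i in range(10)]
        p, _ = strand_bias(occs)
        assert p == 1.0

    def test_total_bias(self):
        occs = [_occ("g", i, i + 2, "+") for i in range(20)]
        p, direction = strand_bias(occs)
        assert p == pytest.approx(2 * 2**-20) and direction == "+"

    def test_majority_direction(self):
        occs = [_occ("g", 0, 2, "-")] * 3 + [_occ("g", 0, 2, "+")]
        assert strand_bias(occs)[1] == "-"

    def test_zero_occurrences_signalled(self):
        with pytest.raises(ValueError):
            strand_bias([])


class TestPositionHistogram:
    def test_upstream_distance_from_start_codon(self):
        rec = md.SequenceRecord("g", "A" * 100, "upstream")
        # flush against the 3' end (start codon) -> distance 0 -> bin 0
        occ = _occ("g", 94, 100, "+")
        assert occurrence_distance(occ, rec) == 0
        h = position_histogram([occ], [rec], "start_codon", 50)
        assert h["count"].iloc[0] == 1

    def test_downstream_distance_from_stop_codon(self):
        rec = md.SequenceRecord("g", "A" * 100, "downstream")
        occ = _occ("g", 0, 6, "+")
        assert occurrence_distance(occ, rec) == 0

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        rec = md.SequenceRecord("g", "A" * 300, "upstream")
        occs = [_occ("g", int(s), int(s) + 5, "+")
                for s in rng.integers(0, 295, size=57)]
        h = position_histogram(occs, [rec], "start_codon", 50)
        assert h["count"].sum() == 57

    def test_gene_counting_mode(self):
        rec = md.SequenceRecord("g", "A" * 100, "upstream")
        occs = [_occ("g", 90, 96, "+"), _occ("g", 92, 98, "+")]
        h_occ = position_histogram(occs, [rec], "start_codon", 50)
        h_gene = position_histogram(occs, [rec], "start_codon", 50,
                                    count_genes=True)
        assert h_occ["count"].sum() == 2 and h_gene["count"].sum() == 1

    def test_uniform_positions_flat(self):
        rng = np.random.default_rng(1)
        recs = [md.SequenceRecord(f"g{i}", "A" * 500, "upstream")
                for i in range(40)]
        occs = [_occ(f"g{rng.integers(40)}", int(s), int(s) + 5, "+")
                for s in rng.integers(0, 495, size=4000)]
        h = position_histogram(occs, recs, "start_codon", 50)
        counts = h["count"].to_numpy()[:10]
        assert counts.min() > 0.6 * counts.mean()


class TestExpressionHeatmap:
    def test_cell_sizes_sum_to_n(self):
        rng = np.random.default_rng(2)
        X = md.ExpressionMatrix([f"g{i}" for i in range(60)],
                                rng.normal(size=(60, 4)))
        pm = PresenceMatrix(X.gene_ids, rng.random(60) < 0.4)
        Z, sizes = expression_heatmap(pm, X, n_bins=5)
        assert (sizes.sum(axis=1) == 60).all()

    def test_concentrated_positives_hit_max_cell(self):
        n = 80
        ids = [f"g{i}" for i in range(n)]
        vals = np.linspace(0, 1, n)[:, None] * np.ones((1, 2))
        X = md.ExpressionMatrix(ids, vals)
        pres = np.zeros(n, dtype=bool)
        pres[-10:] = True  # all positives in the top expression bin
        Z, _ = expression_heatmap(PresenceMatrix(ids, pres), X, n_bins=4)
        assert np.nanargmax(Z[0]) == 3

    def test_cell_at_expectation_is_zero(self):
        n = 100
        ids = [f"g{i}" for i in range(n)]
        vals = np.repeat(np.arange(4), 25)[:, None].astype(float)
        X = md.ExpressionMatrix(ids, vals)
        pres = np.zeros(n, dtype=bool)
        pres[::5] = True  # exactly 5 positives per 25-gene cell = expectation
        Z, sizes = expression_heatmap(PresenceMatrix(ids, pres), X, n_bins=4)
        occupied = sizes[0] > 0
        assert np.allclose(Z[0][occupied], 0.0)

    def test_random_assignment_centered_on_zero(self):
        rng = np.random.default_rng(3)
        zs = []
        for s in range(15):
            X = md.ExpressionMatrix([f"g{i}" for i in range(100)],
                                    rng.normal(size=(100, 3)))
            pm = PresenceMatrix(X.gene_ids, rng.random(100) < 0.3)
            Z, _ = expression_heatmap(pm, X, n_bins=5)
            zs.append(np.nanmean(Z))
        assert abs(np.mean(zs)) < 0.3


class TestRankedGeneList:
    def _setup(self):
        n, k = 30, 4
        ids = [f"g{i:02d}" for i in range(n)]
        counts = np.concatenate([np.full(10, 4), np.full(10, 1), np.full(10, 0)])
        pres = counts > 0
        dp = DensityProfile(ids, counts, k)
        pm = PresenceMatrix(ids, pres)
        return dp, pm, n

    def test_length_is_n_m(self):
        dp, pm, n = self._setup()
        assert len(ranked_gene_list(dp, pm.n_m, n, pm)) == pm.n_m

    def test_sorted_by_zscore_and_matches_elementwise(self):
        dp, pm, n = self._setup()
        df = ranked_gene_list(dp, pm.n_m, n, pm)
        z = df["zscore"].to_numpy()
        assert (np.diff(z) <= 0).all()
        by_id = dict(zip(df.gene_id, df.zscore))
        for gid, c in zip(dp.gene_ids, dp.counts):
            if gid in by_id:
                assert by_id[gid] == pytest.approx(
                    float(md.density_zscore(int(c), dp.k, pm.n_m, n)))

    def test_equal_densities_equal_z(self):
        ids = list("abcd")
        dp = DensityProfile(ids, np.array([1, 1, 1, 1]), 2)
        pm = PresenceMatrix(ids, np.array([True, True, False, False]))
        df = ranked_gene_list(dp, 2, 4, pm)
        assert df["zscore"].nunique() == 1
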