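"""Local-species statistic, evaluation curve, L-method knee, ANOSIM."""

import numpy as np
import pytest
from scipy.stats import rankdata

import bioregions as br
from bioregions.evaluation import anosim_R_only


def matrix_from(rows, sites=None, species=None):
    inc = np.asarray(rows, dtype=bool)
    sites = sites or [f"s{i}" for i in range(inc.shape[0])]
    species = species or [f"x{j}" for j in range(inc.shape[1])]
    return br.OccurrenceMatrix(sites, species, inc)


class TestLocalSpecies:
    def test_single_cluster_everything_local(self, toy_matrix):
        part = br.Partition(toy_matrix.sites, [1, 1, 1])
        assert br.mean_local_fraction(toy_matrix, part) == 1.0

    def test_disjoint_clusters_fully_local(self):
        m = matrix_from([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]])
        part = br.Partition(m.sites, [1, 1, 2, 2])
        tab = br.local_species(m, part)
        assert (tab["proportion"] == 1.0).all()
        assert br.mean_local_fraction(m, part) == 1.0

    def test_hand_enumerated_shared_species(self):
        # A only cluster 1, B only cluster 2, C in both -> 1/2 and 1/2
        m = matrix_from([[1, 0, 1], [0, 1, 1]], species=["A", "B", "C"])
        part = br.Partition(m.sites, [1, 2])
        tab = br.local_species(m, part)
        assert list(tab["proportion"]) == [0.5, 0.5]
        assert br.mean_local_fraction(m, part) == 0.5

    def test_fully_shared_fauna_zero_local(self):
        m = matrix_from([[1, 1], [1, 1], [1, 1]])
        part = br.Partition(m.sites, [1, 2, 2])
        assert br.mean_local_fraction(m, part) == 0.0

    def test_speciesless_cluster_errors(self):
        m = br.OccurrenceMatrix(["a", "b"], ["x"], np.array([[1], [0]]))
        with pytest.raises(br.DataError):
            br.local_species(m, br.Partition(["a", "b"], [1, 2]))


class TestEvaluationCurve:
    def test_first_point_is_identity(self, default_fauna):
        matrix, _, sites, truth = default_fauna
        core = matrix.select_sites(truth.true_partition.sites)
        dend = br.agglomerate(br.pairwise(core))
        curve = br.evaluation_curve(core, dend, b=6)
        assert curve.y[0] == 1.0 and curve.k[0] == 1

    def test_last_point_at_k_n_matches_singleton_computation(self):
        rng = np.random.default_rng(20)
        from conftest import random_incidence
        inc = random_incidence(rng, 6, 40)
        m = matrix_from(inc)
        dend = br.agglomerate(br.pairwise(m))
        curve = br.evaluation_curve(m, dend, b=6)
        # direct computation: per singleton site, fraction of species unique to it
        occ = inc.sum(axis=0)
        expected = np.mean([(inc[i] & (occ == 1)).sum() / inc[i].sum()
                            for i in range(6)])
        assert curve.y[-1] == pytest.approx(expected)

    def test_disjoint_provinces_stay_at_one_until_split(self):
        blocks = [np.arange(0, 3), np.arange(3, 6), np.arange(6, 9)]
        inc = np.zeros((9, 30), dtype=bool)
        for b_i, rows in enumerate(blocks):
            inc[np.ix_(rows, np.arange(b_i * 10, (b_i + 1) * 10))] = \
                np.random.default_rng(b_i).random((3, 10)) < 0.9
        m = matrix_from(inc)
        dend = br.agglomerate(br.pairwise(m))
        curve = br.evaluation_curve(m, dend, b=6)
        assert np.allclose(curve.y[:3], 1.0)
        assert curve.y[3] < 1.0

    def test_max_clusters_paths(self, toy_dissimilarity):
        dend = br.agglomerate(toy_dissimilarity)
        with pytest.raises(br.DegeneracyError):
            br.max_clusters(dend, fraction=1.0)  # b=1: knee infeasible

    def test_max_clusters_from_height_cut(self, default_fauna):
        matrix, _, _, truth = default_fauna
        core = matrix.select_sites(truth.true_partition.sites)
        dend = br.agglomerate(br.pairwise(core))
        b = br.max_clusters(dend, 0.75)
        assert 5 <= b <= core.n_sites
        assert b == dend.cut_height_fraction(0.75).k


class TestLMethod:
    @staticmethod
    def two_line_curve(knee, b=20, y1=0.9, yk=0.12, right_slope=-0.004):
        k = np.arange(1, b + 1)
        left = yk + (y1 - yk) * (knee - k) / (knee - 1)
        right = yk + right_slope * (k - knee)
        return br.EvaluationCurve(k, np.where(k <= knee, left, right))

    def test_noiseless_knee_recovered_exactly(self):
        curve = self.two_line_curve(knee=7)
        res = br.l_method_knee(curve)
        assert res.c_star == 7
        t = res.rmse_total_by_c
        assert t.loc[t["c"] == 7, "rmse_total"].iloc[0] < 1e-10

    def test_flat_curve_tie_breaks_to_smallest_candidate(self):
        curve = br.EvaluationCurve(np.arange(1, 11), np.full(10, 0.4))
        assert br.l_method_knee(curve).c_star == 3

    def test_small_noise_keeps_knee(self):
        rng = np.random.default_rng(21)
        curve = self.two_line_curve(knee=7)
        noisy = br.EvaluationCurve(curve.k,
                                   np.clip(curve.y + rng.normal(0, 1e-3, 20), 0, 1))
        assert br.l_method_knee(noisy).c_star == 7

    def test_too_few_points_errors(self):
        with pytest.raises(br.DegeneracyError):
            br.l_method_knee(br.EvaluationCurve(np.arange(1, 5), np.ones(4)))


def block_dissimilarity(labels, low=0.1, high=0.9, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    n = len(labels)
    v = np.where(labels[:, None] == labels[None, :], low, high).astype(float)
    if jitter:
        noise = rng.normal(0, jitter, (n, n))
        v = np.clip(v + (noise + noise.T) / 2, 0.01, 0.99)
    np.fill_diagonal(v, 0.0)
    return br.DissimilarityMatrix([f"s{i}" for i in range(n)], v)


class TestAnosim:
    def test_complete_separation_gives_R_one(self):
        labels = [1] * 5 + [2] * 5
        D = block_dissimilarity(labels, jitter=0.02, seed=1)
        res = br.anosim(D, br.Partition(D.sites, labels), n_permutations=99, seed=0)
        assert res.R == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_site_order_permutation_leaves_R_unchanged(self):
        labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        D = block_dissimilarity(labels, jitter=0.05, seed=2)
        R1 = anosim_R_only(D, br.Partition(D.sites, labels))
        rng = np.random.default_rng(3)
        perm = rng.permutation(9)
        D2 = br.DissimilarityMatrix([D.sites[i] for i in perm],
                                    D.values[np.ix_(perm, perm)])
        R2 = anosim_R_only(D2, br.Partition(D2.sites, labels[perm]))
        assert R2 == pytest.approx(R1)

    def test_singleton_cluster_rejected(self):
        D = block_dissimilarity([1, 1, 1, 2], jitter=0.02)
        with pytest.raises(br.DataError):
            br.anosim(D, br.Partition(D.sites, [1, 1, 1, 2]), seed=0)

    def test_R_bounds_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            n = int(rng.integers(6, 14))
            v = rng.random((n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            D = br.DissimilarityMatrix([f"s{i}" for i in range(n)], v)
            labels = rng.integers(1, 3, n)
            if min(np.bincount(labels)[1:]) < 2 or len(set(labels)) < 2:
                continue
            R = anosim_R_only(D, br.Partition(D.sites, labels))
            assert -1 - 1e-9 <= R <= 1 + 1e-9

    def test_reproducible_given_seed(self):
        labels = [1, 1, 1, 2, 2, 2]
        D = block_dissimilarity(labels, jitter=0.1, seed=5)
        p = br.Partition(D.sites, labels)
        r1 = br.anosim(D, p, n_permutations=199, seed=42)
        r2 = br.anosim(D, p, n_permutations=199, seed=42)
        assert r1.p_value == r2.p_value

    def test_matches_scikit_bio(self):
        """Independent cross-check of the R statistic against scikit-bio."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        labels = np.array([1, 1, 1, 1, 2, 2, 2, 3, 3, 3])
        D = block_dissimilarity(labels, jitter=0.15, seed=6)
        ours = anosim_R_only(D, br.Partition(D.sites, labels))
        dm = skbio_stats.DistanceMatrix(D.values, ids=D.sites)
        theirs = skbio_stats.anosim(dm, list(map(str, labels)), permutations=0)
        assert ours == pytest.approx(theirs["test statistic"], abs=1e-12)


class TestRefinement:
    def test_fixed_point_unchanged(self):
        labels = [1, 1, 1, 2, 2, 2, 3, 3, 3]
        D = block_dissimilarity(labels, jitter=0.02, seed=7)
        part = br.Partition(D.sites, labels)
        assert br.refine_partition_anosim(D, part) == part

    def test_mislabeled_site_returned_to_its_block(self):
        true = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        D = block_dissimilarity(true, jitter=0.02, seed=8)
        wrong = true.copy()
        wrong[0] = 2
        refined = br.refine_partition_anosim(D, br.Partition(D.sites, wrong))
        np.testing.assert_array_equal(
            refined.relabeled_like(D.sites),
            br.Partition(D.sites, true).labels)

    def test_zero_iterations_returns_input(self):
        labels = [1, 1, 2, 2]
        D = block_dissimilarity(labels, jitter=0.02, seed=9)
        part = br.Partition(D.sites, labels)
        assert br.refine_partition_anosim(D, part, max_iter=0) == part


class TestOptimalPartition:
    def test_recovers_default_fauna(self, fitted_default):
        res, truth = fitted_default
        assert res.k == 3
        assert br.truth_recovery_score(res.partition, truth) == 1.0

    def test_weak_structure_warns(self):
        """When the dissimilarities used for the ANOSIM cross-check carry no
        signal for the selected partition, the fit warns."""
        rng = np.random.default_rng(22)
        from conftest import random_incidence
        inc = random_incidence(rng, 14, 120, p=0.5)
        m = matrix_from(inc)
        dend = br.agglomerate(br.pairwise(m))
        noise = rng.random((14, 14))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        D_noise = br.DissimilarityMatrix([f"s{i}" for i in range(14)], noise)
        with pytest.warns(UserWarning, match="weak structure"):
            part, curve, knee, ares = br.optimal_partition(
                m, D_noise, dend, n_permutations=199, seed=0)
        assert ares.p_value > 0.05

    def test_mid_rank_ties_match_rankdata(self):
        # tie handling sanity: constant D gives R exactly 0
        v = np.full((8, 8), 0.5)
        np.fill_diagonal(v, 0)
        D = br.DissimilarityMatrix([f"s{i}" for i in range(8)], v)
        labels = [1, 1, 1, 1, 2, 2, 2, 2]
        assert anosim_R_only(D, br.Partition(D.sites, labels)) == pytest.approx(0.0)
        assert rankdata(D.condensed()).mean() == pytest.approx((len(D.condensed()) + 1) / 2)
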