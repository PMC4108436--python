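"""Faunal subset selection, batch pipeline runs, and cluster summaries."""

import numpy as np
import pandas as pd
import pytest

import bioregions as br
from bioregions.subsets import ENDEMISM_SLICES, SubsetSpec


@pytest.fixture()
def depth_fixture():
    inc = np.ones((4, 3), dtype=bool)
    m = br.OccurrenceMatrix([f"s{i}" for i in range(4)], ["shallow", "mid", "deep"], inc)
    traits = br.SpeciesTraits(pd.DataFrame({
        "species_id": ["shallow", "mid", "deep"],
        "depth_max_m": [10.0, 30.0, 60.0],
    }))
    return m, traits


class TestSelectSubset:
    def test_all_is_identity(self, toy_matrix):
        traits = br.SpeciesTraits(pd.DataFrame({"species_id": toy_matrix.species}))
        assert br.select_subset(toy_matrix, traits, SubsetSpec("all")) == toy_matrix

    def test_habitat_filter(self, toy_matrix):
        traits = br.SpeciesTraits(pd.DataFrame({
            "species_id": toy_matrix.species,
            "habitat": ["reef", "reef", "pelagic", "soft_bottom"],
        }))
        sub = br.select_subset(toy_matrix, traits,
                               SubsetSpec("reef", habitat=frozenset({"reef"})))
        assert sub.species == ["sp1", "sp2"]

    def test_depth_rules(self, depth_fixture):
        m, traits = depth_fixture
        shallow = br.select_subset(m, traits, SubsetSpec("sh", depth_rule="shallow_le_20m"))
        deep = br.select_subset(m, traits, SubsetSpec("dp", depth_rule="deep_gt_50m"))
        assert shallow.species == ["shallow"]
        assert deep.species == ["deep"]  # the 30 m species matches neither rule

    def test_species_without_depth_excluded_from_depth_subsets(self, depth_fixture):
        m, traits = depth_fixture
        t = br.SpeciesTraits(traits.df.assign(
            depth_max_m=[10.0, np.nan, 60.0]))
        shallow = br.select_subset(m, t, SubsetSpec("sh", depth_rule="shallow_le_20m"))
        assert shallow.species == ["shallow"]

    def test_empty_subset_errors_with_name(self, toy_matrix):
        traits = br.SpeciesTraits(pd.DataFrame({"species_id": toy_matrix.species}))
        with pytest.raises(br.DataError, match="nothing_here"):
            br.select_subset(toy_matrix, traits,
                             SubsetSpec("nothing_here", salinity="non_marine"))

    def test_emptied_sites_dropped_with_warning(self):
        inc = np.array([[1, 0], [0, 1]], dtype=bool)
        m = br.OccurrenceMatrix(["a", "b"], ["reefish", "pelagish"], inc)
        traits = br.SpeciesTraits(pd.DataFrame({
            "species_id": ["reefish", "pelagish"],
            "habitat": ["reef", "pelagic"]}))
        with pytest.warns(UserWarning, match="empty sites"):
            sub = br.select_subset(m, traits, SubsetSpec("reef", habitat=frozenset({"reef"})))
        assert sub.sites == ["a"]

    def test_spec_without_filters_rejected(self):
        with pytest.raises(br.DataError):
            SubsetSpec("oops")


class TestRunAllSubsets:
    def test_grid_of_result_sets(self, default_fauna):
        matrix, traits, sites, truth = default_fauna
        core = matrix.select_sites(truth.true_partition.sites)
        results = br.run_all_subsets(core, traits, n_permutations=99, seed=5)
        assert len(results) == 15  # 5 groups x 3 endemism slices
        assert {r.endemism_slice for r in results.values()} == set(ENDEMISM_SLICES)
        # whole-fauna slice must succeed and match a direct pipeline run
        whole = results[("all", "all")]
        assert whole.ok
        direct = br.Bioregionalization(core, traits).fit(n_permutations=99, seed=5)
        assert whole.partition == direct.partition

    def test_failures_recorded_batch_continues(self, default_fauna):
        matrix, traits, sites, truth = default_fauna
        core = matrix.select_sites(truth.true_partition.sites)
        groups = (SubsetSpec("all"),
                  SubsetSpec("reef", habitat=frozenset({"reef"})))
        # non_marine slice of a marine-only fauna must fail cleanly
        groups = groups + (SubsetSpec("non_marine", salinity="non_marine"),)
        results = br.run_all_subsets(core, traits, groups=groups,
                                     n_permutations=99, seed=5)
        assert len(results) == 9
        assert not results[("non_marine", "all")].ok
        assert results[("all", "all")].ok

    def test_deterministic_given_seed(self, default_fauna):
        matrix, traits, _, truth = default_fauna
        core = matrix.select_sites(truth.true_partition.sites)
        groups = (SubsetSpec("reef", habitat=frozenset({"reef"})),)
        r1 = br.run_all_subsets(core, traits, groups=groups, n_permutations=99, seed=2)
        r2 = br.run_all_subsets(core, traits, groups=groups, n_permutations=99, seed=2)
        k = ("reef", "all")
        assert r1[k].partition == r2[k].partition
        assert r1[k].anosim.p_value == r2[k].anosim.p_value


class TestClusterSummaries:
    def test_disjoint_two_cluster_fixture(self):
        inc = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], bool)
        m = br.OccurrenceMatrix([f"s{i}" for i in range(4)],
                                [f"x{j}" for j in range(4)], inc)
        part = br.Partition(m.sites, [1, 1, 2, 2])
        summ = br.cluster_summaries(m, part)
        assert (summ.per_cluster["pct_local"] == 100.0).all()
        assert summ.pct_shared == 0.0

    def test_85_of_100_species_span_clusters(self):
        # 85 species in both clusters, 15 confined -> 85% shared
        inc = np.zeros((4, 100), dtype=bool)
        inc[:, :85] = True
        inc[:2, 85:93] = True
        inc[2:, 93:] = True
        m = br.OccurrenceMatrix([f"s{i}" for i in range(4)],
                                [f"x{j}" for j in range(100)], inc)
        summ = br.cluster_summaries(m, br.Partition(m.sites, [1, 1, 2, 2]))
        assert summ.pct_shared == pytest.approx(85.0)

    def test_endemics_concentrate_where_they_occur(self):
        inc = np.array([[1, 1, 1, 0], [1, 1, 1, 0], [0, 0, 1, 1], [0, 0, 1, 1]], bool)
        m = br.OccurrenceMatrix([f"s{i}" for i in range(4)],
                                ["e1", "e2", "wide", "n1"], inc)
        traits = br.SpeciesTraits(pd.DataFrame({
            "species_id": ["e1", "e2", "wide", "n1"],
            "endemic": ["regional_endemic", "regional_endemic",
                        "non_endemic", "non_endemic"]}))
        summ = br.cluster_summaries(m, br.Partition(m.sites, [1, 1, 2, 2]), traits)
        per = summ.per_cluster.set_index("cluster")
        assert per.loc[1, "n_endemic"] == 2 and per.loc[2, "n_endemic"] == 0

    def test_max_between_cluster_dissimilarity_reported(self, toy_matrix):
        D = br.pairwise(toy_matrix)
        part = br.Partition(toy_matrix.sites, [1, 1, 2])
        summ = br.cluster_summaries(toy_matrix, part, D=D)
        between = max(D.loc("A", "C"), D.loc("B", "C"))
        assert summ.max_between_dissimilarity == pytest.approx(between)

    def test_local_counts_sum_bound(self, default_fauna):
        matrix, _, _, truth = default_fauna
        core = matrix.select_sites(truth.true_partition.sites)
        summ = br.cluster_summaries(core, truth.true_partition)
        assert summ.per_cluster["n_local"].sum() <= core.n_species
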