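"""Faunal-subset batch analysis and per-cluster summary statistics.

The whole fauna and five trait-defined sub-groups (reef, soft-bottom and
pelagic habitat guilds; exclusively marine; non-marine) are each analyzed in
three endemism slices (all species, regional endemics, non-endemics), giving
the grid of result bundles the study design calls for. Depth-defined subsets
(shallow: depth_max <= 20 m; deep: depth_max > 50 m) test whether species
with or without a thermal refuge in deep water partition the sites the same
way.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .clustering import Partition, agglomerate
from .datamodel import OccurrenceMatrix, SpeciesTraits
from .dissimilarity import DissimilarityMatrix, pairwise
from .errors import BioregionsError, DataError
from .evaluation import cluster_presence, local_species, optimal_partition

logger = logging.getLogger(__name__)

DEPTH_RULES = ("shallow_le_20m", "deep_gt_50m")


@dataclass(frozen=True)
class SubsetSpec:
    """A named species filter over trait columns."""

    name: str
    habitat: frozenset | None = None       # subset of habitat classes
    salinity: str | None = None
    endemism: str | None = None
    depth_rule: str | None = None

    def __post_init__(self) -> None:
        if self.depth_rule is not None and self.depth_rule not in DEPTH_RULES:
            raise DataError(f"unknown depth rule {self.depth_rule!r}")
        if (self.name != "all" and self.habitat is None and self.salinity is None
                and self.endemism is None and self.depth_rule is None):
            raise DataError(f"subset {self.name!r} sets no filter")


DEFAULT_GROUPS: tuple[SubsetSpec, ...] = (
    SubsetSpec("all"),
    SubsetSpec("reef", habitat=frozenset({"reef"})),
    SubsetSpec("soft_bottom", habitat=frozenset({"soft_bottom"})),
    SubsetSpec("pelagic", habitat=frozenset({"pelagic"})),
    SubsetSpec("marine", salinity="marine"),
)

ENDEMISM_SLICES = ("all", "regional_endemic", "non_endemic")


def select_subset(matrix: OccurrenceMatrix, traits: SpeciesTraits,
                  spec: SubsetSpec) -> OccurrenceMatrix:
    """Columns matching the subset's filters; sites emptied by the filter are
    dropped with a warning (the effective site set shrinks for sparse
    faunal groups such as non-marine species)."""
    t = traits.aligned_to(matrix.species)
    keep = np.ones(matrix.n_species, dtype=bool)
    if spec.habitat is not None:
        keep &= t["habitat"].isin(spec.habitat).to_numpy()
    if spec.salinity is not None:
        keep &= (t["salinity"] == spec.salinity).to_numpy()
    if spec.endemism is not None:
        keep &= (t["endemic"] == spec.endemism).to_numpy()
    if spec.depth_rule is not None:
        depth = t["depth_max_m"].to_numpy(dtype=float)
        known = ~np.isnan(depth)
        n_missing = int((~known & keep).sum())
        if n_missing:
            logger.info("subset %s: excluding %d species lacking depth data",
                        spec.name, n_missing)
        if spec.depth_rule == "shallow_le_20m":
            keep &= known & (depth <= 20)
        else:
            keep &= known & (depth > 50)
    if not keep.any():
        raise DataError(f"subset {spec.name!r} selects no species")
    sub = matrix.select_species([s for s, k in zip(matrix.species, keep) if k])
    return sub.drop_empty()


@dataclass
class ClusterSummary:
    """Per-cluster species counts with local and endemic percentages."""

    cluster: int
    n_species: int
    n_local: int
    pct_local: float
    n_endemic: int
    pct_endemic: float


@dataclass
class SummaryTable:
    per_cluster: pd.DataFrame
    max_between_dissimilarity: float | None
    pct_shared: float  # % of species present in >= 2 clusters

    def to_json_dict(self) -> dict:
        return {
            "per_cluster": self.per_cluster.to_dict(orient="records"),
            "max_between_dissimilarity": self.max_between_dissimilarity,
            "pct_shared": self.pct_shared,
        }


def cluster_summaries(matrix: OccurrenceMatrix, partition: Partition,
                      traits: SpeciesTraits | None = None,
                      D: DissimilarityMatrix | None = None) -> SummaryTable:
    """Per-cluster species / local / endemic counts, the maximum pairwise
    dissimilarity between sites of different clusters, and the percentage of
    species present in two or more clusters."""
    loc = local_species(matrix, partition)
    P = cluster_presence(matrix, partition)
    occupancy = P.sum(axis=0)
    pct_shared = 100.0 * float((occupancy >= 2).sum()) / matrix.n_species

    if traits is not None:
        t = traits.aligned_to(matrix.species)
        endemic = (t["endemic"] == "regional_endemic").to_numpy()
    else:
        endemic = np.zeros(matrix.n_species, dtype=bool)
    n_endemic = (P & endemic[None, :]).sum(axis=1)

    df = pd.DataFrame({
        "cluster": loc["cluster"],
        "n_species": loc["n_total"],
        "n_local": loc["n_local"],
        "pct_local": 100.0 * loc["proportion"],
        "n_endemic": n_endemic,
        "pct_endemic": 100.0 * n_endemic / loc["n_total"].to_numpy(),
    })

    max_between = None
    if D is not None:
        labels = partition.relabeled_like(D.sites)
        between = labels[:, None] != labels[None, :]
        if between.any():
            max_between = float(D.values[between].max())
    return SummaryTable(df, max_between, pct_shared)


@dataclass
class SubsetResult:
    """One subset x endemism-slice pipeline outcome (or recorded failure)."""

    group: str
    endemism_slice: str
    ok: bool
    error: str | None = None
    matrix: OccurrenceMatrix | None = None
    D: DissimilarityMatrix | None = None
    dendrogram: object | None = None
    partition: Partition | None = None
    curve: object | None = None
    knee: object | None = None
    anosim: object | None = None
    summary: SummaryTable | None = None
    log: dict = field(default_factory=dict)


def run_all_subsets(matrix: OccurrenceMatrix, traits: SpeciesTraits, *,
                    groups: Iterable[SubsetSpec] = DEFAULT_GROUPS,
                    metric: str = "beta_sim", linkage: str = "average",
                    max_height_fraction: float = 0.75, k_start: int = 1,
                    n_permutations: int = 999, seed: int | None = None,
                    ) -> dict[tuple[str, str], SubsetResult]:
    """Run the full pipeline for every (group, endemism slice) combination.

    Per-subset failures (e.g. a slice left with too few sites) are recorded in
    the returned bundle; the batch continues. Results are independent across
    subsets, so execution order never changes any result.
    """
    results: dict[tuple[str, str], SubsetResult] = {}
    for group in groups:
        for sl in ENDEMISM_SLICES:
            spec = group if sl == "all" else SubsetSpec(
                name=f"{group.name}:{sl}", habitat=group.habitat,
                salinity=group.salinity, endemism=sl, depth_rule=group.depth_rule)
            key = (group.name, sl)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sub = select_subset(matrix, traits, spec)
                    if sub.n_sites < 5:
                        raise DataError(
                            f"subset {spec.name}: only {sub.n_sites} non-empty sites")
                    D = pairwise(sub, metric)
                    dend = agglomerate(D, linkage)
                    part, curve, knee, ares = optimal_partition(
                        sub, D, dend, max_height_fraction=max_height_fraction,
                        k_start=k_start, n_permutations=n_permutations, seed=seed)
                    summary = cluster_summaries(sub, part, traits, D)
                results[key] = SubsetResult(
                    group=group.name, endemism_slice=sl, ok=True, matrix=sub,
                    D=D, dendrogram=dend, partition=part, curve=curve, knee=knee,
                    anosim=ares, summary=summary,
                    log={"n_sites": sub.n_sites, "n_species": sub.n_species,
                         "n_sites_dropped": matrix.n_sites - sub.n_sites,
                         "k": part.k})
            except BioregionsError as exc:
                logger.warning("subset %s/%s failed: %s", group.name, sl, exc)
                results[key] = SubsetResult(group=group.name, endemism_slice=sl,
                                            ok=False, error=str(exc))
    return results
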