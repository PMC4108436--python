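"""Model/Results interface to the bioregionalization pipeline.

:class:`Bioregionalization` is built from an occurrence matrix (optionally
with traits and a site table); :meth:`Bioregionalization.fit` runs
dissimilarity -> hierarchical clustering -> evaluation curve -> L-method knee
-> ANOSIM and returns a :class:`BioregionalizationResults` carrying the
selected partition, the full diagnostics, and reporting helpers
(:meth:`~BioregionalizationResults.summary`, cluster summary tables, the
ecoregion cut, plots, and file export).

Three method combinations are supported for cross-checking:

========================  =======================================
``fit()``                 beta-sim + evaluation curve (default)
``fit(selector="anosim")``  cluster count and membership chosen by
                          maximizing ANOSIM R over dendrogram cuts,
                          then greedy refinement
``metric="bray_curtis_pa"``  Bray-Curtis on presence/absence
========================  =======================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import Dendrogram, Partition, agglomerate
from .datamodel import OccurrenceMatrix, SiteTable, SpeciesTraits
from .dissimilarity import DissimilarityMatrix, pairwise
from .errors import ConfigurationError
from .evaluation import (AnosimResult, EvaluationCurve, KneeResult, anosim,
                         anosim_R_only, evaluation_curve, l_method_knee,
                         max_clusters, refine_partition_anosim)
from .subsets import SummaryTable, cluster_summaries


class Bioregionalization:
    """Hierarchical bioregionalization of a presence/absence fauna.

    Parameters
    ----------
    matrix : OccurrenceMatrix
        Sites x species incidence; every site must host >= 1 species.
    traits : SpeciesTraits, optional
        Used for endemism counts in summaries.
    sites : SiteTable, optional
        When given, analysis is restricted to core-region sites (the ordered
        study sections); adjacent non-core sites only inform endemism
        classification.
    metric : {"beta_sim", "sorensen", "bray_curtis_pa"}
    linkage : {"average", "complete"}
    """

    def __init__(self, matrix: OccurrenceMatrix, traits: SpeciesTraits | None = None,
                 sites: SiteTable | None = None, *, metric: str = "beta_sim",
                 linkage: str = "average", max_height_fraction: float = 0.75,
                 k_start: int = 1):
        if sites is not None:
            core = [s for s in sites.site_ids if sites.core_flags[s] and s in matrix.sites]
            matrix = matrix.select_sites(core).drop_empty(warn=False)
        self.matrix = matrix
        self.traits = traits
        self.sites = sites
        self.metric = metric
        self.linkage = linkage
        self.max_height_fraction = max_height_fraction
        self.k_start = k_start

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "Bioregionalization":
        """Build from a 0/1 DataFrame with sites as index, species as columns."""
        return cls(OccurrenceMatrix.from_frame(df.astype(bool)), **kwargs)

    def fit(self, *, selector: str = "evaluation_curve", n_permutations: int = 999,
            seed: int | None = None, max_refine_iter: int = 20,
            ) -> "BioregionalizationResults":
        """Run the pipeline and return a results object.

        ``selector="evaluation_curve"`` picks the cluster count at the
        L-method knee of the local-species curve; ``selector="anosim"`` picks
        the dendrogram cut maximizing ANOSIM R and refines membership
        greedily (a surrogate for similarity-only selection).
        """
        D = pairwise(self.matrix, self.metric)
        dend = agglomerate(D, self.linkage)
        b = max_clusters(dend, self.max_height_fraction)
        curve = evaluation_curve(self.matrix, dend, b, k_start=self.k_start)
        knee = l_method_knee(curve)

        if selector == "evaluation_curve":
            part = dend.cut_k(knee.c_star)
            refined_from = None
        elif selector == "anosim":
            # Major clusters by similarity alone: walk the dendrogram cuts from
            # coarse to fine and stop at the first local maximum of R — the
            # point where splitting further no longer improves separation.
            candidates = []
            for k in range(2, b + 1):
                p = dend.cut_k(k)
                sizes = np.bincount(p.labels)[1:]
                if (sizes >= 2).all():
                    candidates.append((anosim_R_only(D, p), p))
            if not candidates:
                raise ConfigurationError("no dendrogram cut with all clusters >= 2 sites")
            start = candidates[-1][1]
            for (r, p), (r_next, _) in zip(candidates, candidates[1:]):
                if r >= r_next - 1e-12:
                    start = p
                    break
            refined_from = start
            part = refine_partition_anosim(D, start, max_iter=max_refine_iter)
        else:
            raise ConfigurationError(f"unknown selector {selector!r}")

        ares = anosim(D, part, n_permutations=n_permutations, seed=seed)
        return BioregionalizationResults(
            model=self, D=D, dendrogram=dend, curve=curve, knee=knee,
            partition=part, anosim_result=ares, selector=selector,
            refined_from=refined_from, seed=seed)


@dataclass
class BioregionalizationResults:
    """Fitted bioregionalization: partition, diagnostics and reports."""

    model: Bioregionalization
    D: DissimilarityMatrix
    dendrogram: Dendrogram
    curve: EvaluationCurve
    knee: KneeResult
    partition: Partition
    anosim_result: AnosimResult
    selector: str
    refined_from: Partition | None = None
    seed: int | None = None

    @property
    def k(self) -> int:
        return self.partition.k

    def cluster_summary(self) -> SummaryTable:
        return cluster_summaries(self.model.matrix, self.partition,
                                 self.model.traits, self.D)

    def ecoregions(self, fraction: float = 1 / 3) -> Partition:
        """Fine-scale subdivision: cut the dendrogram at ``fraction`` of its
        maximum dissimilarity (default one third)."""
        return self.dendrogram.cut_height_fraction(fraction)

    def summary(self) -> str:
        """Human-readable report of the fit."""
        s = self.cluster_summary()
        lines = [
            "Bioregionalization results",
            "==========================",
            f"metric: {self.D.metric_name}   linkage: {self.model.linkage}   "
            f"selector: {self.selector}",
            f"sites: {self.model.matrix.n_sites}   species: {self.model.matrix.n_species}",
            f"max clusters considered (75% height cut): b = {self.curve.b}",
            f"optimal number of clusters: k = {self.k}"
            + (f" (L-method knee, RMSE={self._knee_rmse():.4g})"
               if self.selector == "evaluation_curve" else " (max-R ANOSIM selection)"),
            f"ANOSIM: R = {self.anosim_result.R:.3f}, "
            f"p = {self.anosim_result.p_value:.4f} "
            f"({self.anosim_result.n_permutations} permutations)",
            f"species shared by >=2 clusters: {s.pct_shared:.1f}%",
            "",
            s.per_cluster.round(1).to_string(index=False),
            "",
            f"ecoregions at 1/3 max height: {self.ecoregions().k} clusters",
        ]
        return "\n".join(lines)

    def _knee_rmse(self) -> float:
        t = self.knee.rmse_total_by_c
        return float(t.loc[t["c"] == self.knee.c_star, "rmse_total"].iloc[0])

    # -- plots (never load-bearing) ----------------------------------------

    def plot_curve(self, ax=None):
        """Evaluation curve with the fitted L-method lines and the knee."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.curve.k, self.curve.y, "o-", label="mean local fraction")
        c = self.knee.c_star
        k = self.curve.k
        sl, il = self.knee.left_fit
        sr, ir = self.knee.right_fit
        ax.plot(k[k <= c], sl * k[k <= c] + il, "--", label="left fit")
        ax.plot(k[k >= c], sr * k[k >= c] + ir, "--", label="right fit")
        ax.axvline(c, color="grey", lw=0.8)
        ax.set_xlabel("number of clusters k")
        ax.set_ylabel("mean local-species proportion")
        ax.legend()
        return ax

    def plot_dendrogram(self, ax=None):
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        scipy_dendrogram(self.dendrogram.merges, labels=self.dendrogram.leaves,
                         ax=ax, leaf_rotation=90)
        ax.set_ylabel(f"{self.D.metric_name} dissimilarity")
        return ax

    # -- export -------------------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        """Write the full results bundle (CSV/JSON/Newick) plus a manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.D.to_csv(out / "dissimilarity.csv")
        self.dendrogram.write_newick(out / "dendrogram.nwk")
        self.curve.to_csv(out / "evaluation_curve.csv")
        self.partition.to_csv(out / "partition.csv")
        self.ecoregions().to_csv(out / "ecoregions.csv")
        (out / "knee.json").write_text(json.dumps(self.knee.to_json_dict(), indent=2))
        (out / "anosim.json").write_text(json.dumps(self.anosim_result.to_json_dict(), indent=2))
        (out / "cluster_summary.json").write_text(
            json.dumps(self.cluster_summary().to_json_dict(), indent=2, default=float))
        manifest = {
            "metric": self.D.metric_name,
            "linkage": self.model.linkage,
            "selector": self.selector,
            "selector_note": ("greedy max-R refinement is a surrogate for "
                              "similarity-only cluster selection"
                              if self.selector == "anosim" else "L-method knee"),
            "k": self.k,
            "b": self.curve.b,
            "k_start": self.curve.k_start,
            "max_height_fraction": self.model.max_height_fraction,
            "n_permutations": self.anosim_result.n_permutations,
            "seed": self.seed,
            "n_sites": self.model.matrix.n_sites,
            "n_species": self.model.matrix.n_species,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
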