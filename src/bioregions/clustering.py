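"""Agglomerative clustering of sites, dendrogram cuts, and Newick export.

UPGMA (average linkage) is the default: it is the standard choice in
regionalization analyses of assemblage dissimilarities and yields ultrametric
trees with monotone merge heights. Complete linkage is available for
sensitivity analysis. Ward linkage is deliberately not offered — it assumes
Euclidean geometry, which beta-sim dissimilarities do not have.

Dendrograms are stored as a scipy-style merge table over ordered leaves, cut
either to an exact number of clusters (:meth:`Dendrogram.cut_k`, nested
across k) or at a fraction of the maximum merge height
(:meth:`Dendrogram.cut_height_fraction`, used both for the 75% cap on
candidate cluster counts and for the 1/3-height ecoregion cut).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .dissimilarity import DissimilarityMatrix
from .errors import ConfigurationError, DataError

LINKAGES = ("average", "complete")


@dataclass
class Partition:
    """Assignment of sites to clusters labeled contiguously 1..k.

    Labels are renumbered by order of first appearance along the site order,
    so equal partitions of the same site list compare equal.
    """

    sites: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if lab.shape != (len(self.sites),):
            raise DataError("one label per site required")
        # renumber to 1..k by first appearance
        order: dict[int, int] = {}
        for v in lab:
            if v not in order:
                order[v] = len(order) + 1
        self.labels = np.array([order[v] for v in lab], dtype=int)

    @property
    def k(self) -> int:
        return int(self.labels.max())

    @property
    def assignment(self) -> dict[str, int]:
        return dict(zip(self.sites, (int(v) for v in self.labels)))

    def members(self, label: int) -> list[str]:
        return [s for s, v in zip(self.sites, self.labels) if v == label]

    def cluster_indices(self) -> dict[int, np.ndarray]:
        return {lab: np.flatnonzero(self.labels == lab) for lab in range(1, self.k + 1)}

    def relabeled_like(self, sites: list[str]) -> np.ndarray:
        a = self.assignment
        return np.array([a[s] for s in sites], dtype=int)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"site_id": self.sites, "cluster": self.labels}).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "Partition":
        df = pd.read_csv(path)
        return cls(df["site_id"].astype(str).tolist(), df["cluster"].to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.sites == other.sites and np.array_equal(self.labels, other.labels)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over ordered site leaves.

    ``merges`` follows scipy's linkage convention: row i merges nodes
    ``left``/``right`` (ids < n are leaves, id n+i is the cluster formed by
    row i) at ``height``, creating a cluster of ``size`` leaves.
    """

    leaves: list[str]
    merges: np.ndarray  # (n-1, 4): left, right, height, size

    def __post_init__(self) -> None:
        n = len(self.leaves)
        Z = np.asarray(self.merges, dtype=float)
        if Z.shape != (n - 1, 4):
            raise DataError(f"expected {n - 1} merges for {n} leaves, got {Z.shape}")
        self.merges = Z

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def max_height(self) -> float:
        return float(self.heights[-1])

    # -- cuts ---------------------------------------------------------------

    def _labels_after(self, n_merges: int) -> np.ndarray:
        """Leaf labels after applying the first ``n_merges`` merges."""
        n = self.n_leaves
        parent = list(range(n + n_merges))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for row in range(n_merges):
            left, right = int(self.merges[row, 0]), int(self.merges[row, 1])
            new = n + row
            parent[find(left)] = new
            parent[find(right)] = new
        return np.array([find(i) for i in range(n)])

    def cut_k(self, k: int) -> Partition:
        """Partition into exactly ``k`` clusters by undoing the last k-1
        merges. cut_k(k) refines cut_k(k-1) by construction."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ConfigurationError(f"k={k} outside 1..{n}")
        return Partition(list(self.leaves), self._labels_after(n - k))

    def cut_height_fraction(self, fraction: float) -> Partition:
        """Clusters are the subtrees whose merges all sit strictly below
        ``fraction * max_height``; fraction=1 yields a single cluster even
        when ties reach the root."""
        if not 0 < fraction <= 1:
            raise ConfigurationError("fraction must be in (0, 1]")
        if fraction == 1:
            return self.cut_k(1)
        threshold = fraction * self.max_height
        n_applied = int(np.count_nonzero(self.heights < threshold))
        return Partition(list(self.leaves), self._labels_after(n_applied))

    # -- derived structures -------------------------------------------------

    def cophenetic(self) -> DissimilarityMatrix:
        """Pairwise cophenetic distances (height of the lowest common merge)."""
        vals = squareform(cophenet(self.merges))
        return DissimilarityMatrix(list(self.leaves), vals, metric_name="cophenetic")

    # -- Newick -------------------------------------------------------------

    def to_newick(self) -> str:
        """Ultrametric Newick string; branch lengths are half-height
        differences, so path lengths between leaves equal cophenetic
        distances."""
        n = self.n_leaves
        height = np.concatenate([np.zeros(n), self.merges[:, 2]])

        parts: dict[int, str] = {}
        for i, name in enumerate(self.leaves):
            parts[i] = _quote_newick(name)
        for row in range(n - 1):
            left, right = int(self.merges[row, 0]), int(self.merges[row, 1])
            h = height[n + row]
            bl_l = (h - height[left]) / 2
            bl_r = (h - height[right]) / 2
            parts[n + row] = f"({parts.pop(left)}:{bl_l:.12g},{parts.pop(right)}:{bl_r:.12g})"
        return parts[2 * n - 2] + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, text: str) -> "Dendrogram":
        """Rebuild a dendrogram from an ultrametric binary Newick string."""
        import dendropy

        if not text.strip():
            raise DataError("empty Newick string")
        try:
            tree = dendropy.Tree.get(data=text, schema="newick",
                                     suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises assorted parse errors
            raise DataError(f"Newick parse error: {exc}") from exc

        # node height above leaves = 2 * (half-height distance to any leaf)
        def depth_to_leaf(node) -> float:
            d = 0.0
            while not node.is_leaf():
                child = node.child_nodes()[0]
                d += child.edge.length or 0.0
                node = child
            return d

        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(leaves) != len(set(leaves)):
            raise DataError("duplicate leaf names in Newick tree")
        leaf_index = {name: i for i, name in enumerate(leaves)}
        n = len(leaves)

        internal = []
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                node._cluster_id = leaf_index[node.taxon.label]
            else:
                kids = node.child_nodes()
                if len(kids) != 2:
                    raise DataError("Newick tree must be strictly binary")
                internal.append(node)
        internal.sort(key=lambda nd: 2 * depth_to_leaf(nd))

        merges = np.zeros((n - 1, 4))
        sizes = {i: 1 for i in range(n)}
        if len(internal) != n - 1:
            raise DataError("tree is not a binary dendrogram")
        for row, node in enumerate(internal):
            left, right = (kid._cluster_id for kid in node.child_nodes())
            h = 2 * depth_to_leaf(node)
            size = sizes[left] + sizes[right]
            merges[row] = (left, right, h, size)
            node._cluster_id = n + row
            sizes[n + row] = size
        return cls(leaves, merges)

    @classmethod
    def read_newick(cls, path: str | Path) -> "Dendrogram":
        return cls.from_newick(Path(path).read_text())


def _quote_newick(name: str) -> str:
    if any(ch in name for ch in " ,():;'[]"):
        return "'" + name.replace("'", "''") + "'"
    return name


def agglomerate(D: DissimilarityMatrix, method: str = "average") -> Dendrogram:
    """Hierarchical agglomerative clustering of a dissimilarity matrix.

    Deterministic given D; heights are in the metric's units.
    """
    if method not in LINKAGES:
        raise ConfigurationError(f"linkage {method!r} not in {LINKAGES} "
                                 "(Ward is invalid on non-Euclidean dissimilarities)")
    if D.n_sites < 2:
        raise DataError("need at least 2 sites to cluster")
    Z = linkage(D.condensed(), method=method)
    return Dendrogram(list(D.sites), Z)
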