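"""Optimal cluster-number inference and permutation testing.

The central idea: a good biogeographic partition maximizes species turnover
between clusters, which shows up as "local species" — species confined to a
single cluster. Cutting the dendrogram at every candidate cluster count k and
plotting the mean per-cluster local-species proportion against k produces an
L-shaped **evaluation curve**: the proportion falls steeply while cuts still
separate genuine provinces and flattens once cuts start splitting homogeneous
faunas. The knee of that curve is located with the **L-method** (Salvador &
Chan): for every candidate knee c, fit one least-squares line to the points
left of (and including) c and another to the points right of (and including)
c, and minimize the point-count-weighted total root-mean-squared error

    RMSE_c = (c - k_start)/(b - k_start) * RMSE(L_c)
           + (b - c)/(b - k_start) * RMSE(R_c)

where b is the largest cluster count considered. b comes from cutting the
dendrogram at 75% of its maximum height, which keeps the curve L-shaped and
avoids evaluating unrealistically fine partitions. Because each line needs at
least three points, the smallest examinable knee is c = 3.

ANOSIM (Clarke's analysis of similarities) serves as the cross-check: a
rank-based permutation test of between- versus within-cluster dissimilarity,
with R = 1 at complete separation and R ≈ 0 under no structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .clustering import Dendrogram, Partition
from .datamodel import OccurrenceMatrix
from .dissimilarity import DissimilarityMatrix
from .errors import ConfigurationError, DataError, DegeneracyError

# ---------------------------------------------------------------------------
# Local species
# ---------------------------------------------------------------------------


def cluster_presence(matrix: OccurrenceMatrix, partition: Partition) -> np.ndarray:
    """k x n_species boolean table: species present in >=1 site of cluster."""
    labels = partition.relabeled_like(matrix.sites)
    k = labels.max()
    P = np.zeros((k, matrix.n_species), dtype=bool)
    for lab in range(1, k + 1):
        P[lab - 1] = matrix.incidence[labels == lab].any(axis=0)
    return P


def local_species(matrix: OccurrenceMatrix, partition: Partition) -> pd.DataFrame:
    """Per-cluster local-species counts.

    A species is *local* to a cluster when it occurs in that cluster and in no
    other — regardless of whether it is a regional endemic. Returns one row
    per cluster with ``n_local``, ``n_total`` and ``proportion``.
    """
    P = cluster_presence(matrix, partition)
    occupancy = P.sum(axis=0)
    n_total = P.sum(axis=1)
    if (n_total == 0).any():
        dead = [i + 1 for i in np.flatnonzero(n_total == 0)]
        raise DataError(f"clusters with zero species: {dead}")
    n_local = (P & (occupancy == 1)).sum(axis=1)
    return pd.DataFrame({
        "cluster": np.arange(1, P.shape[0] + 1),
        "n_local": n_local,
        "n_total": n_total,
        "proportion": n_local / n_total,
    })


def mean_local_fraction(matrix: OccurrenceMatrix, partition: Partition) -> float:
    """Unweighted mean over clusters of the per-cluster local-species
    proportion (a mean of proportions, not a pooled ratio)."""
    return float(local_species(matrix, partition)["proportion"].mean())


# ---------------------------------------------------------------------------
# Evaluation curve and the L-method
# ---------------------------------------------------------------------------

@dataclass
class EvaluationCurve:
    """Mean local-species proportion as a function of cluster count k."""

    k: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        if self.k.shape != self.y.shape or self.k.ndim != 1:
            raise DataError("curve k and y must be equal-length vectors")
        if not np.array_equal(self.k, np.arange(self.k[0], self.k[0] + len(self.k))):
            raise DataError("curve k values must be contiguous integers")
        if ((self.y < -1e-12) | (self.y > 1 + 1e-12)).any():
            raise DataError("curve values must lie in [0, 1]")

    @property
    def k_start(self) -> int:
        return int(self.k[0])

    @property
    def b(self) -> int:
        return int(self.k[-1])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"k": self.k, "mean_local_fraction": self.y}).to_csv(path, index=False)


def max_clusters(dendrogram: Dendrogram, fraction: float = 0.75) -> int:
    """Largest cluster count considered: the number of clusters obtained by
    cutting the dendrogram at ``fraction`` of its maximum height."""
    b = dendrogram.cut_height_fraction(fraction).k
    if b < 5:
        raise DegeneracyError(
            f"height cut yields b={b} < 5 clusters: knee search infeasible; "
            "deepen the dendrogram or raise the fraction")
    return b


def evaluation_curve(matrix: OccurrenceMatrix, dendrogram: Dendrogram, b: int,
                     k_start: int = 1) -> EvaluationCurve:
    """Evaluate mean local-species proportion at every k from k_start to b."""
    if k_start < 1 or b > dendrogram.n_leaves or b < k_start:
        raise ConfigurationError(f"invalid curve range k={k_start}..{b}")
    ks = np.arange(k_start, b + 1)
    ys = [mean_local_fraction(matrix, dendrogram.cut_k(int(k))) for k in ks]
    return EvaluationCurve(ks, np.array(ys))


@dataclass
class KneeResult:
    """L-method output: the knee location and the full candidate table."""

    c_star: int
    rmse_total_by_c: pd.DataFrame
    left_fit: tuple[float, float]   # (slope, intercept) at c_star
    right_fit: tuple[float, float]

    def to_json_dict(self) -> dict:
        return {
            "c_star": self.c_star,
            "left_fit": {"slope": self.left_fit[0], "intercept": self.left_fit[1]},
            "right_fit": {"slope": self.right_fit[0], "intercept": self.right_fit[1]},
            "rmse_total_by_c": self.rmse_total_by_c.to_dict(orient="records"),
        }


def _ols_rmse(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (slope, intercept, rmse)."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float(np.sqrt(np.mean(resid ** 2)))


def l_method_knee(curve: EvaluationCurve) -> KneeResult:
    """Locate the knee of an evaluation curve by the L-method.

    Every candidate c with at least three points on each side (the boundary
    point belongs to both fits) is scored by the point-count-weighted total
    RMSE of the two line fits; the minimizer wins, ties going to the smallest
    c. The candidate range starts at c = k_start + 2, hence never below 3
    when the curve starts at k = 1.
    """
    k, y = curve.k, curve.y
    k_start, b = curve.k_start, curve.b
    if len(k) < 5:
        raise DegeneracyError("knee search needs at least 5 curve points")
    rows = []
    best = None
    for c in range(k_start + 2, b - 1):  # >=3 points each side
        left = k <= c
        right = k >= c
        sl, il, rmse_l = _ols_rmse(k[left], y[left])
        sr, ir, rmse_r = _ols_rmse(k[right], y[right])
        w_l = (c - k_start) / (b - k_start)
        w_r = (b - c) / (b - k_start)
        total = w_l * rmse_l + w_r * rmse_r
        rows.append({"c": c, "rmse_left": rmse_l, "rmse_right": rmse_r,
                     "rmse_total": total})
        if best is None or total < best[0] - 1e-15:
            best = (total, c, (sl, il), (sr, ir))
    table = pd.DataFrame(rows)
    return KneeResult(c_star=best[1], rmse_total_by_c=table,
                      left_fit=best[2], right_fit=best[3])


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    """ANOSIM statistic with its permutation p-value."""

    R: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    permuted_R: np.ndarray | None = field(default=None, repr=False)

    def to_json_dict(self) -> dict:
        return {"R": self.R, "p_value": self.p_value,
                "n_permutations": self.n_permutations, "seed": self.seed}


def _anosim_R(ranks: np.ndarray, within: np.ndarray, denom: float) -> np.ndarray:
    """R for one within-pair mask (1-D) or a batch of masks (2-D)."""
    within = np.atleast_2d(within)
    n_within = within.sum(axis=1)
    n_total = within.shape[1]
    sum_within = (ranks[None, :] * within).sum(axis=1)
    rw = sum_within / n_within
    rb = (ranks.sum() - sum_within) / (n_total - n_within)
    return (rb - rw) / denom


def _within_mask(labels: np.ndarray) -> np.ndarray:
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    return labels[iu] == labels[ju]


def anosim(D: DissimilarityMatrix, partition: Partition, n_permutations: int = 999,
           seed: int | None = None) -> AnosimResult:
    """Clarke's analysis of similarities.

    R = (mean rank of between-cluster dissimilarities - mean rank of
    within-cluster dissimilarities) / (M/2), with M = n(n-1)/2 pairs and
    mid-ranks for ties; R = 1 when every between-pair outranks every
    within-pair. The p-value counts label permutations with R at least the
    observed value, with the add-one rule.
    """
    labels = partition.relabeled_like(D.sites)
    if partition.k < 2:
        raise DataError("ANOSIM needs at least 2 clusters")
    sizes = np.bincount(labels)[1:]
    if (sizes < 2).any():
        raise DataError(f"ANOSIM requires every cluster to hold >=2 sites; sizes={sizes.tolist()}")
    if n_permutations < 99:
        raise ConfigurationError("use at least 99 permutations")
    ranks = rankdata(D.condensed())  # mid-ranks for ties
    M = len(ranks)
    denom = M / 2
    R_obs = float(_anosim_R(ranks, _within_mask(labels), denom)[0])

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(labels) for _ in range(n_permutations)])
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    masks = perms[:, iu] == perms[:, ju]
    R_perm = _anosim_R(ranks, masks, denom)
    p = (1 + int((R_perm >= R_obs - 1e-12).sum())) / (1 + n_permutations)
    return AnosimResult(R=R_obs, p_value=p, n_permutations=n_permutations,
                        seed=seed, permuted_R=R_perm)


def anosim_R_only(D: DissimilarityMatrix, partition: Partition) -> float:
    """The observed R statistic without permutations (used by refinement)."""
    labels = partition.relabeled_like(D.sites)
    ranks = rankdata(D.condensed())
    return float(_anosim_R(ranks, _within_mask(labels), len(ranks) / 2)[0])


def refine_partition_anosim(D: DissimilarityMatrix, partition: Partition,
                            max_iter: int = 20) -> Partition:
    """Greedy ANOSIM refinement of cluster membership.

    One pass visits sites in site order; each site is tentatively moved to
    every other cluster and the move that most increases R (if any) is kept.
    Passes repeat to a fixed point or ``max_iter``. A move that would empty a
    cluster is never taken. Deterministic. This greedy maximizer is a declared
    surrogate for the under-specified refinement step it stands in for.
    """
    if partition.k < 2:
        raise DataError("refinement needs k >= 2")
    labels = partition.relabeled_like(D.sites).copy()
    ranks = rankdata(D.condensed())
    denom = len(ranks) / 2
    k = partition.k

    def R_of(lab: np.ndarray) -> float:
        w = _within_mask(lab)
        if w.sum() == 0 or w.sum() == len(w):
            return -np.inf
        return float(_anosim_R(ranks, w, denom)[0])

    current = R_of(labels)
    for _ in range(max_iter):
        changed = False
        for i in range(len(labels)):
            orig = labels[i]
            if (labels == orig).sum() <= 1:
                continue  # never empty a cluster
            best_lab, best_R = orig, current
            for cand in range(1, k + 1):
                if cand == orig:
                    continue
                labels[i] = cand
                r = R_of(labels)
                if r > best_R + 1e-12:
                    best_lab, best_R = cand, r
            labels[i] = best_lab
            if best_lab != orig:
                current = best_R
                changed = True
        if not changed:
            break
    return Partition(list(D.sites), labels)


# ---------------------------------------------------------------------------
# End-to-end optimum
# ---------------------------------------------------------------------------

def optimal_partition(matrix: OccurrenceMatrix, D: DissimilarityMatrix,
                      dendrogram: Dendrogram, *, max_height_fraction: float = 0.75,
                      k_start: int = 1, n_permutations: int = 999,
                      seed: int | None = None,
                      ) -> tuple[Partition, EvaluationCurve, KneeResult, AnosimResult]:
    """Full evaluation-curve inference: curve, knee, partition, ANOSIM check.

    Emits a "weak structure" warning when the ANOSIM permutation test on the
    selected partition is not significant (p > 0.05).
    """
    b = max_clusters(dendrogram, max_height_fraction)
    curve = evaluation_curve(matrix, dendrogram, b, k_start=k_start)
    knee = l_method_knee(curve)
    part = dendrogram.cut_k(knee.c_star)
    res = anosim(D, part, n_permutations=n_permutations, seed=seed)
    if res.p_value > 0.05:
        warnings.warn(
            f"weak structure: ANOSIM p={res.p_value:.3f} for the selected "
            f"k={knee.c_star} partition", stacklevel=2)
    return part, curve, knee, res
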