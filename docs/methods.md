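# Methods notes

This note records what the package computes, the choices made where the
design was genuinely open, and what the synthetic experiments do and do not
demonstrate.

## Dissimilarity

βsim = min(b,c)/(min(b,c)+a) over the incidence components of a site pair.
Properties relied on elsewhere: joint-absence invariance (appending empty
species columns changes nothing), nestedness-zero (a fauna that is a subset
of another scores 0), and richness insensitivity (padding the richer site
with unique species cannot change min(b,c)). "Bray–Curtis" on 0/1 data is
exactly Sørensen (b+c)/(2a+b+c); it is exposed as `bray_curtis_pa` to make
that identification explicit. A pair of empty assemblages is an error, never
a silent 0 — a zero would fabricate similarity from missing data. Values are
kept at full precision; nothing is rounded before clustering.

## Clustering

UPGMA (average linkage) is the default because it is the standard for
assemblage-dissimilarity regionalization and yields ultrametric trees with
monotone heights; complete linkage is available for sensitivity analysis.
Ward linkage is refused: it presumes Euclidean geometry that βsim does not
have. Linkage is computed by scipy's nearest-neighbor-chain implementation,
which is deterministic for a given matrix; merge order among exactly tied
dissimilarities follows scipy's internal order, and no test asserts tie
topology. `cut_k` operates by replaying the merge sequence, which guarantees
exactly k clusters and that cut_k(k) refines cut_k(k−1) even under tied
heights (threshold-based cutting guarantees neither). `cut_height_fraction`
uses strict `< fraction × max_height` membership so fraction = 1 returns one
cluster even when ties reach the root.

Newick export writes ultrametric branch lengths (half-height differences), so
leaf-to-leaf path lengths equal cophenetic distances; parsing (via dendropy)
reconstructs merges from node depths and requires strictly binary trees.

## Evaluation curve and the L-method

The curve plots, for k = 1..b, the unweighted mean over clusters of the
per-cluster local-species proportion — a mean of proportions, not a pooled
ratio, so small distinctive clusters count as much as large ones. The cap b
comes from cutting the dendrogram at 75% of its maximum height; b < 5 is an
error because the knee search needs five points.

The L-method scores each candidate knee c ∈ [3, b−2] by the point-count
weighted sum of left/right line-fit RMSEs, the boundary point belonging to
both fits; ties go to the smallest c. The curve starts at k = 1, which makes
c = 3 the smallest candidate with three left-side points.

**Known limitation (by construction).** The k = 1 point is the identity
y = 1: with one cluster every species is trivially local. Whenever the fauna
shares many species across provinces (realistic shelf faunas share half or
more), y(2) sits far below 1 and the resulting cliff dominates the left-line
RMSE; because that RMSE is weighted by (c−1)/(b−1), the total is then
increasing in c and the method returns its floor c = 3 regardless of deeper
structure. Three-province faunas are therefore recovered robustly (the floor
coincides with the truth, and the cut itself is verified by ARI against
truth), but a four-province fauna with realistic sharing is reported as
three. Numerical exploration across generator settings (local pool fractions
0.12–0.35, endemism 0.45–0.95, uniform or adjacent widespread ranges) found
no regime in which four provinces are recovered: softening the cliff by
raising turnover simultaneously flattens the dendrogram's sub-structure until
b < 5. Starting the curve at k = 2 instead would raise the candidate floor to
4 under the three-points-per-line rule and is exposed via `k_start` for
sensitivity analysis only. The acceptance suite asserts the four-province
case as specified and documents its failure rather than hiding it.

## ANOSIM

R = (r̄_between − r̄_within)/(M/2) with M = n(n−1)/2 site pairs and mid-ranks
for ties; this normalization gives R = 1 exactly when every between-cluster
pair outranks every within-cluster pair and keeps R in [−1, 1]. The p-value
uses the add-one permutation rule, p = (1 + #{R* ≥ R}) / (1 + n_perm), with
label permutations vectorized over the condensed rank vector. Every cluster
must hold at least two sites. The statistic was cross-checked against
scikit-bio's implementation in the test suite.

When ANOSIM itself selects the partition (`selector="anosim"`), the model
walks dendrogram cuts from coarse to fine and stops at the first local
maximum of R — the point where further splitting no longer improves
separation — then greedily reassigns single sites to the cluster that most
increases R until a fixed point (never emptying a cluster). This greedy
maximizer is a declared surrogate for a similarity-only refinement procedure
that has no published algorithmic form; it is flagged as such in result
manifests. A "weak structure" warning fires when the final partition's
ANOSIM p exceeds 0.05. Note the cross-check is partially circular when the
partition was derived from the same dissimilarities; the warning is
therefore a guardrail, not a calibrated test.

## Endemism

A species is classified a regional endemic when (occupied core sites) /
(occupied sites) ≥ 0.75, boundary inclusive. Site counts stand proxy for
geographic range area — the only range information an incidence matrix
carries. The proxy over-calls endemism for widespread species when few
non-core sites are sampled (with 4 adjacent sites, a species in 24 core and
4 non-core sites scores 0.857); the synthetic generator's trait labels are
therefore authoritative for subset analyses, and the classifier is validated
on constructed fixtures where the ratio is exact.

## Record cleaning

Duplicates: one record kept per (species, site, coordinates rounded to 2
decimals ≈ 1 km); `source` deliberately excluded from the key. Outliers: a
record of a *common* species (≥ 20 records, configurable) is deleted when no
conspecific record lies within 500 km great-circle distance; rare species are
exempt — a single record of a rarely collected species is data, not noise.
Both passes are idempotent at the default one-neighbor rule, since a removed
record was within range of nobody.

## Synthetic faunas

The generator emulates the study conditions the pipeline targets: 45 ordered
shelf sections in 3 provinces plus 4 adjacent non-core sites, 1,559 species,
45% regional endemics, a 39/39/20 reef/soft-bottom/pelagic guild mix,
occupancy 0.8 within occupied ranges, and province-local species targeted at
12% of each province's pool (solved analytically from the widespread-species
coverage). Widespread species occupy two provinces with probability 0.7,
otherwise all; non-endemics additionally occupy the non-core sites
(occupancy 0.6). Province-locals stray into one foreign site with
probability `leakage` = 0.02.

Provinces are internally subdivided into 3 ecoregions, and 70% of species
are ecoregion-restricted within each province they occupy. This nesting is
what gives dendrograms the graded heights of real regionalization analyses
(fine subdivisions inside major provinces); without it all within-province
merges collapse to one level and the 75% cap cannot produce a workable
candidate range. Expected per-site richness is computed in closed form
before sampling and must land in the richness window — 400–900 for the
standard 1,559-species pool, scaled proportionally for other pool sizes —
otherwise the spec is rejected as infeasible. Under the defaults it is ≈ 440
(realized 395–490). A four-province split of the same shelf dilutes per-site
richness to ≈ 360, so four-province experiments state a 300–900 window
explicitly.

What the generator does **not** emulate: spatially contiguous ranges at site
resolution, environmental gradients, detection error, and the expert range
curation of real databases. Passing the recovery experiments therefore shows
the pipeline is correct and sensitive under clean block-plus-nesting
turnover; it does not show robustness to gradient-like real data, where
province boundaries are genuinely fuzzy.

## Problem sizes and determinism

The standard experiments use the full emulated scale (45 sites × 1,559
species); a single pipeline run takes well under a second, the
twenty-replicate recovery experiment a few seconds. All stochastic
operations take explicit seeds; `scripts/acceptance.py` derives every seed
from its `--seed` argument via a SeedSequence, and repeated runs are
byte-identical.
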