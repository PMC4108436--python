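# bioregions

Quantitative bioregionalization of presence/absence faunas: given a
sites × species incidence matrix, the package finds the major biogeographic
units (provinces) of a study area and their fine-scale subdivisions
(ecoregions), using faunal distinctiveness rather than arbitrary endemism
rules.

It is written for marine biogeographers working with shorefish (or any
shelf-fauna) occurrence data: the motivating use case is partitioning tens of
ordered shelf sections spanning a tropical region by comparing their resident
faunas — hundreds of thousands of cleaned occurrence records collapsed into a
matrix of roughly 45 sites × 1,500 species.

## The method

1. **Dissimilarity.** For each pair of sites with `a` shared species and
   `b`, `c` species unique to each, compute the Simpson-based turnover index

   βsim = min(b, c) / (min(b, c) + a)

   βsim ignores joint absences, scores nested faunas 0, and is insensitive to
   richness differences — unlike Bray–Curtis, which on presence/absence data
   reduces to Sørensen `(b + c)/(2a + b + c)` and is also provided.
2. **Clustering.** UPGMA (average-linkage) agglomeration of the dissimilarity
   matrix into an ultrametric dendrogram.
3. **Evaluation curve.** For every candidate cluster count k (up to the
   number of clusters b obtained by cutting the dendrogram at 75% of its
   maximum height), cut the tree into k clusters and record the mean
   per-cluster proportion of *local species* — species confined to a single
   cluster. The proportion falls steeply while cuts separate genuine
   provinces and flattens once they start splitting homogeneous faunas.
4. **L-method knee.** The optimal k is the knee of that curve: for each
   candidate c, fit least-squares lines to the points left and right of c
   (boundary shared, at least three points per line, so c ≥ 3) and minimize
   the point-count-weighted total RMSE

   RMSE_c = (c − 1)/(b − 1) · RMSE(L_c) + (b − c)/(b − 1) · RMSE(R_c).

5. **ANOSIM cross-check.** Clarke's rank-based permutation test
   (R = (r̄_between − r̄_within)/(M/2), M site pairs) validates the selected
   partition; an alternative selector chooses k by ANOSIM R directly and
   refines membership greedily.
6. **Ecoregions.** Cutting the dendrogram at 1/3 of its maximum height gives
   the fine-scale subdivision.

Endemism classification (a species is a regional endemic when ≥ 75% of its
occupied sites lie inside the core bounding area), record cleaning
(duplicate and range-outlier removal), faunal-subset batch analysis (habitat
guilds × endemism slices, depth-limited subsets), and a synthetic fauna
generator with known province structure are included.

## Worked example

```python
import bioregions as br

# a synthetic fauna with 3 latent provinces over 45 shelf sections
matrix, traits, sites, truth = br.generate(br.FaunaSpec(seed=1))

model = br.Bioregionalization(matrix, traits, sites)   # beta-sim + UPGMA
res = model.fit(seed=1)                                # curve + knee + ANOSIM
print(res.summary())
print("ARI vs truth:", br.truth_recovery_score(res.partition, truth))
```

prints

```
Bioregionalization results
==========================
metric: beta_sim   linkage: average   selector: evaluation_curve
sites: 45   species: 1559
max clusters considered (75% height cut): b = 9
optimal number of clusters: k = 3 (L-method knee, RMSE=0.04329)
ANOSIM: R = 1.000, p = 0.0010 (999 permutations)
species shared by >=2 clusters: 76.8%

 cluster  n_species  n_local  pct_local  n_endemic  pct_endemic
       1       1015      120       11.8        379         37.3
       2       1028      116       11.3        379         36.9
       3       1036      125       12.1        373         36.0

ecoregions at 1/3 max height: 9 clusters
ARI: 1.0
```

The fit recovered the three latent provinces exactly (k = 3, adjusted Rand
index 1.0 against the generator's truth), with 11–12% of each province's
species local to it and perfect ANOSIM separation (R = 1, p = 0.001).

The same pipeline is available from the shell:

```sh
bioregions simulate --seed 1 --out fauna/
bioregions analyze fauna/matrix.csv --traits fauna/traits.csv \
    --sites fauna/sites.csv --out results/
bioregions subsets fauna/matrix.csv --traits fauna/traits.csv --out subsets/
bioregions methods-compare fauna/matrix.csv --sites fauna/sites.csv --out cmp/
```

## Layout

- `src/bioregions/datamodel.py` — incidence matrix, site/trait tables, endemism
- `src/bioregions/cleaning.py` — record ingestion, dedupe, outlier deletion
- `src/bioregions/dissimilarity.py` — βsim / Sørensen, pairwise matrices
- `src/bioregions/clustering.py` — UPGMA, cuts, cophenetic, Newick
- `src/bioregions/evaluation.py` — local species, evaluation curve, L-method, ANOSIM
- `src/bioregions/subsets.py` — faunal subset batches, cluster summaries
- `src/bioregions/synthetic.py` — fauna generator with known truth
- `src/bioregions/model.py`, `compare.py` — Model/Results interface, method comparison
- `src/bioregions/cli.py` — `bioregions` command
- `docs/methods.md` — modelling notes, parameter choices, limitations
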