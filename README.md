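# phenoclust

Two-tier clustering of binary psychiatric symptom data: data-driven item
clusters, participant phenotype groups, and Gaussian-mixture subtyping of
diagnosed subsamples.

## The problem

Categorical psychiatric diagnoses sit awkwardly on population data:
symptoms are heterogeneous within disorders and overlap across them, and
in middle-aged and older community cohorts most people endorse only a few
subclinical complaints.  Questionnaire responses (CES-D for depression,
HADS-A for anxiety, PSQI for sleep — 43 items in the default registry)
are heavily zero-skewed, which makes Pearson-correlation-based factor
analysis a poor fit.  `phenoclust` implements the alternative: treat
endorsement as binary and cluster twice —

* **items**, by co-occurrence of endorsement, with the asymmetric
  **Jaccard distance** d(x, y) = (b + c) / (a + b + c), where a, b, c, d
  count the (1,1), (1,0), (0,1), (0,0) coordinate pairs (joint absence is
  uninformative for symptom affinity);
* **participants**, with the symmetric **simple matching distance**
  (b + c) / (a + b + c + d) (agreeing on absence *is* informative about
  phenotype similarity),

both agglomerated by **Ward's linkage** through the Lance–Williams
recurrence

    d(k, i∪j) = [(nᵢ+nₖ)·d(k,i) + (nⱼ+nₖ)·d(k,j) − nₖ·d(i,j)] / (nᵢ+nⱼ+nₖ),

in both common dialects (`ward_d` on raw, `ward_d2` on squared
dissimilarities).  The number of item clusters k_i and participant groups
k_p is chosen by a three-step procedure: an elbow scan of dendrogram cuts
(k = 2..20), an average-silhouette-width survey of aggregated
item-cluster score datasets over k_i = 3..10 × k_p = 3..10, and a
rank-based decision over a region of interest (default 3..5 × 3..5)
combining silhouette and the between/total sum-of-squares ratio for
hierarchical cuts, k-means and PAM.  The item solution is validated
against a random-item-assignment null and a participant bootstrap, and a
diagnosed subsample is subtyped with EM-fitted Gaussian mixtures over six
covariance structures (EII … VVV), selected by BIC = 2·log L − p·ln n
(maximized).

Because cohort data of this kind is access-restricted, the package ships
a synthetic cohort generator that plants the assumed structure
(item-cluster co-endorsement, participant severity groups, zero-skew,
MCAR missingness) and returns ground truth, so the whole pipeline is
testable by parameter recovery.

## Worked example

```python
import phenoclust as pc

cfg = pc.preset("discovery_like")          # n = 2000, planted (3, 4)
responses, truth = pc.generate_cohort(cfg, seed=11)
responses = pc.impute_mode_of_m(responses, m=5, seed=12)
binary = pc.binarize(responses)

result = pc.select_cluster_numbers(binary, seed=13)
print(f"selected k_i = {result.k_i}, k_p = {result.k_p}")
print(f"item elbow knee at k = {result.elbow_items.knee_k}")

inputs = pc.prepare_inputs(binary)
items = pc.cut(inputs.item_dendro, result.k_i)
scores = pc.aggregate_cluster_scores(binary, items)
print("mean scores per item cluster:", scores.data.mean().round(2).to_dict())

null = pc.random_assignment_null(binary, items, k_p=result.k_p, B=199, seed=14)
print(f"observed bt_ratio = {null.observed:.3f}, "
      f"null 95th pct = {null.percentile(95):.3f}, "
      f"empirical p = {null.empirical_p:.3f}")
```

prints (a few minutes on one core):

```
selected k_i = 3, k_p = 4
item elbow knee at k = 3
mean scores per item cluster: {'C1': 6.52, 'C2': 1.57, 'C3': 0.92}
observed bt_ratio = 0.879, null 95th pct = 0.856, empirical p = 0.005
```

The procedure recovers the planted three item clusters and four
participant groups.  The mean aggregated scores say that participants
endorse on average ~6.5 of the 19 items of the large "mixed" cluster but
under 2 of each smaller cluster — the zero-skewed regime the method is
built for.  The observed between/total sum-of-squares ratio exceeds every
one of 199 random same-size item groupings (empirical p = 1/200), i.e.
the dendrogram solution explains participant score variance far better
than chance.

A command-line interface mirrors the library
(`phenoclust simulate | preprocess | cluster-items | select |
cluster-participants | validate | gmm | run-all | compare`); `run-all`
writes the full artifact bundle (dendrogram Newick, merge table, cluster
assignments, selection and validation JSON, boxplot-ready group scores,
BIC table) stamped with the config hash and seed.

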