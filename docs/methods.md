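# Methods

This note documents the statistical procedure the package implements,
the choices made where the design was genuinely open, and what the
synthetic-data results do and do not demonstrate.

## Data model and preprocessing

The unit of analysis is a participants × items table of ordinal Likert
codes 0–3 from three instruments (20 CES-D, 7 HADS-A and 16 PSQI items;
43 in the default registry).  Which 16 of the 24 PSQI items enter the
analysis is configurable, since sleep questionnaires are scored
differently across cohorts; the registry accepts any instrument/item
layout via YAML.

Missing cells (typical rate ~1.5% per item in population cohorts) are
imputed as the **mode of m = 5 stochastic draws** per cell.  Draws come
from the observed ordinal values of that item among the participant's
k = 10 nearest neighbours by Hamming distance on the jointly observed
binary-coded items, falling back to the item's marginal distribution
when no neighbour information exists.  This is a deliberately simple
conditional hot-deck; it preserves the "mode of several imputations"
semantics of chained-equations multiple imputation without modelling
full conditional regressions, which is out of scope.  Mode ties break
toward the smaller code (conservative toward non-endorsement).
Imputation operates on the ordinal codes, before dichotomization.

Dichotomization maps 0 → 0 ("no complaints") and 1–3 → 1 ("symptom
endorsed").  Items endorsed by fewer than `min_endorsement` participants
(default 1) are screened out before item clustering, because an all-zero
item makes the Jaccard distance degenerate.

## Distances

* Items: Jaccard distance (b+c)/(a+b+c).  The degenerate all-zero pair
  is defined as distance 0 with a warning (screening should remove it).
* Participants: simple matching distance (b+c)/(a+b+c+d), identical to
  the normalized Hamming distance.

Both matrices are stored dense; at 43 items and a few thousand
participants this is desk-scale (a 2000² float matrix is 32 MB).

## Ward agglomeration

Ward linkage is implemented via the Lance–Williams recurrence in both
dialects found in the ecosystem: `ward_d` applies the update to raw
dissimilarities, `ward_d2` (the default) to squared dissimilarities with
square-root merge heights.  On Euclidean input `ward_d2` reproduces the
standard implementations exactly (tested against scipy's linkage and a
from-scratch greedy minimiser of the within-cluster sum-of-squares
increase).  On non-Euclidean input (Jaccard, simple matching) the two
dialects can differ and merge heights can invert; inversions are counted
and logged, not fatal, and heights are reported in linkage units without
a variance interpretation.  Ties in the closest pair break
lexicographically on matrix position, so dendrograms are reproducible
across platforms.

## Choosing k_i and k_p

1. **Elbow scan** (k = 2..20) of the within-cluster cohesion of
   dendrogram cuts, for items and participants independently.  The knee
   is formalized as the maximum discrete second difference
   f(k−1) − 2f(k) + f(k+1); because this step is intrinsically visual,
   the full curve is persisted, a flat-curve warning is raised when no
   knee stands out, and the result is advisory only.
2. **Silhouette survey** over k_i = 3..10 × k_p = 3..10: for each k_i
   the item dendrogram is cut and aggregated item-cluster scores (per
   participant, the count of endorsed items in each item cluster) are
   built; participants are partitioned by the dendrogram cut and by
   k-means on the scores.  Silhouettes are computed in the space each
   partition was built in: simple-matching distances for hierarchical
   participant cuts, Euclidean score distances for k-means.
3. **Rank decision** over the region of interest (default 3..5 × 3..5):
   silhouette and the between/total sum-of-squares ratio are computed
   per cell for hierarchical cuts, k-means and PAM; each
   (method, metric) column is ranked across cells (average ranks on
   ties) and the cell with the lowest mean rank wins, ties toward
   smaller k_i then k_p.  k-means and the hierarchical cuts enter the
   ranking by default; PAM is computed and reported but not ranked
   (k-means consistently outperforms it on these scores).  The exact
   aggregation rule behind "rank both metrics" is not uniquely
   determined by the procedure's description anywhere; mean rank with
   small-k tie-breaks is the simplest scheme and is recorded, not
   asserted as canonical.

Scores are not z-scored before k-means by default (columns share the
endorsement-count scale); a `standardize` flag recomputes everything on
z-scored columns for sensitivity analysis.

## Partitioners and metrics

k-means is Lloyd's algorithm from k-means++ seeding, best of `n_init`
restarts by within-SS, empty clusters re-seeded at the farthest point;
deterministic given the seed.  PAM is greedy BUILD plus
best-improvement SWAP on the provided dissimilarity matrix.  Silhouette
uses s(i) = (b−a)/max(a,b) with s = 0 for singleton members and for
entities with a = b = 0.  The sum-of-squares decomposition reports
within, between, total and between/total, with bt_ratio = 0 (and a
warning) when the total is zero.

## Validation

* **Random-assignment null**: items are shuffled into k_i clusters
  matching the observed cluster-size profile (so the null isolates
  membership, not size; a uniform-assignment option exists), scores are
  rebuilt, k-means is run at k_p, and the between/total ratio is
  recorded; the empirical p uses the add-one permutation correction
  p = (1 + #{draws ≥ observed}) / (1 + B).
* **Participant bootstrap**: the item clustering is recomputed on
  bootstrap resamples of participants and pairwise co-clustering
  frequencies are reported; zero-variance items are dropped per draw.
* **Adjusted Rand index** quantifies partition agreement (sex-stratified
  and replication comparisons); verified against a permutation-
  expectation oracle and scikit-learn.
* **Dispersion**: per-cluster median absolute deviation of participant
  scores divided by the cluster's item count.  The raw descriptive MAD
  is the default; the 1.4826 normal-consistency constant is a flag,
  since the convention is not fixed for such descriptive ratios.
* **Correlations**: Spearman with average ranks, overall and within
  participant groups.

## Gaussian mixture stage

For a diagnosed subsample, aggregated scores are approximately
continuous and the package fits Gaussian mixtures by EM (k-means++-based
initialization, best of `n_init` restarts, covariance eigenvalue floor
1e-6, convergence on relative log-likelihood change < 1e-6).  Six
covariance structures are supported — EII, VII, EEI, VVI, EEE, VVV in
the volume/shape nomenclature — and model choice maximizes
BIC = 2·log L − p·ln n.  The eigendecomposition-constrained families
with shared shape but variable orientation (e.g. VEV) are not
implemented: VVV can represent any such solution, and component-count
recovery rather than structure-string identity is the scientific
deliverable.  A seed-controlled undersampling helper balances diagnosis
classes for sensitivity re-runs.

## Synthetic cohorts

The generator plants exactly the structure the analysis assumes: each
participant draws a latent group from `group_weights`; each item is
endorsed Bernoulli with probability `endorsement_probs[group,
item-cluster]`; endorsed items receive ordinal codes 1/2/3 by
`ordinal_split` (default 0.6/0.3/0.1); missingness is injected MCAR.
Items are exchangeable within a cluster by default (an optional
per-item logit-normal difficulty jitter exists).  The `discovery_like`
preset (n = 2000, items 19/12/12, four severity-graded groups with
weights 0.45/0.30/0.15/0.10, missingness 1.4%) is calibrated so the
population mean endorsements land near 6.8/19, 1.6/12 and 1.0/12 items
with ~78% zero cells; group profiles are graded so that group 1 is low
and group 4 high on everything, groups 2–3 intermediate with "mixed"
items most common throughout — and so that each smaller item cluster's
endorsement is concentrated enough for within-cluster Jaccard distances
to fall below between-cluster ones, which is what makes the planted
partition recoverable at all.  `replication_like` differs in
missingness (1.9%) and default size (n = 910, the ~0.455 ratio of a
replication-to-discovery cohort at desk scale).  `diagnosed_like`
bypasses binary generation and emits 3-d scores directly from a
four-component Gaussian mixture (n = 413; diagnosis labels with exact
counts 40 depression / 352 anxiety / 21 comorbid, depression and
comorbidity concentrated in the severity extremes); component means sit
at least 3 sd inside the feasible score box so the range clip is
negligible and the data are genuinely near-Gaussian.  `noise` has no
planted structure.

What passing recovery tests show: the pipeline correctly identifies
group-driven co-endorsement structure of realistic strength, skew and
missingness at realistic sample sizes.  What they do not show: behavior
under item-level random effects, non-MCAR missingness, ordinal
information loss, or real psychometric structure (no item response
model is used) — on real cohorts the cluster content must still be
judged substantively.

## Problem sizes and numerical conventions

Simulation-backed tests run at the sizes where their questions are
statistically meaningful but cheap: single-run structural recovery at
n = 2000 (the discovery-scale preset), multi-seed recovery-rate checks
at n = 1200 (below ~n = 1000 the four-versus-five participant-group
decision becomes bound by sampling noise in the rarest group, which has
weight 0.10), flat-grid and null-calibration checks at n = 400–500.
One property deserves a note: on structureless data the k-means
silhouette level still drifts with k_i (fewer, larger item clusters
give lower-dimensional, more heavily tied integer score spaces, which
mechanically inflate silhouettes) — this is an artifact of the metric,
not evidence of structure, so grid flatness on noise is asserted across
k_p within each k_i row rather than across the whole grid.

Floating-point conventions: within+between = total is enforced to 1e-9
relative; silhouette denominators are floored at the smallest positive
float; the EM covariance floor is 1e-6; all randomness flows from
explicit integer seeds through numpy Generators, and every artifact is
stamped with the config hash and seed.

## Known limitations

* The imputer is a neighbour-conditional hot-deck, not chained
  equations; with strongly non-MCAR missingness it will understate
  uncertainty.
* Jaccard + Ward on non-Euclidean dissimilarities has no variance
  interpretation of heights, and dendrogram inversions (logged) can
  occur.
* The VEV-style covariance families are unimplemented (bracketed by VVI
  and VVV).
* Cross-sectional only; no trajectories, no item weighting, no latent
  factor layer.
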