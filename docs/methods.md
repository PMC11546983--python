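# Methods

## Distance model

The package is deliberately model-free at the distance level: the
p-distance (proportion of differing sites among sites compared) is used
without multiple-hit correction, because the downstream machinery —
clustering, validity statistics, classification — only needs a monotone
divergence measure, and at the divergences typical of congeneric
mitochondrial comparisons (≲ 0.15) the p-distance is nearly linear in
evolutionary distance. "Ambiguous positions" are removed per pair
(pairwise deletion): a site counts for a pair only if both sequences carry
A/C/G/T there. Each pair therefore has its own denominator `n_valid`,
which is retained in the `DistanceMatrix` and exported in the long-format
table. A pair with no unambiguous overlap raises an error naming both
sequences rather than silently producing a distance.

Within-group distance sets enumerate the full off-diagonal block of the
group's sub-matrix (m·(m−1) values for m members), the convention used
when a symmetric block is plotted point-by-point; averages are unaffected
by the symmetric duplication. Between-group sets hold the |A|·|B| distinct
cross pairs.

Pairwise similarity is defined as `1 − d`. Only the sign relation to the
p-distance is essential; `1 − d` is the simplest monotone choice and keeps
similarity in [0, 1] with a unit diagonal.

Min–max scaling maps the observed extremes to 0 and 1. A constant input
maps to all zeros rather than raising: a contrast-free vector has no
information either way, and erroring would break pipelines on degenerate
fixtures. Scaling of a matrix uses off-diagonal extremes only, so the zero
diagonal does not pin the minimum.

## Clustering

The five algorithms were chosen to span model families (centroid,
agglomerative, factorisation, density, exemplar message-passing); their
agreement — not any single partition — is the delimitation evidence. The
feature representation per algorithm:

* K-means and the validity statistics consume **rows of the distance
  matrix** as feature vectors: sequence i is described by its distance
  profile to every other sequence. This gives all methods a common
  upstream object and makes K-means applicable without choosing a
  sequence embedding.
* Hierarchical clustering (complete linkage) and DBSCAN consume the
  matrix as a **precomputed metric**. DBSCAN runs on the **min–max
  scaled** matrix: its defaults (`eps = 0.5`, `min_pts = 20`, the point
  itself included) are calibrated to a 0–1 distance scale and would
  return a single cluster on raw p-distances that rarely exceed 0.15.
  Both parameters are exposed; `min_pts = 20` presumes groups of ≥ 20
  sequences and must be lowered for small datasets.
* NMF factorises the (non-negative) distance matrix with the
  Kullback–Leibler objective and multiplicative updates, the classic
  formulation for molecular-pattern discovery; of `nrun` random restarts
  the factorisation with the smallest final divergence wins, and each
  sequence is assigned to its dominant basis component. A floor of 1e−9
  replaces exact zeros, which otherwise stall the KL updates; it is far
  below any meaningful p-distance and does not disturb block structure.
  `nrun` defaults to 1000 in the pipeline; tests and the acceptance
  script use 20–100 restarts, which on these matrix sizes already reach
  the same partition (the restart distribution is extremely peaked).
* Affinity propagation consumes the similarity `1 − d` with preference
  set to the median off-diagonal similarity, the customary default that
  lets the cluster count emerge from the data. Damping is 0.5: heavier
  damping (0.9) was observed to over-smooth small instances into a
  single cluster under scikit-learn's update schedule, while 0.5
  converges on both toy matrices and the 95-sequence standard conditions.

Consensus: every partition is relabelled against the first by Hungarian
matching on the overlap matrix, each sequence takes the majority label,
and DBSCAN noise points abstain. Tied votes are resolved by the
hierarchical partition (deterministic given the matrix) and flagged in
the result. Agreement is reported as the pairwise adjusted Rand matrix,
computed over points that are noise in neither partition; `unanimous`
means every pairwise ARI equals 1.

## Cluster-number selection

* **Elbow**: the visual "inflection point" of the SSE curve is formalised
  as the k maximising the second forward difference SSE(k−1) − 2·SSE(k) +
  SSE(k+1); a flat curve leaves the elbow undefined (reported as `None`).
* **Silhouette**: `aᵢ` is the mean within-cluster distance excluding
  self, `bᵢ` the smallest mean distance to another cluster, `sᵢ = (bᵢ −
  aᵢ)/max(aᵢ, bᵢ)`; a singleton cluster scores 0, the standard convention
  for the degenerate branch.
* **Gap statistic**: `gap(k) = E*[log W_k] − log W_k` with W_k from
  K-means, B Monte-Carlo reference datasets, and `se = sd·√(1 + 1/B)`;
  selection by the 1-SE rule (smallest k with gap(k) ≥ gap(k+1) −
  se(k+1)). The reference is drawn uniformly over the ranges of the
  **principal-axis-rotated** data and rotated back (the `scaledPCA`
  null). This matters here: distance-matrix rows are strongly correlated
  features, and a raw axis-aligned uniform box is so much wider than the
  data's support that the gap curve rises monotonically in k and the 1-SE
  rule runs to the end of the range; the PCA-rotated null restores a peak
  at the true k. The axis-aligned variant remains available
  (`reference="uniform"`). B defaults to 100 in the pipeline — on these
  problem sizes the Monte-Carlo error is already far below the gap
  differences that drive selection — and can be raised to 1000 for
  publication-grade curves.

The final `k` is the majority over the three criteria; with three
distinct answers the elbow decides, since a sharp SSE inflection is the
least ambiguous signal on this kind of data. The full curve is always
exported: the gap curve in particular can carry several local maxima and
deserves inspection, not blind argmax.

## Classification

The ordinal encoding (A=1, T=2, C=3, G=4, gap and every IUPAC ambiguity
code = 0) is kept as-is, without one-hot expansion. This is a known
limitation: it imposes an artificial order on the bases which
kernel/linear models inherit; tree ensembles are largely insensitive to
it because any base partition reachable by a categorical split on {0..4}
is reachable by at most two threshold splits. Ambiguity codes share the
gap code 0 because the encoding defines no rank for them and 0 is its
missing-data sink.

Models (scikit-learn): random forest (500 trees, √m features per split),
SVM (RBF kernel, probability estimates enabled so ROC is defined), MLP
(one hidden layer of 100 units, SGD on the log-loss, adaptive learning
rate, max 3000 epochs, no early stopping so that a fixed seed gives a
bit-reproducible fit). Cross-validation is stratified 5-fold: with a
65/30 imbalance, unstratified splits can produce single-class test sets.
Per fold, precision TP/(TP+FP), recall TP/(TP+FN), F1 (harmonic mean,
zero-denominator cases → 0), AUC (Mann–Whitney normalisation, ties at
1/2), and the confusion counts; the report carries per-fold values, the
AUC mean ± sd per model, and summed confusion matrices, and is a pure
function of (data, folds, seed).

Site importance is the forest's normalised mean impurity decrease,
fitted on **all** samples: importance extraction is descriptive, not
predictive, so holding data out would only add variance. Key sites use
strict thresholds (importance > t) and are reported as 1-based alignment
columns sorted by importance. `logo_data` emits per-column A/C/G/T/gap
frequencies plus the importance track, ready for any logo renderer.

## Synthetic data generator

The generator emulates the statistical shape the analysis assumes: a
uniform-random ancestor; one founder per group by per-site substitution
with probability `d_between` (uniform among the three alternatives —
Jukes–Cantor-like, the simplest model consistent with a model-free
distance analysis); individuals from their founder at `d_within`; a set
of planted columns overwritten with fixed, within-group-monomorphic
differences; gaps injected independently at `gap_rate` (never at planted
columns, which would break their monomorphism). Defaults — 733 columns,
group sizes 65/30, `d_within = 0.005`, `d_between = 0.05`, `gap_rate =
0.005`, 6 planted sites — copy the shape of a real two-population shark
control-region dataset, giving within-group mean p-distances near 0.01
and between-group means near 0.11.

Closed-form expectations: the uniform-alternative channel with rate d has
identity eigenvalue `λ(d) = 1 − 4d/3`, so a path through branches with
rates d₁…d_k differs per site with probability `¾·(1 − Πλ(dᵢ))`. Within
pairs traverse two `d_within` branches; between pairs two `d_within` and
two `d_between` branches; planted columns contribute 0 within and 1
between; gaps are excluded pairwise and leave the proportion unbiased.
These formulas are verified against simulation to within 3 Monte-Carlo
standard errors in the test suite.

What the generator does **not** emulate: rate heterogeneity across sites,
indel evolution (gaps are iid, not phylogenetic), recombination-free
genealogy within groups (individuals are a star phylogeny around their
founder), and sequencing ambiguity codes. Passing tests therefore show
the pipeline recovers clean two-lineage structure of realistic size and
divergence; they do not show robustness to rate variation or to deeply
structured within-group genealogies.

One structural consequence is worth stating plainly: at the default
`d_between`, the founder branches fix ~60 additional columns between the
groups, and those columns are statistically indistinguishable from the 6
planted ones. Random-forest importance consequently spreads over the
whole fixed-difference set, and the planted columns — though always
positive-importance — are not preferentially ranked in the top 6. A
planted-site recovery figure at the top-6 cutoff is reported by the
acceptance script for transparency and is expected to be low under these
conditions; ranking the planted sites above their statistical twins would
require information the data do not contain.

## Determinism

Every stochastic stage takes an explicit seed: the generator, K-means
restarts, NMF restart streams (child seeds drawn from a seeded
`default_rng`), affinity propagation's tie-breaking noise, the gap
statistic's reference draws, fold shuffling, and all three classifiers.
Identical (input, config, seed) reproduce every output file bit-for-bit;
the run manifest records the config, seeds and input SHA-256 so a run is
reconstructible from the manifest alone.

## Problem sizes

Tests and the acceptance script run the full standard conditions (95 ×
733) for the headline checks, and reduced instances (20–50 sequences,
200–300 columns, NMF restarts 5–100, gap B 15–100) for unit-level
checks — sizes chosen so the complete suite exercises every stage,
including the five-algorithm consensus and three-criterion selection,
within a few minutes on a single core.
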