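# Methods

## Data model

The unit of analysis is a molecules × descriptors table. Descriptors carry a
block tag — `ADMET` (pharmacokinetic/safety), `ES` (electronic structure) or
`OTHER` — because the two blocks are analyzed separately as well as jointly,
and because their units differ by orders of magnitude (g/mol and kcal/mol
versus eV and unitless counts). Missing values are a hard error: the intended
inputs are small, curated panels, and silent imputation would corrupt every
downstream correlation. Validation failures always name the offending
molecule or descriptor.

## Scaling

Every analysis operates on z-scores, z = (x − μ)/σ, computed per descriptor.
σ uses the population denominator n by default (the convention of the common
standard-scaler implementations); a `ddof=1` switch gives the sample variant.
The choice is immaterial to the Pearson similarity matrix (correlation is
scale-invariant) and to K-means run on it, but it changes the scaled values
themselves, so it is stored with the table (μ, σ per descriptor) and the
transformation is exactly invertible. Binary descriptors (e.g. a
blood–brain-barrier flag) are z-scaled exactly like continuous ones — they
are treated as ordinary coordinates of the profile vector. Scaling is always
applied *after* block selection, so each block-subset analysis has its own
statistics; because scaling is columnwise, this is numerically equal to
scaling first and selecting afterwards, and an integration test pins the
pipeline order anyway. Zero-variance columns are rejected (σ = 0 makes z
undefined); a `drop_constant` flag removes them instead for exploratory use.

## Similarity matrix

M<sub>corr</sub>[i,j] is the correlation of the descriptor vectors of
molecules i and j — correlation across the row dimension of the scaled
table, implemented by transposing and correlating columns. Pearson is the
default and the only method feeding clustering; Kendall and Spearman are
offered for comparison. The matrix is symmetrized against float noise
((M+Mᵀ)/2) and the diagonal forced to exactly 1. A molecule whose scaled
vector is constant has undefined correlations and is rejected by name.

Secondary summaries:

* **Threshold pairs**: off-diagonal pairs with ρ ≥ τ, each reported once,
  sorted by descending ρ. Default τ = 0.75, the conventional "strong
  similarity" cut for this kind of panel.
* **Correlation profiles**: per-molecule five-number boxplot summaries of the
  correlation row, with outliers outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] (the
  standard Tukey fence; whiskers are the most extreme values inside the
  fences). Including the diagonal lets the self-correlation of 1.0 surface
  as a lone upper outlier for molecules weakly correlated with the rest of
  the panel — a useful flag for profile uniqueness.

## K-means with ASED

Lloyd's algorithm: initialize k centroids, repeat (assign each point to the
nearest centroid under the configured metric; recompute each centroid as the
member mean) until the largest centroid shift drops below `tol` (default
1e-6) or `max_iter` (default 300) is reached. Best of `n_init` (default 10)
restarts by final WSS. The seed is a required argument — there is no hidden
global randomness — and results are bit-reproducible given it.

Metrics: `ased`, `l2`, `manhattan`, `cosine`, `correlation`. ASED is
(Σ(aᵢ−bᵢ)²)² = L2⁴, a strictly increasing function of the Euclidean distance
on [0, ∞); argmin assignment is therefore identical to L2's, and with
identical initialization the full trajectory, labels and centroids coincide.
The test suite asserts this equivalence on randomized instances rather than
short-circuiting ASED to L2, so the amplification is really computed and
really shown to be inert for hard assignment. Under Manhattan/cosine/
correlation metrics the mean update is no longer the assignment-optimal
centroid; those metrics are provided for comparison, and the WSS
monotonicity guarantee is only claimed for the squared-Euclidean family.

WSS is always the sum of **squared** Euclidean distances to the assigned
centroid (inertia). The mean-update step is the exact minimizer of that
objective — the reason the non-squared "sum of distances" reading would be
inconsistent with a mean centroid update — and it is the quantity the elbow
method and the convergence check monitor.

Empty clusters during iteration are re-seeded with the point farthest from
its current centroid, a deterministic rule that strictly reduces WSS.
Initializations: `random` (distinct points) and `kmeanspp` (D² sampling).
A "bayesian" initialization is sometimes mentioned in this context but has
no standard definition; requesting it raises `NotImplementedError` rather
than guessing.

For the descriptor-analysis pipeline the feature space is the full row
vectors of M<sub>corr</sub> (N features per molecule): clustering molecules
by the shape of their correlation profile against the whole panel. Any
feature matrix is accepted, though — the elbow/recovery demonstrations also
run directly on scaled descriptors.

### Choosing k

* **Elbow**: WSS(k) per k with best-of-`n_init` restarts (per-k seeds derived
  from the base seed so ks are independent but reproducible), knee suggested
  at the maximum second difference WSS(k−1) − 2·WSS(k) + WSS(k+1). This is
  the crudest discrete-curvature estimate; it is reliable when the WSS curve
  genuinely flattens after the true k (well-separated clusters) and is
  reported as a suggestion, not a decision.
* **PCA variance**: k = smallest m with cumulative explained-variance ratio
  ≥ threshold, default 0.95 ("almost all of the variance"; exposed as a
  flag). This reads the eigenvalue spectrum, so it reflects cluster count
  only insofar as class structure dominates the variance.

## PCA, loadings, descriptor retention

PCA is computed on the scaled table with the full SVD solver,
min(N−1, d) components. Loadings (descriptors × components, orthonormal
columns) carry a deterministic sign convention: each column is flipped so its
largest-magnitude entry is positive; scores are flipped consistently. All
downstream comparisons are made on |loading|, so the convention only
stabilizes output files.

`top_loadings` reports, per component, the descriptor(s) attaining the
maximum |loading|; ties within 5·10⁻³ (two printed decimals) are reported
jointly. `reduce_descriptors` keeps descriptors whose max |loading| over the
first `n_components` (default 5) components reaches `cutoff` (default 0.45)
and emits the retained columns of the raw table for rescaling and
re-analysis. Both defaults are conventions, not derived quantities, and the
rule is fully configurable; note that on correlation-matrix PCA an
*independent* descriptor owns a unit-eigenvalue component concentrated on
itself, so the component window should be chosen to cover the variance-
bearing structure, not the noise floor.

## ROC evaluation of metrics

Ground truth is pairwise same-class membership over all N(N−1)/2 unordered
pairs (degenerate labelings — no positives or no negatives — are rejected).
A metric scores a pair by the negated distance between the two scaled
descriptor vectors; the ROC curve sweeps the unique score values (tied
scores enter simultaneously, giving the step curve consistent with
trapezoidal AUC, via scikit-learn's `roc_curve` with
`drop_intermediate=False`). The central property — AUC and the whole curve
are invariant under strictly increasing transforms of the distance — is
asserted to 1e-12 for ASED vs L2 and for a cubic transform. An exploratory
`cocluster_roc` mode scores pairs by co-cluster assignment at a given k; it
is a coarse two-level diagnostic, not a calibrated metric comparison.

## Synthetic panels

`make_blob_table` emulates the *shape* of a real descriptor panel: default
30 molecules in 5 classes of 6 (a typical size for a curated
quantum-chemistry panel, where DFT cost limits the molecule count), 10
ADMET-like + 14 ES-like descriptors, one binary flag, ADMET-like columns
inflated ×50 to mimic unit heterogeneity (analyses that skip z-scaling fail
visibly on these fixtures). Class centers sit at the vertices of a regular
simplex at a random orientation (every pair of classes equally separated;
a `random`-layout alternative rescales Gaussian centers so the *closest*
pair sits at the requested separation). `separation` is measured in units of
the within-class standard deviation; the default of 6 gives clearly
clustered but not trivial structure, while the recovery studies use 10
(essentially perfect recovery expected) and 0 (chance-level agreement
expected). Binary columns threshold a latent Gaussian centered on the class
center, so their per-class rates converge to 0.5 as separation → 0 — at
separation 0 the classes are indistinguishable in every column.

What the generator does **not** emulate: real descriptor distributions
(skewness, heavy tails, discreteness of counts), realistic inter-descriptor
correlation within a class, or any chemistry. Passing tests on these
fixtures shows the algorithms are implemented correctly and behave as the
theory predicts under known structure; it does not certify performance on
any particular experimental panel.

`make_correlated_pair` plants an exact population correlation ρ between two
vectors (b = ρa + √(1−ρ²)ε) for Monte-Carlo recovery checks of the
similarity machinery.

## Numerical choices and degenerate inputs

* Correlations compared at two decimals where quoted; matrix invariants at
  1e-12; scaling round-trips at 1e-9.
* Assignment ties break to the lowest centroid index (NumPy argmin).
* `k > N`, `k < 1`, empty blocks, empty retention, constant columns/vectors
  and degenerate pair labelings raise typed errors naming the offender.
* Problem sizes in the test and acceptance runs (panels of 30–80 molecules,
  up to ~100 Monte-Carlo repetitions) keep every demonstration well inside
  interactive runtimes while leaving Monte-Carlo error far below the asserted
  tolerances.

## Known limitations

* ASED is inert for hard-assignment K-means by construction; it is included
  and measured because establishing that equivalence (distances, labels,
  centroids, ROC) is part of the package's purpose. Objectives that would
  differentiate it (e.g. ASED-consistent centroid estimation) are out of
  scope.
* The elbow knee by maximum second difference is sensitive to curve
  convexity when clusters are weakly separated; inspect the WSS table rather
  than trusting the single suggested k.
* The mean update is not optimal for the Manhattan/cosine/correlation
  metrics; those runs are heuristic comparisons.
* The 0.45/5-component retention defaults are conventions; retention results
  should be read jointly with the loadings table.
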