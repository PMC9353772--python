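# Methods

This note documents the models and procedures implemented in `mdinet`, the
parameter choices that matter, and what the synthetic benchmarks do and do
not demonstrate.

## Mass-difference networks

**Model.** Nodes are detected neutral monoisotopic masses (Da). For every
unordered pair of features and every mass-difference building block (MDB)
in the active table, an undirected edge labelled with that MDB exists iff

    | |m_u − m_v| − Δm_MDB | ≤ tol(u, v),      tol(u, v) = ppm · max(m_u, m_v) · 10⁻⁶

with `ppm = 1.0` by default. The tolerance is referenced to the **larger**
mass of the pair: relative measurement error scales with the measured mass,
and referencing the difference itself would demand physically unattainable
accuracy. An alternative `sum` reference (`tol_ref="sum"`) is exposed for
sensitivity analyses. The implementation sorts masses and searches a window
per MDB; it is tested to be edge-for-edge identical to the O(n²·|MDB|)
brute-force scan.

Edges are direction-free (a gain one way is a loss the other), and the
graph is a multigraph: if several MDBs match one pair, one edge per match
is created, with no best-match selection. With the default table and masses
below 5000 Da at 1 ppm, parallel edges are effectively impossible, but the
contract allows them; node degree counts parallel edges separately, while
path-based metrics and orbit counts use the simple-graph skeleton (a
documented asymmetry).

**Per-sample networks.** An sMDiN is the induced subgraph on the features
detected (non-missing) in one sample, with degree-0 nodes removed as
uninformative. Because edge existence depends only on the two endpoint
masses, subgraphing is provably identical to rebuilding from the sample's
masses; this equivalence is property-tested.

**The default MDB table.** Fifteen small (< 80 Da), ubiquitous
transformations covering all six common metabolite elements (CHNOPS), plus
two optional glycation-related blocks (carboxymethylation CHCOOH,
carboxyethylation CCH₃COOH) for systems where methylglyoxal chemistry is of
interest. Delta masses are always recomputed from elemental composition
using IUPAC monoisotopic atomic masses hard-coded at ≥ 7 decimals
(C = 12 exact, H = 1.00782503, N = 14.00307400, O = 15.99491462,
P = 30.97376163, S = 31.97207100); a user table with a stated mass that
disagrees with its composition by more than 10⁻⁵ Da is rejected. One naming
caveat: the hydroxymethylation-related block carries its conventional
transformation-list label "CHOH", and its registered composition is CHO
(29.002740 Da); a net CH₂O change (30.010565 Da) is a different block and
is not in the default table. The matching arithmetic uses the registered
29.002740 Da value.

A helper computes theoretical ion m/z for the reference-feature
normalization: [M−H]⁻ subtracts one hydrogen atom and adds one electron
mass (leucine enkephalin C₂₈H₃₇N₅O₇ → 554.262022).

## Graph-metric profiles

Each metric maps a set of sMDiNs to a samples × features matrix with
absence encoded as 0 (never missing), column universe fixed across samples.

- **Degree** — number of incident edges (multiplicity counted).
- **Betweenness** — Σ over unordered pairs {s,t} of σ(s,t|v)/σ(s,t),
  endpoints excluded, **unnormalized**. Library defaults normalize; the
  implementation disables that and is verified against explicit
  shortest-path enumeration.
- **Closeness** — C(v) = ((n−1)/(N−1)) · ((n−1)/Σ_u d(u,v)) where n is the
  size of v's connected component and N the sMDiN node count; this
  component-corrected (Wasserman–Faust) form handles the disconnected
  networks that sMDiNs typically are.
- **MDBI** — per sample, the fraction of edges carrying each MDB label;
  rows sum to 1 whenever edges exist, all-zero for an empty network.
- **WMDBI** — each edge weighted by w(e) = imp(u) + imp(v), where node
  importances are the gini importances of a random forest (default 100
  trees) fitted to the *training* degree profiles, normalized to sum 1
  (uniform fallback if the forest returns all zeros). Per sample, the
  weighted fraction per MDB; a sample whose edges all weigh zero falls back
  to its unweighted MDBI row. WMDBI is the only profile with fitted state:
  in cross-validation the importances must be re-fitted per fold on
  training data only (the harness's `transformer` hook supports this).
- **GCD-11** — per node, counts of the 15 automorphism orbits of all
  connected 2–4-node graphlets, computed by ESU enumeration of connected
  subsets and degree-sequence classification (verified against exhaustive
  subset enumeration). The 11 non-redundant orbits {0,1,2,4,5,6,7,8,9,10,11}
  enter a Spearman correlation (average ranks for ties) across nodes, after
  appending an all-ones dummy row so constant columns never yield undefined
  correlations; any residual undefined entry is set to 0. The signature is
  the 55 upper-triangle off-diagonal entries (C(11,2)); a 66-entry variant
  including the diagonal is available. Five-node graphlets (GCD-73) are out
  of scope.

## Intensity-based pretreatment (IDT)

The baseline pipeline is imputation → normalization → glog → Pareto:

- **1/5-min imputation** — missing ← (per-sample minimum)/5, the
  limit-of-detection heuristic appropriate when values are missing because
  a metabolite is absent or below detection.
- **Random-forest imputation** (missForest-style) — initialize by 1/5-min,
  then per feature with missingness (least-missing first) regress on the
  100 most |Pearson|-correlated features (all, if fewer) with a 50-tree
  forest, samples as observations; iterate until the sum of squared changes
  in imputed cells stops decreasing, max 10 rounds; deterministic under the
  config seed.
- **Reference-feature normalization** — divide each sample by its intensity
  of a lock-mass feature located by mass within a ppm tolerance (default:
  leucine enkephalin [M−H]⁻ 554.262022, 1 ppm); the reference feature is
  removed afterwards. Zero or multiple candidates is an error.
- **PQN** — reference spectrum = per-feature mean over samples; each sample
  divided by the median of its feature-wise quotients against the
  reference (features with positive reference). With a data-derived
  reference, rescaling one sample perturbs the reference, so exact
  scale-invariance holds in the fixed-reference form: with the reference
  held (e.g. fitted on training data), scaling any sample by k > 0 leaves
  the output bit-identical. That fixed-reference form is what the pipeline
  uses on test data.
- **glog** — g(x) = log₂((x + √(x² + λ))/2); λ = 0 is exactly log₂. Default
  λ = (smallest non-missing intensity)², a small offset on the data's own
  scale, since the transform is standard but λ is dataset-dependent.
- **Pareto** — per feature, subtract the mean and divide by √SD (constant
  features → zeros); post-scaling variance equals the pre-scaling SD.

**Leakage guards** (`idt_pipeline(train, test, cfg)`): train features are
filtered to ≥ 2 occurrences in training samples; test data are reindexed to
the train universe; test features occurring in a single test sample are
imputed by 1/5-min rather than the forest; features absent from the test
set are filled with the training minimum; PQN reference, glog λ and Pareto
mean/SD are fitted on train and re-applied to test. Tests assert the train
side is exactly centered while the test side is not, proving no test
statistics leak into the fit.

## Clustering and classification harness

**HCA** is UPGMA (average linkage) on Euclidean distances via
`scipy.cluster.hierarchy.linkage`; ties are resolved by scipy's
deterministic ordering. Statistics on the merge history:

- *Correct clustering %*: a class counts iff some dendrogram node's leaf
  set equals exactly the class's samples.
- *Discrimination distance*: for each correctly clustered class, the gap
  between the height at which its pure node formed and the height of the
  merge that absorbs it, normalized by the maximum merge height; 0 for
  incorrect classes; averaged over classes. The phrase "distance to the
  next closest node" admits a second reading — the absorption height
  itself — which is available via `variant="absorption"`; the gap is the
  default because it measures how long the class persists as a separate
  cluster, which is the robustness notion the statistic is meant to capture.
- *Correct first cluster %*: a sample counts iff its first merge (the
  smallest internal node containing it) joins only own-class samples;
  joining an existing pure own-class cluster counts.

**K-means** (Euclidean, k = number of classes) restarts 20 times keeping
the least-inertia solution. A class is correct iff some cluster equals it
exactly (homogeneity *and* completeness — stricter than the HCA notion, so
lower percentages are expected); its discrimination distance is the
distance from its centroid to the nearest other centroid normalized by the
maximum pairwise centroid distance (the normalization constant chosen as
the centroid-set analogue of the dendrogram's maximum height). Partition
agreement is the adjusted Rand index.

**Classifiers.** Random forest (default 100 trees, gini importances
averaged over folds) and PLS-DA (NIPALS PLS2 via scikit-learn's
`PLSRegression`). PLS-DA encodes multiclass responses one-hot with argmax
decision (ties → lowest class index) and two-class responses as 0/1 with a
0.5 threshold; profiles are auto-scaled inside each fold (fit on train).
The component count can be fixed (4 for MDBI, 6 for WMDBI by default) or
selected by maximizing Q² = 1 − PRESS/TSS under internal stratified CV.
Accuracy is the mean ± SD over (default 20) iterations of re-drawn
stratified k-fold CV. A master seed spawns per-iteration and per-fold
sub-seeds (`numpy.random.SeedSequence`), making every number reproducible
bit for bit. Permutation tests shuffle labels (default 500 times) and
report p = (1 + #{permuted ≥ observed})/(1 + n_perm), never zero. ROC/AUC
pools cross-validated positive-class scores over stratified folds
(trapezoidal AUC), two-class only.

## Synthetic data generator

The generator emulates the occurrence structure the method exploits:

- random CHNOPS seed formulas under the standard elemental-ratio sanity
  bounds (H/C 0.2–3.1, O/C ≤ 1.5, N/C ≤ 1.3, S/C ≤ 0.8, P/C ≤ 0.3,
  P/O ≤ 0.34, ≥ 1 C and H), masses 80–1000 Da;
- mass families grown by randomly applying MDB deltas in either direction
  (children violating counts/ratios rejected), every accepted application
  recorded as a planted edge — so ground-truth network edges are known;
- one consensus mass per feature perturbed by a uniform relative error of
  ± 0.2 ppm by default (well inside the 1 ppm matching window, as for
  aligned ultrahigh-resolution data; the aligned-matrix abstraction has one
  mass per feature, so the error is per feature, not per sample);
- presence drawn Bernoulli-independently per (feature, sample): features
  created by a class's designated "enriched" MDB occur with probability
  0.9 in that class and 0.1 elsewhere; all other features are core, present
  with probability 0.8 everywhere;
- intensities log-normal (μ = 16, σ = 1 on the natural-log scale, the
  magnitude of FT-MS peak heights); absence is MISSING.

Default condition sizes: 3 classes × 3 replicate samples, 40 seed formulas
grown 6 steps each (≈ 230 features). The verification suite uses 5 or 20
samples per class where a statistic needs more replication (clustering
recovery, importance ranking), 30 generator seeds for planted-edge
recovery, 100 random mass sets (n ≤ 200) for the network-oracle
equivalence, and 50 random graphs (≤ 30 nodes) for the orbit oracle —
sizes at which the brute-force references are exact and cheap.

**What passing does and does not show.** The generator plants exactly the
kind of signal the method detects: class-structured occurrence along
MDB-linked families. Success demonstrates the pipeline is correct and can
recover such signal; it does not demonstrate performance on real data,
where occurrence is correlated across features and samples, mass errors are
heteroscedastic, chemistry violates the independence assumptions, and
spurious edges arise from coincidental mass matches at higher masses.
Chromatography, adducts and isotopic envelopes are not simulated.

## Numerical choices and degenerate inputs

- Empty networks are legal everywhere: summaries return zeros, profiles
  all-zero rows, the GCD vector zeros.
- Zero intensities are treated as MISSING on ingestion by default
  (alignment tools emit 0 for absence); disable with
  `zero_is_missing=False`.
- Duplicate-mass merging (masses equal after rounding to 6 decimals,
  matching the precision masses are quoted at) unions occurrence and sums
  co-occurring intensities; the combine rule is configurable and cannot
  affect network structure, which consumes presence only.
- Matching windows include their boundary (≤ tolerance), with a 1 + 10⁻⁹
  slack on the internal search window only (final acceptance is exact).
- All stochastic components accept seeds; derived sub-seeds stay below 2³¹.

## Known limitations

- Betweenness/closeness/orbit computations on very large, dense networks
  (tens of thousands of connected nodes) are not optimized; the intended
  scale is the sparse networks of a few thousand features typical of
  aligned high-resolution datasets.
- No formula annotation or propagation, no spurious-edge curation via
  elemental-ratio constraints, no adduct/isotope handling.
- The GCD signature uses 55 orbit-pair correlations; implementations in the
  wild occasionally quote other counts (66 with the diagonal); both are
  exposed, nothing in between.
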