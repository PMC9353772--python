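# mdinet

Sample-level **mass-difference networks** (sMDiNs) for untargeted
metabolomics profiling and class discrimination.

## The problem

High-accuracy mass spectrometry (FT-ICR, Orbitrap) detects thousands of
metabolite features per sample, conventionally analyzed as an intensity
matrix after imputation, normalization, transformation and scaling. An
alternative representation uses only which features are *present*: with
sub-ppm mass accuracy, two neutral masses that differ by the exact mass of
a small chemical transformation (methylation +CH₂ = 14.015650 Da,
hydroxylation +O = 15.994915 Da, ...) are plausibly related by that
reaction. Linking all such pairs yields a **mass-difference network
(MDiN)**: nodes are detected masses, edges are putative chemical
transformations drawn from a curated list of mass-difference building
blocks (MDBs). Subgraphing the dataset network on the features detected in
one sample (and dropping isolated nodes) gives that sample's **sMDiN** — a
chemically structured fingerprint of the sample that uses occurrence, not
intensity.

`mdinet` builds these networks and turns collections of sMDiNs into
samples × features matrices via six graph metrics, which drop straight into
standard clustering and classification workflows:

| metric | per-sample features | what it captures |
|---|---|---|
| degree | one per mass feature | local connectivity of each metabolite |
| betweenness | one per mass feature | Σ_{s,t} σ(s,t\|v)/σ(s,t) over unordered pairs, unnormalized |
| closeness | one per mass feature | ((n−1)/(N−1))·((n−1)/Σ_u d(u,v)), component-corrected |
| MDBI | one per MDB | fraction of edges attributed to each transformation |
| WMDBI | one per MDB | MDBI with each edge weighted by the summed random-forest importance of its endpoints |
| GCD-11 | 55 orbit pairs | Spearman correlations among the 11 non-redundant graphlet-orbit counts (2–4-node graphlets) |

The package also implements the intensity-based pretreatment (IDT) baseline
these profiles are benchmarked against (1/5-minimum or random-forest
imputation, reference-feature or probabilistic quotient normalization,
generalized log, Pareto scaling, with train/test leakage guards), a
clustering/classification harness with the bespoke performance statistics
(correct clustering %, discrimination distance, correct first cluster %,
adjusted Rand, repeated stratified CV, permutation tests, ROC/AUC), and a
synthetic-data generator that plants MDB-linked mass families with
class-structured occurrence so the whole pipeline is testable end to end.

## Worked example

```python
import mdinet as M
from mdinet.evaluation import (hca, hca_correct_clustering,
                               hca_discrimination_distance, rf_classify_cv)

# 3 classes x 5 samples; each class over-expresses one transformation
data, truth = M.generate_dataset(M.SyntheticConfig(n_classes=3,
                                                   samples_per_class=5, seed=42))
mdbs = M.default_mdb_table()                 # 15 blocks, all < 80 Da
net = M.build_mdin(data, mdbs, ppm=1.0)      # 1 ppm matching tolerance
print(M.summarize(net, total_feature_count=data.n_features))

smdins = M.derive_all_smdins(net, data)
deg = M.degree_profile(smdins, data.feature_ids)
labels = dict(data.classes)
tree = hca(deg)                              # UPGMA, Euclidean
print(hca_correct_clustering(tree, labels),
      round(hca_discrimination_distance(tree, labels), 3))

mdbi = M.mdbi_profile(smdins, mdbs)
res = rf_classify_cv(mdbi, [labels[s] for s in mdbi.index],
                     n_folds=3, n_iterations=20, seed=0)
print(f"{res.accuracy_mean:.3f} +/- {res.accuracy_sd:.3f}")
print(list(res.importances.sort_values(ascending=False).index[:3]))
```

prints

```
NetworkSummary(n_nodes=226, n_edges=234, largest_component_size=12,
               pct_connected_nodes=100.0, diameter=7, radius=4)
100.0 0.133
0.910 +/- 0.079
['CO2', 'O', 'CH2']
```

The 226-feature network connects every feature (the generator grows
features in MDB-linked families). Degree profiles cluster the three classes
perfectly (correct clustering 100%, mean normalized separation 0.133). A
random forest on the 15-column MDBI profile classifies samples at 0.91
accuracy over 20 iterations of stratified 3-fold CV, and its top-ranked
transformations — CO₂, O, CH₂ — are exactly the three planted
class-enriched MDBs (`truth.enriched_mdb`).

The same steps are available from the shell:

```sh
mdn simulate --classes 3 --per-class 5 --seed 42 --out data.tsv
mdn build data.tsv --ppm 1.0 --out net.graphml
mdn profile data.tsv --config data.config.json --metric degree --out degree.tsv
mdn cluster degree.tsv --config data.config.json --method hca
mdn classify degree.tsv --config data.config.json --model rf --folds 3
```

## Layout

- `mdinet.datamodel` — aligned feature × sample matrices, occurrence
  filters, blank subtraction, duplicate-mass merging, TSV/CSV I/O.
- `mdinet.mdbs` — MDB registry: elemental deltas, exact monoisotopic
  masses, default table, CSV I/O.
- `mdinet.network` — MDiN construction (1 ppm default), sMDiN derivation,
  summaries, GraphML/edge-TSV export.
- `mdinet.profiles` — the six graph-metric profile matrices.
- `mdinet.pretreatment` — the IDT baseline pipeline.
- `mdinet.evaluation` — clustering/classification harness and statistics.
- `mdinet.synthetic` — synthetic dataset generator with ground truth.
- `mdinet.cli` — the `mdn` command-line interface.

See `docs/methods.md` for the underlying models, parameter choices and
known limitations.
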