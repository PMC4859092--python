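# psfsom — pathway signal flow portraits of expression cohorts

`psfsom` scores how strongly each signaling route of a curated pathway map is
switched on or off in a sample, and turns those scores into comparable
"portraits" of disease classes. It was built for multi-cohort microarray
compendia of lung diseases (healthy lung, chronic lung diseases, lung
cancers), but runs on any gene-expression matrix plus a collection of
KEGG-style pathway topologies.

The pipeline:

1. **Preprocessing** — probe sets are collapsed to genes, matrices are
   brought to linear scale (a quantile autocheck detects log2/log10 data),
   and every value becomes a fold change (FC) relative to the mean of the
   healthy-control samples of the same dataset.
2. **Pathway signal flow (PSF)** — each pathway is a signed directed graph
   parsed from KGML. A unit input signal enters at the source nodes and is
   propagated towards the sinks: a node multiplies the incoming signal by
   its own FC (mean over the node's genes), an activating edge passes the
   parent signal, an inhibiting edge passes its reciprocal, and multiple
   parents are averaged. The rule is calibrated so FC ≡ 1 gives PSF = 1 at
   every sink; PSF > 1 means pathway activation, PSF < 1 de-activation.
3. **SOM portraits** — sink-wise centered log2 PSF profiles are arranged on
   a self-organizing map (default 50 × 50; learning rate 0.02,
   inverse-learning-rate constant 0.01, neighborhood radius 3, 12 epochs).
   Averaging the unit weights (*meta-PSFs*) over a class's samples gives
   that class's portrait; connected grid regions beyond 90% of the
   portrait's extremes are its over-/under-expression *spots*, and the
   union of spots over classes forms the lettered summary spot map.
4. **Differential testing** — per sink, a shrinkage t-test (pooled variance
   shrunk towards the across-sink median) compares each disease class with
   the controls; a sink is significant when p < 0.05 and
   Benjamini–Hochberg q < 0.2.
5. **Disease communities** — classes become nodes of a graph weighted by
   the number of pathways (or sinks) significantly deregulated in the same
   direction in both classes; random-walk (walktrap) community detection
   groups diseases with shared deregulation states. Hierarchical
   clustering, a second-level SOM, and ICA give complementary views of
   between-class diversity.

A fully tested synthetic-data generator (`psfsom.synth`) emulates the study
setting at desk scale — layered pathway DAGs with activation/inhibition
edges serialized as real KGML, plus a block-structured cohort with planted
deregulation and known ground truth — so every stage is verifiable without
downloading anything.

## Worked example

```python
from psfsom import synth, expression, psf, stats, similarity

design = synth.SyntheticDesign(seed=1)      # 13 classes x 20 samples, 10 pathways
graphs, kgml, expr, sheet, truth = synth.generate_dataset(design)

linear, how = expression.detect_and_linearize(expr)   # 'linear'
fc = expression.compute_fold_change(linear, sheet)
psf_matrix = psf.compute_psf_matrix(graphs, fc)       # 62 sinks x 260 samples

diff = stats.differential_psf(psf_matrix, sheet, "B1C1", "HC")
print(diff["significant"].sum())                      # 23 significant sinks

graph = similarity.build_disease_graph(
    stats.differential_all_classes(psf_matrix, sheet, "HC"), level="sink")
print(similarity.walktrap_communities(graph).to_string())
```

The community printout groups the twelve disease classes exactly into the
four planted blocks:

```
B1C1    0
B1C2    0
B1C3    0
B2C1    1
...
B4C3    3
```

The numbered scripts under `analysis/` run the same steps as narrative
drivers and write their tables under `results/`. `analysis/06_benchmark_recovery.py`
scores the full pipeline against the planted truth over 20 seeds and prints

```
20-seed means: recall 1.000, false-positive rate 0.046, walktrap ARI 1.000,
super-group split (Pearson) 100%, (Euclidean) 100%
```

i.e. every planted deregulated sink is recovered, fewer than 5% of truly
unaffected sinks are falsely called, the walktrap communities match the
planted disease blocks perfectly, and the first split of the dendrogram
separates the two planted disease families under both similarity metrics.

There is also a CLI (`psfsom simulate|preprocess|psf|som|spots|diff|graph|run`)
that chains the stages from a JSON config and writes a manifest with file
checksums so reruns are verifiably identical; see `psfsom --help`.

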