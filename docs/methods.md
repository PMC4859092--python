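# Methods

This note documents the models and procedures implemented in `psfsom`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Pathway model

A pathway is parsed from KGML into a signed directed graph. Entries of type
`gene`, `compound` and `group` become nodes (`group` members are flattened
into one multi-gene node, matching the rule that a node's fold change is
the mean over its genes); entries of type `map` and the relations touching
them are dropped. A relation whose subtype names contain "inhibition" or
"repression" gets sign −1; all other subtypes (including "indirect effect"
and unknown ones) default to +1 — the conservative reading of KGML
annotation. Sources are nodes of in-degree 0, sinks of out-degree 0.

Curated maps contain feedback loops, but signal propagation needs a
topological order. Cycles are broken by depth-first search rooted at the
source nodes (then at any remaining unvisited nodes), visiting ids in
lexicographic order and discarding every edge that closes a cycle onto the
active DFS stack. The rule is deterministic, so repeated runs of a pipeline
remove identical edge sets; removed edges are logged. A pathway whose every
node lies on a cycle has no entry point and is rejected.

## Preprocessing

Probe-level matrices are collapsed by arithmetic mean over the probes of a
gene after dropping unmapped probes. The scale autocheck computes the
quantiles (0, 0.25, 0.99, 1) of the matrix and declares it linear if the
99th percentile exceeds 100, or if the range exceeds 50 with a strictly
positive lower quartile; otherwise log2 is assumed and the matrix is
exponentiated (log10 only on explicit request). Probe collapsing runs on
whatever scale the input is in; means are therefore linear-scale means
whenever the input is linear, which is the representation everything
downstream uses.

Fold change is computed per dataset: FC(g, s) = x(g, s) / mean of x(g, ·)
over that dataset's control samples. Genes with non-positive control means
are dropped with a warning. By construction the control-sample FCs of every
gene average to exactly 1, which is the only cross-dataset harmonization
performed — no batch correction, mirroring a design in which each dataset
carries its own controls.

## Pathway signal flow

For one sample, node weights are the gene-mean FCs (1 for compound nodes
and nodes without measured genes, preserving topology when expression is
incomplete). In topological order:

* source: signal = input_signal × FC(source), input_signal = 1 by default;
* other node v: each parent u contributes signal(u) for an activating edge
  and 1/signal(u) for an inhibiting one; signal(v) = FC(v) × arithmetic
  mean of the contributions.

The arithmetic-mean combination (rather than a sum) makes the calibration
contract hold for any in-degree: FC ≡ 1 implies PSF = 1 at every sink,
verified exactly over thousands of random topologies. Reciprocal inhibition
makes sink activity strictly monotone in an upstream FC, with direction set
by the parity of inhibiting edges on the path. PSF values at sinks of one
pathway are reported as rows `pathway_id:sink_node_id`; propagation is
vectorized over samples.

For map training and class comparison, PSF is log2-transformed and each
sink row is centered on its mean over all samples ("centralized"), so
values express deviation from the cohort-average activity of that sink.
The log scale is the natural one here: differential activity is a log fold
difference, and multiplicative propagation becomes additive.

## SOM portraits and spots

Online Kohonen training arranges the sink profiles (one value per sample)
on a rectangular grid; defaults follow the published configuration
(50 × 50 grid, learning rate α₀ = 0.02, inverse decay α_e = α₀/(1 + 0.01 e)
per epoch e, Gaussian neighborhood truncated at radius 3, 12 epochs,
Euclidean matching). Desk-scale analyses and the test-suite use 10 × 10
grids.

Two numerical choices matter at small scale and are this package's own:

* **Linear initialization.** Units start on the plane of the first two
  principal components, spanning the data's PC-score range. A random
  initialization leaves units that no sink ever wins at arbitrary values;
  on sparse maps those values can exceed the real signal and corrupt class
  portraits. With linear initialization untouched units always hold
  data-like profiles and the map is globally ordered from the start, which
  is also why a fixed (non-decaying) neighborhood radius suffices.
* **Per-epoch learning-rate decay.** The inverse-learning-rate constant is
  applied per epoch, not per presentation step; a per-step reading freezes
  the map after a few hundred updates and leaves it untrained.

A class portrait is the mean of the unit weights over the class's samples.
Spots are 4-connected components (non-toroidal borders) of units at or
beyond 90% of the portrait's signed extreme — read as a fraction of the
extreme value, not a quantile; an alternative k-means spot method is
available via `spot_method="kmeans"`. The summary map unions all class
over-spots and letters merged components by descending peak value. Spot
detection highlights the dominant co-deregulated modules; planted sinks of
widely differing amplitude are intentionally *not* all captured, since the
threshold tracks the extreme.

## Differential testing

Per sink, the two-sample t-statistic uses a pooled variance v_k shrunk
towards the across-sink median v_med:

    v*_k = λ v_med + (1 − λ) v_k,
    λ = min(1, Σ_k Var̂(v_k) / Σ_k (v_k − v_med)²),

with Var̂(v_k) the standard unbiased estimate of the sampling variance of a
sample variance computed from the pooled within-group squared residuals —
a shrinkage-t in the Opgen-Rhein/Strimmer spirit, stabilizing inference at
small n. Degrees of freedom are n₁ + n₂ − 2 (no Welch correction; a
documented approximation alongside the pooled shrunken variance).
Benjamini–Hochberg q-values control FDR, and the significance call is the
double criterion p < 0.05 ∧ q < 0.2. On null simulations the empirical
type-I error at p < 0.05 sits within [0.03, 0.07].

## Disease similarity and communities

The co-regulation graph links two classes when at least one sink is
significant in both with the same sign of delta. Edge weights count
pathways by default — the published convention for the disease graph — but
a `level="sink"` option counts shared sinks instead. The benchmark and the
analysis scripts use sink-level weights: with only ten desk-scale pathways,
pathway-level weights saturate at the number of planted pathways and lose
the graded sharing structure that community detection relies on; shared
sinks are also what the class-community tables of this analysis style
report. Communities come from Pons–Latapy walktrap (weighted random walks
of length 4, agglomerative merging, maximum-modularity cut); isolated
classes form singleton communities.

Hierarchical clustering uses average linkage on either 1 − Pearson r or
Euclidean distance. The class profiles clustered in the analyses are
*differential* profiles — the class-mean centralized log2 PSF minus the
control-class profile — matching the differential portraits computed
against healthy controls; with cohort-centered (non-differential) profiles
each class's strong private deregulation induces anti-correlation terms
against every other class that can mask family structure. The second-level
SOM reuses the map trainer on class profiles; ICA (FastICA) components are
sign-fixed by making each component's largest-magnitude score positive, so
seeded runs are exactly reproducible.

## Synthetic data and what the benchmark shows

The generator builds layered DAGs (each node has a parent in the previous
layer and a child in the next, so sinks are exactly the last layer), signs
edges inhibitory with a configurable probability, gives every node its own
genes, and serializes valid KGML so the real parser is exercised. Baseline
expression is log-normal (meanlog 7, sdlog 1 — intensities that the scale
autocheck correctly declares linear); each sample multiplies the baseline
by 2^N(0, σ) gene-wise noise with σ = 0.3 on the log2 scale; disease
samples additionally multiply the genes of their planted targets by the
effect size (2 by default; reciprocal for down-regulation).

The default cohort has one control class and 4 disease blocks of 3 classes
(20 samples each). Each block fully deregulates its 2 own pathways, with
alternating up/down directions across the block's pathways so class
profile means stay balanced. Two additional unbranched activation-only
*mirror chains* are deregulated by every disease class — upward in blocks
1–2 ("cancer-like"), downward in blocks 3–4 ("inflammation-like"). A fully
deregulated chain compounds the per-gene effect deterministically along
its length, so the mirror dominates between-class profile similarity and
drives the family split in hierarchical clustering, while contributing
only its single sink per chain to the co-regulation graph — sharing the
same sinks with *opposite* signs between families produces no co-regulation
edge across them, leaving the block structure dominant for community
detection.

Ground truth is derived by noise-free propagation of the planted factors:
sinks whose |log2 shift| reaches half the per-gene log2 effect are truth
sinks with their propagated sign (inhibition can attenuate or flip a
planted direction); weaker nonzero shifts are recorded as background and
excluded from both recall and false-positive accounting, since calling
them is neither a hit nor an error. The false-positive rate is measured
over exactly-null sinks; note that the significance rule itself admits up
to 20% FDR by construction, so FDR — not the null false-positive rate — is
the quantity bounded by the q-threshold.

At the benchmark's conditions (10 pathways, effect size 2, noise 0.3,
20 samples per class, 10 × 10 SOM grids, 20 seeds) the pipeline attains
recall 1.0, mean false-positive rate ≈ 0.05, walktrap ARI 1.0 against the
planted blocks, and a correct family split in every seed under both
metrics. What this does *not* show: the generator has no probe-level
artifacts, no batch structure between datasets, no correlated gene noise,
and its pathways are far smaller and more regular than curated maps —
passing tests demonstrate the correctness and calibration of the
machinery, not clinical performance on real cohorts.

## Problem sizes and reproducibility

Tests and analyses run at desk scale: 10 pathways (~60 sinks), 260
samples, 10 × 10 maps; the benchmark repeats the full pipeline over 20
seeds. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`), SOM training and ICA are seeded and
sign-fixed, cycle breaking and row orders are deterministic, and the
pipeline manifest records SHA-256 checksums of every artifact so a rerun
with the same config is verifiably identical.

## Known limitations

* The multi-parent mean and reciprocal inhibition are one defensible
  propagation rule; max/min or sum-based combinations are out of scope.
* Cycle breaking is greedy and order-dependent by design (deterministic,
  but not a minimum feedback-arc set).
* The shrinkage-t degrees of freedom ignore the variance shrinkage's
  effective sample size; with many sinks the approximation is standard.
* With few samples per class, the shared control group induces positive
  correlation between per-class differential results; sinks where the
  control mean is extreme can reach significance in several classes at
  once. Large control cohorts dilute this; the co-regulation graph
  inherits it as occasional spurious low-weight edges.
* GEO Series Matrix parsing covers the plain-text single-table layout;
  probe annotation must be supplied as an explicit probe→gene map.
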