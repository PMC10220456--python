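# Methods

## The model

A competing-endogenous-RNA (ceRNA) network is an undirected weighted graph
over genes: an edge between genes *i* and *j* records that the two
transcripts are inferred to compete for a shared pool of miRNAs, with an
effect size *w_ij* (mscor for SPONGE-style networks, plain correlation for
simpler inference) and usually an adjusted p-value. This package does not
infer such networks; it consumes them.

The method has four stages.

**1. Filtering.** Edges are kept when `p_adj < p_adj_max` (default 0.05)
and `weight > weight_min` (default 0.1): significant associations with
non-negligible effect size. Networks without a significance column are
filtered on weight alone. An optional Benjamini–Hochberg step
(`adjust_p=True`, via `scipy.stats.false_discovery_control`) treats the
column as raw p-values; off by default because ceRNA tools conventionally
report adjusted values.

**2. Weighted centrality and modules.** For node *i* in the filtered
network,

    Degree_i     = Σ_j x_ij                 (x_ij = 1 iff an edge exists)
    Strength_i   = Σ_j w_ij
    Centrality_i(α) = Degree_i^(1−α) · Strength_i^α

α interpolates between counting partners (α=0) and summing effect sizes
(α=1). The default α=1 ranks ceRNAs by total sponge cross-talk. The top-k
nodes (default k=750; restrictable to a gene class such as lncRNAs) become
module centers, and a module is the center plus its first-degree neighbors
in the filtered network. Modules are then intersected with the genes
actually measured in a given expression matrix and kept when their
remaining size is within [10, 200], the conventional gene-set window for
single-sample enrichment. The center itself may be unmeasured; the module
survives on its neighbors.

**3. Scoring.** Module activity per sample comes from single-sample
enrichment of the module gene set:

* *Overall Expression (OE, default).* Expression is centered per gene
  across samples; genes are assigned to `n_bins` (default 50)
  equal-frequency bins by mean expression; each of `n_control_draws`
  (default 100) control sets replaces every module gene by a random gene
  from the same bin. Score = mean centered module expression − mean control
  expression. The subtraction removes abundance-dependent technical trends.
* *ssGSEA.* Per sample, genes get average ranks; walking the list in
  decreasing-rank order, ES = Σ_i (P_in(i) − P_out(i)) with P_in the
  cumulative `rank^τ`-weighted in-set ECDF (τ = 0.25) and P_out the
  unweighted out-of-set ECDF. Purely rank-based, hence invariant to
  monotone per-sample transforms.

The exact kernel-density GSVA variant is not implemented; OE is the default
engine and ssGSEA the rank-based alternative, and on planted data the two
rank samples concordantly (tested: Spearman ρ > 0.8).

**4. Classification and prioritization.** Scores (modules × samples)
feed a classifier: random forest by reference, linear SVM and gradient
boosting behind the same `ModelSpec` interface. Hyperparameters (mtry; C;
nrounds/max_depth/eta) are tuned by stratified repeated cross-validation
(default 3×10-fold) maximizing subset accuracy — the fraction of samples
whose label is predicted exactly — and the winning configuration is refit
on the full training set. An independent cohort, scored with the *same*
modules, gives the external test accuracy; no refitting occurs there.
Module importance is the forest's mean decrease in Gini impurity. The null
model draws, for each real module, a random module of identical size from
the genes present in both the filtered network and the expression matrix,
and repeats the whole scoring/training protocol.

## Numerical and design choices

* **Determinism.** Edge tables are canonicalized (lexicographic endpoint
  order, duplicates collapsed keeping the first, stable sorts throughout);
  ranking ties break by identifier; hyperparameter ties break toward the
  smallest values; every random step consumes an explicit seed, and the
  pipeline derives independent per-stage seeds from one master seed via
  `numpy.random.SeedSequence`. Two runs with the same config are
  byte-identical in their score matrices. Strength is accumulated by
  scatter-adding all `gene_a` endpoints in edge order, then all `gene_b`
  endpoints — fixing the float summation order is part of the
  reproducibility contract.
* **Degenerate inputs.** Isolated nodes get centrality 0 (0^(1−α)·0^α is
  taken as 0: an unconnected ceRNA has no sponge activity). Genes constant
  across samples have exactly zero centered expression in OE (enforced,
  not left to rounding). A module covering every measured gene is an error
  in ssGSEA (no out-of-set ECDF). Genes with any missing value are dropped
  per dataset with a logged count. Mixed presence/absence of p-values in
  one edge table is an error rather than a silent half-filter.
* **ssGSEA ties.** Average ranks equalize the weights of tied genes, but
  the interleaving of tied in-set and out-of-set genes still affects the
  running sum; the walk order is fixed deterministically by input gene
  order.
* **Module building contract.** Centers must be nodes of the filtered
  network (they are selected from its centrality table, so a center with no
  surviving edge cannot arise in the pipeline). `include_center` defaults
  on. Random-module sampling draws from the intersection of network and
  expression genes so the null modules are always scoreable.
* **Cross-cohort feature matching.** When a test cohort is supplied, the
  pipeline size-filters modules against both cohorts and uses the
  intersection, so train and test score matrices share features; a missing
  feature at evaluation time is an error, never imputed.

## The synthetic benchmark

The generator (`spongeffects.simulate`) emulates the study design, not the
biochemistry. `simulate_cerna_network` builds a hub-and-spoke topology —
`n_hub_genes` hubs (default 10) with disjoint neighborhoods of 15–30
spokes, plus sparse random background pairing — because the method
presupposes hubs: centrality selection must have something to find. Edge
weights are uniform on (0.15, 0.9) and adjusted p-values below 0.045, the
regime of an already-plausible ceRNA network, so default filtering is a
pass-through in simulation. `simulate_expression` gives every gene a
baseline mean uniform on [2, 12] (log2 scale; spreads genes across OE's
abundance bins) with i.i.d. Gaussian noise (SD 0.5) and shifts each planted
module's genes by ±1.0 (alternating sign across modules) in one class's
samples. Defaults: 5 balanced classes × 50 samples, 5 of the 10 hub
modules informative, 1500 genes total so planted genes are a small minority
of the pool that size-matched random modules draw from.

What this does *not* emulate: correlated gene–gene noise, batch and
platform effects, class imbalance, overlapping modules, and explicit
miRNA titration kinetics. Passing benchmarks therefore demonstrate that the
machinery recovers module-level additive signal under honest nulls — not
that any particular biological cohort will classify equally well.

Benchmark problem sizes (`spongeffects.benchmark`) are chosen at desk
scale: the planted-recovery run uses the default 1500-gene, 2×250-sample
design with 300-tree forests; chance calibration uses a 600-gene,
150-sample cohort with 20 label permutations and 5-fold CV; the
missing-gene experiment uses 100 trials of a 400-gene, 100-sample, 3-module
design. On one CPU the three together run in about two minutes.

## Known limitations

* OE scores depend on dataset-level centering and binning, so adding
  samples re-centers everyone's scores; ssGSEA is strictly sample-local.
  Cross-cohort comparisons should score each cohort separately (as the
  pipeline does) rather than concatenate.
* Centrality ties at the k-th rank are cut deterministically, not included.
* Gini importance inherits the known bias of impurity measures toward
  high-variance features; scores are roughly variance-matched across
  modules, which mitigates but does not remove it.
* The miRNA ranking counts module-internal edge annotations
  (`scope="internal"`); edges incident to a single module gene can be
  counted with `scope="incident"`, but no significance model is attached to
  either count.
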