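# wallnet

Weighted gene co-expression network analysis linked to cell wall composition.

`wallnet` is for plant systems biologists who want to connect transcriptome-wide
co-expression structure with compositional phenotypes — cellulose (% dry
matter), the hemicellulose monosaccharides xylose/arabinose/galactose (mg/g)
and the H/G/S monolignols (μmol/g) measured across a panel of tissues. It
implements the full chain from probe-level microarray intensities to a
trait–module relevance network, and ships a synthetic-data generator with
planted structure so every stage is testable without any download.

## The method

Given a genes × samples expression matrix, the network is built in three steps:

1. **Similarity** — S_ij = |cor(x_i, x_j)|, the absolute Pearson correlation
   of the two expression profiles.
2. **Soft-threshold adjacency** — A_ij = S_ij^β with β ≥ 1 chosen as the
   smallest power at which the connectivity distribution
   k_i = Σ_{j≠i} A_ij approximates a scale-free law (signed R² of the
   log-log frequency fit ≥ 0.8).
3. **Topological overlap** — TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
   where l_ij = Σ_u a_iu a_uj sums shared-neighbour weight; 1 − TOM is the
   dissimilarity for average-linkage hierarchical clustering.

The dendrogram is cut into modules (minimum size 50; label 0 = unassigned),
near-collinear modules are merged at eigengene dissimilarity 0.20, and each
module is summarised by its **eigengene** — the first principal component of
its standardised member profiles. Genes carry connectivity statistics
(kTotal = kWithin + kOut, and kME, the correlation with a module eigengene)
used to rank hubs.

Modules meet the traits twice:

* **Correlation screening** — eigengene–trait Pearson correlations with
  two-sided Student asymptotic p-values (t = r√(n−2)/√(1−r²), df = n−2);
  within a module, candidate genes for a trait are those whose p-value falls
  below the 25th percentile of the module's p-value distribution, and
  candidates are classified by the combination of traits they pass
  ("Cel", "Cel + Xyl", "Multi", ...).
* **Regularized CCA** — ridge-penalised canonical correlation between the
  trait block X (samples × traits) and the eigengene block Y (samples ×
  modules); penalties are mandatory when modules outnumber samples.
  Correlations of the original variables with the averaged canonical
  variates (canonical structure correlations) give each trait and module a
  coordinate per component, and their cross-block inner products, thresholded
  at |score| ≥ τ = 0.5, form a signed bipartite relevance network.

One-sided Fisher / hypergeometric term enrichment against user-supplied
annotation maps (GMT or two-column TSV) identifies what each module does.

## Worked example

```python
import wallnet as w

design = w.PlantedDesign(seed=1)            # 5 modules x 100 genes + 200 noise genes, 29 samples
expr, truth = w.generate_expression(design)
traits = w.generate_traits(truth, design)   # 7 cell wall traits on published ranges

result = w.CoexpressionNetwork(expr).fit()  # selects beta, builds TOM, detects modules
print(result.summary())

cca = w.TraitCCA(traits, result.eigengenes).fit(tau=0.5)
print(cca.summary())
```

prints

```
Co-expression network results
===============================
genes: 700   samples: 29
soft threshold beta: 18 (scan max signed R2 = 0.848)
modules: 5   unassigned genes: 173

module  size  var_explained
   ME1   117  0.552
   ME2   111  0.631
   ME3   107  0.659
   ME4    97  0.709
   ME5    95  0.719

Regularized CCA results
=========================
traits: 7   eigengenes: 5   samples: 29
lambda_x=0.1  lambda_y=0.1
canonical correlations (first 5): 0.942, 0.909, 0.353, 0.123, 0.085
structure components retained: 3
relevance network: 7 edges at tau=0.5
```

The five planted modules are recovered (plus the unassigned noise genes), the
eigengene of each explains 55–72 % of its module's variance, and the two
leading canonical components tie the module eigengenes to the traits they
drive. `result.trait_correlations(traits)` returns the modules × traits grid
of (r, p); here the cellulose/Xyl-driving module correlates with those traits
at r ≈ 0.95–0.97 while decoy modules stay near zero.

A command-line interface mirrors the library
(`wallnet simulate | preprocess | modules | traits | screen | cca | enrich | run`);
`wallnet run --out rundir` executes the whole pipeline on the default
synthetic design and writes every intermediate plus a `summary.json`.

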