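# neurocoex

Co-expression module preservation analysis for case/control transcriptomics,
built around the question that motivates it: when a set of genes is
co-regulated in one group of brains (say, controls), does that co-regulation
survive in another group (say, schizophrenia cases)? The package implements
the full analysis chain around that question, from two-colour microarray
differential expression through weighted network construction to permutation
preservation statistics — together with synthetic-data generators that plant
known structure, so every stage can be validated end to end without access
to any cohort data.

## Who this is for

Bioinformaticians analysing small case/control expression cohorts
(microarray or otherwise) who want a transparent, fully scripted version of
the classic weighted co-expression workflow: self-self-calibrated
differential expression on two-channel arrays, β-value methylation
transition screens, Wilcoxon and permutation covariate scans on bulk
cohorts, permutation gene-set enrichment against reference module
collections, unsigned WGCNA-style networks with adaptive tree cutting, and
module-preservation Z statistics.

## The core model

**Network.** For a genes × samples matrix X, the unsigned adjacency is
a_ij = |cor(x_i, x_j)|^β, with the soft power β chosen as the smallest
candidate whose connectivity distribution satisfies the scale-free topology
criterion (R² ≥ 0.8 on the log-log connectivity histogram; β = 7 is the
reference default). Pairwise similarity is the topological overlap measure

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

and modules are branches of the average-linkage dendrogram of 1 − TOM, cut
adaptively (minimum module size 20, deepSplit 2). Each module is summarised
by its eigengene (first principal component of the standardised member
profiles); membership strength kME is the correlation of a gene with the
eigengene, and hubs are genes with kME > 0.75 to their own module.

**Preservation.** Modules defined in a reference dataset are scored in a
test dataset by three density statistics (mean intra-module |cor|, mean
adjacency, eigengene variance explained) and three connectivity statistics
(reference-vs-test correlation of intramodular connectivity, of kME, and of
the intra-module correlation pattern). Each statistic is converted to a
permutation Z against random gene sets of the same size;
Z_summary = (median density Z + median connectivity Z) / 2, with
Z_summary > 10 strong, 2 < Z_summary ≤ 10 moderate, and ≤ 2 not preserved.
A rank-based medianRank is reported alongside as a size-insensitive
ordering.

## Worked example

Simulate a 29-case / 30-control cohort with three planted modules (sizes
40/30/20, factor loading 0.9), one of which loses its shared factor in the
cases; detect modules in controls; test their preservation in cases:

```python
from neurocoex import CoexpressionNetwork, ModulePreservation
from neurocoex.simulate import SimCohortConfig, ModuleSpec, gen_brain_cohort

cfg = SimCohortConfig(
    n_genes=300,
    module_specs=[ModuleSpec(40, 0.9, True), ModuleSpec(30, 0.9, True),
                  ModuleSpec(20, 0.9, False)],   # last module destroyed in cases
    seed=1,
)
expr, meta, truth = gen_brain_cohort(cfg)
ctrl = expr.loc[:, (meta["diagnosis"] == "control").to_numpy()]
case = expr.loc[:, (meta["diagnosis"] == "case").to_numpy()]

net = CoexpressionNetwork(ctrl, power=7, min_module_size=20).fit()
print(net.summary())
pres = ModulePreservation(ctrl, case, net.modules, power=7,
                          n_permutations=1000, seed=2).fit()
print(pres.summary())
```

Output:

```
Co-expression network summary
  genes: 300  samples: 30
  soft power: 7  (unsigned, |cor|^beta)

  module          size  varExpl  hubs
  unassigned       210
  turquoise         40    0.752    40
  blue              30    0.835    30
  brown             20    0.811    20

Module preservation (permutation Z statistics)
  permutations: 1000  power: 7

  module          size   Zdens   Zconn    Zsum  medRank  class
  turquoise         40   49.06   -1.69   23.69      1.5  strong
  blue              30   41.81   -2.52   19.65      1.5  strong
  brown             20   -0.53   -2.07   -1.30      3.0  not_preserved
```

The three planted modules are recovered exactly (40/30/20 genes, eigengene
variance explained 0.75–0.84). The two modules whose shared factor survives
in cases score Z_summary ≈ 20–24 (strongly preserved); the factor-destroyed
module scores −1.3 (not preserved) and ranks last by observed statistics —
exactly the planted contrast.

The same chains are scriptable from the shell via the `neurocoex` CLI
(subcommands `simulate`, `cellmodel`, `brain`, `preservation`, `mset`,
`enrich`), which reads and writes tab-separated matrices, GMT collections
and JSON summaries.

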