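# Methods

This note documents the statistical procedures implemented in `neurocoex`,
the parameters that matter, the design choices made where the methodology
left them open, and what the synthetic-data validation does and does not
establish.

## Two-channel differential expression with self-self calibration

A self-self hybridization labels the same RNA with both dyes on one array,
so its log2 ratios M sample the technical null at every mean log intensity
A. After within-array LOWESS normalization of M on A (span 0.2, fitted on
reliable probes and interpolated to all probes; arrays with fewer than 10
reliable probes are refused), the null envelope is estimated per
equal-occupancy A-bin (default 20 bins, merged until each holds ≥ 20
probes) as the empirical (1−q)/2 and 1−(1−q)/2 quantiles of M at
credibility q = 0.99, interpolated piecewise-linearly between bin midpoints
and extended flat beyond the observed A range. A test probe is called
up/down only when its M strictly exceeds the envelope at its A; a probe
exactly on the envelope is flat (conservative convention).

Gene-level calls require, in **every** replicate: ≥ 2 probes; *more than*
50% of probes reliable (strict, following the rule's wording); and ≥ 80%
(inclusive) of the *reliable* probes sharing one non-flat direction —
unreliable probes carry no direction, so they are excluded from the
agreement denominator (configurable). The direction must agree across
replicates. Condition-exclusive genes are the case calls whose gene is
absent from the control calls in either direction.

Calibration: on held-out self-self data the non-flat call rate matches
1 − q within ±0.003 at 10⁵ probes. On synthetic arrays with planted
effects ≥ 4·σ(A), sensitivity ≥ 0.9 at false-discovery proportion ≤ 0.1.

## Methylation transitions

β-values are categorized inclusively: β ≤ 0.2 hypo-methylated, β ≥ 0.8
hyper-methylated, otherwise intermediate. "Differentially methylated"
between two cell types of one subject is operationalized as a **full
category flip** (hyper↔hypo); intermediate values never transition. The
alternative reading — any category change, including transitions through
the intermediate band — is available via `mode="any_change"` and flagged in
output metadata. Case-exclusive transitions are the set difference of
(CpG, direction) pairs between subjects. Fibroblast panels are carried and
reported but do not enter the exclusivity rule.

## Brain cohort statistics

**Rank-sum scan.** Per-gene two-sided Wilcoxon rank-sum between diagnoses:
exact null distribution when the combined n ≤ 25 without ties, otherwise
the tie-corrected normal approximation. Genes with p < 0.01 are flagged;
BH-adjusted values are reported alongside but deliberately not used for the
flag (the screen is an uncorrected one). Constant genes get p = 1 with a
warning.

**pH permutation scan.** The regression design is
`expression ~ diagnosis + pH` with the partial F for pH, permuting pH only
(diagnosis intact), p_perm = (1 + #{F_perm ≥ F_obs}) / (n_perm + 1)
(plus-one: permutation p-values are never zero). The partial F is computed
by double residualization on diagnosis, which reduces each permutation to
one correlation per gene and makes 1000 permutations over thousands of
genes cheap. Covariates beyond pH are out of scope but the residualization
design extends naturally.

**Stage filters.** Developmental RPKM panels are gated by
fraction(RPKM ≥ 1) > 0.75 **or** IQR > 0.5 (a disjunction: broadly or
dynamically expressed). Stage fold change is direction-symmetric,
max(m1/m2, m2/m1) of group means with pseudocount 0.01 against zero means;
stage-differential means fold change > 2.

## MSET

The Modular Single-set Enrichment Test scores a query set against each
reference module by permutation: the observed overlap is compared with the
overlaps of random sets of size |query ∩ background| drawn uniformly
without replacement from the background, with the plus-one p-value
convention. Query genes absent from the background are dropped before
sizing (the array could never have produced them), and modules are
restricted to the background. One shared pool of draws is scored against
all modules — statistically equivalent to independent pools, since each
module's p depends only on the marginal overlap distribution. At default
n_sim = 10,000 the Monte-Carlo p agrees with the exact hypergeometric tail
within 3 standard errors on every small-background configuration tested.

## Network construction

Unsigned adjacency |cor|^β (Pearson; absolute value keeps odd powers in
[0, 1]), diagonal 1. The soft power is the smallest candidate whose
connectivity distribution fits a scale-free law with signed R² ≥ 0.8
(10 equal-occupancy bins of log10 k, regression of log frequency on log
mean bin connectivity, R² zeroed for positive slope); if none passes, the
best-fitting power is used with a warning. TOM follows the standard
shared-neighbour formula and is validated element-wise against a
brute-force triple loop at 1e−12.

**Adaptive tree cut.** Average-linkage clustering of 1 − TOM, then a
dynamic-hybrid-style branch decomposition authored for this package:

1. an adaptive cut at 99% of the range between the 5th percentile and the
   maximum of merge heights defines coarse branches;
2. within a branch, two children are split apart when each is a viable
   cluster — ≥ `min_module_size` leaves (default 20), normalized core
   scatter (mean internal merge height) ≤ maxCoreScatter, and a gap from
   the parent merge to the child's *core top* ≥ minGap;
3. otherwise the branch spine is walked from the top, peeling small side
   branches; the largest normalized height drop along the spine, when it
   exceeds minGap, separates fringe (unassigned) from the branch core;
4. a PAM-like stage reassigns unassigned genes to the nearest cluster by
   average dissimilarity, but only within the cluster's own peripheral
   radius (95th percentile of member-to-cluster dissimilarity), so
   background genes stay unassigned.

`deep_split` ∈ {0..4} maps to maxCoreScatter (0.64, 0.73, 0.82, 0.91,
0.95) with minGap = (1 − maxCoreScatter)·3/4; higher values split more
aggressively. The procedure is fully deterministic. A static fallback
(constant-height cut + size filter) is available via `tree_cut="height"`;
it recovers the same planted modules but keeps some dendrogram fringe,
since it has no gap trimming.

Module eigengenes are the first right singular vector over samples of the
row-standardised module matrix (unit norm, sign oriented to nonnegative
mean member correlation); constant genes are dropped from the PC with a
warning. kME is the gene-eigengene Pearson correlation; hubs require
kME > 0.75 (strict) to the gene's own module.

## Module preservation

Observed statistics per module — density, computed in the test data:
mean intra-module |cor|, mean intra-module adjacency, eigengene proportion
of variance explained; connectivity, agreement between reference and test:
correlation of intramodular connectivity (kIM), of kME, and of the
vectorised intra-module correlation matrices. The null recomputes all six
on random gene sets of the same size; Z = (obs − mean_null)/sd_null per
statistic; Z_density and Z_connectivity are medians of their groups;
Z_summary is their mean. Classes: > 10 strong, 2–10 moderate, ≤ 2 not
preserved; boundary values resolve downward (2 → not preserved,
10 → moderate). Statistics with degenerate null spread (e.g. every
connectivity statistic when test ≡ reference, where all null draws score
exactly 1) are dropped from their median with a warning; a composite whose
statistics were all dropped does not enter Z_summary. medianRank ranks
modules per observed statistic (1 = most preserved, average ranks on ties)
and takes the per-module median — a size-insensitive companion to the Zs.

Null gene sets are drawn from **all** genes of the intersection by default
(the label-permutation null). Restricting draws to assigned genes is
available, but when most assigned genes belong to strong modules the null
draws are module mixtures that are themselves highly coherent, which biases
connectivity Zs downward by about 3 units; the all-genes default avoids
that distortion. Permutations are shared across modules of equal size.

Calibration: each individual statistic's Z is well calibrated on random
gene sets (mean ≈ 0, sd within 0.92–1.07 over 200 replicates). The
composite Z_summary also centres at 0, but its spread is ≈ 0.53, not 1:
the median of three weakly correlated unit-normal Zs has sd ≈ 0.67–0.8, and
averaging two such medians shrinks further. Z_summary is therefore a
conservative score relative to a nominal N(0, 1) reading of its thresholds;
the 2/10 thresholds are conventions of the preservation literature, not
quantiles of the composite's null.

## Synthetic-data generators

The generators define the validation conditions; their defaults are the
study design the package emulates.

* **Brain cohort** (`gen_brain_cohort`): 29 cases + 30 controls, 300 genes.
  Module genes follow a single-factor model x = a·f + √(1−a²)·ε with equal
  loadings within a module (a = 0.9 default, giving within-module
  correlation a² = 0.81 at unit noise); non-preserved modules replace the
  shared factor with independent per-gene factors in case samples,
  destroying connectivity without shifting means. pH is N(6.5, 0.25) with
  cases shifted −0.2 (the reported direction of the case/control pH
  difference); a configurable fraction of genes (20% default) receives a
  pH slope (2.5 log2-units per pH unit by default, chosen so the
  permutation scan has power ≈ 1 at the cohort size). Optional mean-shift
  DEGs are available for end-to-end runs.
* **Two-channel arrays** (`gen_two_channel`): A ~ Uniform(6, 16),
  M = μ_g + ε(A) with σ(A) = 0.1 + 2/A (the MA-plot funnel); DEG
  magnitudes uniform on (0.5, 6.8) by default, matching the reported
  effect-size range; probes 97% reliable.
* **Methylation panels** (`gen_methylation`): background CpGs stay within
  one β category everywhere; planted CpGs flip hyper↔hypo between hiPSC
  and NPC in one subject only.
* **Stage panel** (`gen_stage_panel`): 184 genes over 16 foetal + 22
  non-foetal samples, 73 genes (40%) planted at 4-fold stage differences
  with ±10% multiplicative noise.

No generator models probe sequences, scanner artifacts, batch structure,
heavy-tailed noise, or correlated confounders beyond the single pH
covariate. Passing the planted-structure tests therefore demonstrates that
the algorithms recover the structure they are defined to detect under
clean factor-model conditions — not that real cohorts, with their weaker
and messier signals, would yield the same certainty.

## Numerical choices and problem sizes

Pearson correlation throughout (configurable at the statistic level);
constant rows are removed before correlation with a warning. Pairwise
guards keep adjacency in [0, 1] even for degenerate inputs. All
permutation p-values use the plus-one convention. Every pipeline run draws
its randomness from one root seed split per stage
(`numpy.random.SeedSequence.spawn`), and emits its configuration as JSON,
so re-runs are byte-identical.

Validation runs use cohorts of 140–300 genes and 59 samples, 10⁵ probes
for envelope calibration, 1000 permutations for preservation contrasts,
and 200 replicates × 100 permutations for null-Z calibration — sizes at
which every planted contrast is decisively resolved while the full suite
completes in about a minute.

## Known limitations

* The adaptive tree cut follows the dynamic-hybrid *design* (adaptive
  height, core/gap candidacy, PAM rescue) but is an independent
  implementation; on dendrograms with gradual, gap-free fringe its
  fringe/core boundary can differ from other implementations.
* Preservation's Z_summary spread is below 1 under the null (see above);
  comparisons should lean on the planted contrasts and medianRank, not on
  a literal N(0,1) reading.
* The two-channel model assumes background correction and within-array
  replicate averaging happened upstream; dye-swap designs are out of scope.
* Blockwise network construction for very large gene sets (> 20,000) is
  not implemented; matrices are dense.
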