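# Methods

## Overview

`csnets` constructs cell-line-specific transcription-factor (TF) → gene
regulatory networks in two stages and then refines them jointly across cell
lines:

1. **Preliminary networks.** Probability-scored predicted binding sites (for
   example from DNase-seq footprint models) are mapped into promoter windows.
   A promoter window is TSS ± 2 kb, one window per annotated transcript TSS.
   A site is assigned to a gene when it overlaps any of the gene's windows by
   at least one base. When several sites of one TF land in one gene's
   promoter in one cell line, the edge keeps the **maximum** probability: the
   chance of at least one binding event is dominated by the strongest site
   and the value stays in [0, 1]. The result per cell line is a set of edges
   (TF, gene) with existence probabilities P(1, i).

2. **Cross-cell-line refinement.** Each (TF, gene) pair defines a pairwise
   binary Markov random field (MRF) over the cell lines: x_i = 1 means the
   edge exists in cell line i. Refinement smooths the per-cell-line
   probabilities across similar cell lines, raising weakly supported edges in
   cell lines whose neighbours strongly support them and vice versa.

## The Markov random field

### Potentials

For cell line i with preliminary probability P(1, i) (and P(0, i) = 1 −
P(1, i)), the node potential is

    φ_i(x_i) = P(1,i)/P(0,i)  if P(1,i) > P(0,i) and x_i = 1
             = P(0,i)/P(1,i)  if P(0,i) > P(1,i) and x_i = 0
             = 1              otherwise

i.e. a node is rewarded for taking its locally preferred label, in proportion
to the odds in its favour. For coupled cell lines i, j with coupling weight
w_ij, the edge potential is

    ψ_ij(x_i, x_j) = exp(w_ij)  if x_i = x_j
                   = 1          otherwise

The pseudo-energy of a labeling X is E(X) = −γ − Σ_i ln φ_i − Σ_ij ln ψ_ij
with γ = 0 (γ only shifts the energy uniformly and never changes the MAP
labeling or marginals; it is kept as an explicit instance attribute).

### Coupling weights

Cell lines i and j are coupled when w_ij = (CSI_ij + TNI_ij)/2 exceeds a
threshold c (default **0.5**); the same w_ij is the edge potential's weight.

- **CSI (cell-line similarity index).** The expression matrix is restricted
  to differentially expressed genes if a list is supplied, otherwise to the
  592 highest-variance genes. Each gene row is z-scored (mean 0, population
  SD 1; constant rows are dropped with a warning). The matrix is decomposed
  by SVD, and cell line j is represented by its coordinates in the leading
  `n_dims` singular dimensions, scaled by the singular values (s_k · v_kj).
  CSI_ij is the Pearson correlation of the two coordinate vectors. Each
  right singular vector's sign is fixed so that its largest-magnitude entry
  is positive; the SVD's sign is otherwise arbitrary and changes with the
  gene row order, and the CSI is not sign-invariant.
- **TNI (TF non-specificity index).** Per TF, the Jaccard index
  |T_i ∩ T_j| / |T_i ∪ T_j| of the TF's preliminary target sets in the two
  cell lines (a minimum-denominator variant is available behind a flag). Two
  empty target sets give 0.

The default `n_dims` for general use is 16. The synthetic recovery
experiment defaults to **4**: the truncation must discard the
noise-dominated trailing dimensions to do its denoising job — at full rank
(`n_dims` = number of cell lines) the CSI degenerates to the plain
correlation of the z-scored columns — while 2 dimensions are degenerate for
a correlation of coordinate vectors (the Pearson correlation of two
2-vectors is ±1).

### Inference

Three inference routes are implemented; all operate per (TF, gene) pair over
the cell lines:

- **Exact MAP by s–t min-cut.** With c ≥ 0 every edge satisfies the
  submodularity condition β(1,1) + β(0,0) = 2w ≥ 0 = β(1,0) + β(0,1) on the
  pairwise log-potentials (asserted at instance construction), so the energy
  is exactly minimizable by a minimum s–t cut. The standard reduction is
  used: each pairwise term contributes an arc i→j of capacity 2w plus unary
  adjustments, and unary differences become arcs from the source or to the
  sink. The cut is computed with `networkx.minimum_cut`.
- **Loopy belief propagation (LBP)** for approximate marginals Pr(x_i = 1):
  synchronous (flooding) sum-product updates with damping 0.5, convergence
  tolerance 1e−6, at most 200 iterations by default. On tree-structured
  fields the beliefs equal the exact marginals; isolated nodes take the
  closed form Pr(x_i = 1) = P(1, i) exactly.
- **ICM (iterated conditional modes)**: strict-descent single-site flips from
  a nodewise-argmax initialization; a fast greedy baseline.

A brute-force oracle (exhaustive enumeration, n ≤ 20, exact marginals via
log-sum-exp) backs the test suite.

`refine_networks` builds one MRF per (TF, gene) pair in the union of
preliminary edges, over **all** cell lines; cell lines without an observed
site for the pair enter with P(1, i) = ε (a flag restricts the field to
observed cell lines instead). The refined probability is the LBP belief (or
the 0/1 MAP label for the `mincut`/`icm` methods), and an edge is called
when it exceeds the call threshold (default 0.5).

### Numerical choices

- Probabilities are clamped to [ε, 1−ε] with ε = 1e−6 before any ratio or
  logarithm is formed, so potentials stay finite.
- Energies and exact marginals are computed in log space (log-sum-exp).
- The exact one-sided binomial test sums the upper tail in log space via
  `gammaln`, accurate to at least 1e−12 relative error against an exact
  rational-arithmetic oracle for n ≤ 30 and still correct far below the
  double-precision reporting bound 2.2e−16.

## Evaluation against ChIP-seq-style gold standards

For one (TF, cell line) experiment, peaks are mapped into promoter windows
and each candidate target gene is scored by its best overlapping peak. The
candidates are ranked (score descending, gene id ascending for ties) and
truncated at M, the **median of three set sizes**: the ChIP candidate set,
the refined network's target set, and the preliminary network's target set.
Networks are scored by:

- **ROC AUC** with positives = the gold-standard targets and negatives = all
  other promoter-bearing genes; genes the network does not score count as
  score 0. The AUC is computed with midranks, equivalent to pairwise
  concordance counting with ties at ½.
- **Overlap score**: the size of the intersection of the network's top-M
  targets with the gold standard.

The relative change (new − old)/old compares refined to preliminary values
(undefined and excluded when old = 0). `improvement_summary` reports the
count of positive changes, the percentage, and a one-sided exact binomial
p-value against chance (p₀ = 0.5).

## Downstream analyses

- Tissue networks: edge union over member cell lines with per-edge support
  counts; degree summaries.
- Network comparison: Jaccard coefficient of edge sets; per-TF Jaccard
  distance of target sets; differential networks as symmetric differences of
  called edge sets, with genes ranked by differential in-degree.
- Clustering: average-linkage (UPGMA) on a distance matrix, emitted as a
  Newick string. Branch lengths follow the ultrametric convention (a node
  at merge height h sits at depth h/2), so the path length between two
  leaves equals their cophenetic distance.
- Functional enrichment: one-sided Fisher exact tests of TF targets against
  gene sets with Benjamini–Hochberg control; the "enrichment score" is the
  proportion of significant tests.
- Rank-set enrichment (GSEA-style): genes ranked by descending score; the
  running sum gains |score|/Σ|score over hits| at target genes, loses
  1/(N − n_targets) elsewhere; ES is the maximum of the running sum
  evaluated only at boundaries between distinct score values (the order
  within a tied block is arbitrary, so the statistic must not depend on it;
  with all scores equal, ES = 0). The p-value is the add-one fraction of
  gene-label permutations with ES ≥ observed.

## Synthetic data generator

The generator (`csnets.simulate`) emulates the structure the model assumes,
with everything a deterministic function of the configuration including the
seed:

- Cell lines are assigned to tissues round-robin. True networks are a
  global core edge set ∪ tissue-shared edges ∪ per-cell-line private edges
  (fractions of all TF×gene pairs: 0.05 / 0.05 / 0.01 by default).
- Expression = tissue-level gene programs N(0, 1) plus per-cell-line noise
  N(0, noise_sd²) (default 0.5), so within-tissue cell lines are more
  similar than between-tissue ones.
- Observed binding probabilities: true edges draw from Beta(0.8a, 0.2a) and
  false candidate ("decoy") pairs from Beta(0.2a, 0.8a), with concentration
  a = 5 by default (larger = cleaner). Each cell line also receives 50
  decoy sites so preliminary networks differ between cell lines and the TNI
  is informative.
- ChIP-like peaks sit in the promoters of true targets with scores
  increasing in a per-edge strength.
- **Null condition** (`null_binding=True`): the candidate pairs receiving
  sites are drawn uniformly at random per cell line (same counts as the
  signal condition) and every probability is Uniform(0, 1), so the binding
  observations carry no information about the truth. A "pure noise via a
  small beta concentration" design was rejected: Beta(0.8a, 0.2a) retains a
  mean of 0.8 for any a > 0, so lowering a degrades but never removes the
  signal, which is not a null.

`recovery_experiment` runs the full pipeline on synthetic data and reports
per-(TF, cell line) AUCs of preliminary and refined scores against the true
target sets, and the fraction of evaluations improved. Exact AUC ties count
as half an improvement, the standard paired-comparison (sign-test)
convention; this makes identity refinement (coupling threshold c = 1, no
couplings) score exactly 0.5 and keeps the null condition centred at 0.5
rather than biased downward by ties.

### Generator scope and limitations

The generator is artifact plumbing at desk scale, not a biological
simulation: genome coordinates are a single synthetic chromosome with evenly
spaced genes on the + strand, there is no motif content or read-level
simulation, and expression programs are Gaussian. Conclusions supported by
the synthetic experiments are about the *pipeline's* behaviour (the
refinement helps when the model's assumptions hold and does no systematic
harm under a null), not about any real cell line.

## Parameter defaults

| Parameter | Default | Rationale |
|---|---|---|
| promoter half-width | 2000 bp | TSS ± 2 kb window |
| ε probability clamp | 1e−6 | keeps odds ratios finite |
| coupling threshold c | 0.5 | couple only clearly similar cell lines; guarantees submodularity (c ≥ 0) |
| call threshold | 0.5 | posterior majority |
| CSI dimensions | 16 (pipeline), 4 (synthetic recovery) | see CSI section |
| fallback DE genes | 592 | variance-ranked substitute when no DE list is given |
| LBP damping / tol / max iter | 0.5 / 1e−6 / 200 | stable synchronous updates |
| γ | 0 | pure energy offset |

## Limitations

- LBP is exact only on trees; on loopy coupling graphs the beliefs are
  approximations (the min-cut MAP route stays exact for any topology).
- The MRF treats each (TF, gene) pair independently; there is no sharing of
  information across genes beyond the coupling weights.
- Evaluation treats ChIP-derived top-M targets as ground truth; M and the
  tie-breaking rule (score descending, gene id ascending) are conventions,
  and negatives are simply all other promoter-bearing genes.
- The published per-count binomial p-values for the original networks are
  not all reproducible from the printed counts with a textbook one-sided
  exact binomial test; only the "< 2.2e−16" significance bound and the
  printed percentages are treated as recomputable quantities.
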