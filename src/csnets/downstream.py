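"""Downstream analyses: tissue networks, taxonomy, enrichment, differential regulation.

Tissue-level networks are edge unions over member cell lines.  Network
similarity uses the Jaccard coefficient of edge sets; cell lines / tissues
are clustered by average linkage (UPGMA) on 1 − similarity.  Functional
coherence of a TF with its targets uses one-sided Fisher exact tests per GO
term with Benjamini–Hochberg control, summarized as the proportion of
significant tests (the "enrichment score").  Disease TF prioritisation uses
a GSEA-style weighted Kolmogorov–Smirnov running sum over a gene ranking
with a gene-label permutation p-value.  Condition comparisons (e.g. treated
vs untreated cells) use per-TF Jaccard distances of target sets and rank
genes by their number of differential incoming edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .preliminary import CellLineNetwork

__all__ = [
    "TissueNetwork",
    "EnrichmentTest",
    "DifferentialNetwork",
    "merge_tissue",
    "degree_summary",
    "network_jaccard",
    "tf_target_jaccard_distance",
    "differential_network",
    "rank_differential_targets",
    "fisher_go_enrichment",
    "enrichment_score",
    "rank_set_enrichment",
    "hclust_average",
]

Edge = tuple[str, str]  # (tf, gene)


@dataclass
class TissueNetwork:
    """Union of member cell-line networks with per-edge support counts."""

    tissue: str
    cell_lines: list[str]
    edges: set[Edge]
    support: dict[Edge, int]


@dataclass
class EnrichmentTest:
    """One Fisher exact test of TF targets against one gene set."""

    tf_id: str
    group: str
    term_id: str
    table: tuple[int, int, int, int]
    odds_ratio: float
    p: float
    fdr_significant: bool = False


@dataclass
class DifferentialNetwork:
    """Edges present in exactly one of two conditions."""

    condition_a: str
    condition_b: str
    edges: set[Edge]
    per_tf_counts: dict[str, int] = field(default_factory=dict)
    per_gene_counts: dict[str, int] = field(default_factory=dict)


def _called_edges(net: CellLineNetwork) -> set[Edge]:
    return {(e.tf_id, e.gene_id) for e in net.edges}


def merge_tissue(
    networks: list[CellLineNetwork], tissue: str = ""
) -> TissueNetwork:
    """Merge cell-line networks of one tissue: edge union with support counts."""
    if not networks:
        raise ValueError("need at least one network to merge")
    support: dict[Edge, int] = {}
    for net in networks:
        for e in _called_edges(net):
            support[e] = support.get(e, 0) + 1
    return TissueNetwork(
        tissue=tissue,
        cell_lines=[n.cell_line for n in networks],
        edges=set(support),
        support=support,
    )


def degree_summary(net: TissueNetwork) -> tuple[int, int, float, float]:
    """(n nodes, n edges, mean in-degree, mean out-degree).

    Mean in-degree = edges per distinct target gene; mean out-degree = edges
    per distinct TF; nodes = TFs ∪ targets.
    """
    if not net.edges:
        raise ValueError("empty network")
    tfs = {tf for tf, _ in net.edges}
    targets = {g for _, g in net.edges}
    n_edges = len(net.edges)
    return (
        len(tfs | targets),
        n_edges,
        n_edges / len(targets),
        n_edges / len(tfs),
    )


def network_jaccard(e1: set[Edge], e2: set[Edge]) -> float:
    """Jaccard coefficient of two edge sets; 0 when both are empty."""
    union = e1 | e2
    if not union:
        return 0.0
    return len(e1 & e2) / len(union)


def tf_target_jaccard_distance(
    targets_a: set[str], targets_b: set[str]
) -> tuple[float, int]:
    """(1 − Jaccard, |symmetric difference|) of one TF's target sets.

    Undefined (raises) when both sets are empty.
    """
    union = targets_a | targets_b
    if not union:
        raise ValueError("Jaccard distance undefined for two empty target sets")
    jaccard = len(targets_a & targets_b) / len(union)
    return 1.0 - jaccard, len(targets_a ^ targets_b)


def differential_network(
    net_a: CellLineNetwork, net_b: CellLineNetwork
) -> DifferentialNetwork:
    """Symmetric difference of called edges between two conditions."""
    ea, eb = _called_edges(net_a), _called_edges(net_b)
    diff = ea ^ eb
    per_tf: dict[str, int] = {}
    per_gene: dict[str, int] = {}
    for tf, gene in diff:
        per_tf[tf] = per_tf.get(tf, 0) + 1
        per_gene[gene] = per_gene.get(gene, 0) + 1
    return DifferentialNetwork(
        condition_a=net_a.cell_line,
        condition_b=net_b.cell_line,
        edges=diff,
        per_tf_counts=per_tf,
        per_gene_counts=per_gene,
    )


def rank_differential_targets(diff: DifferentialNetwork) -> list[tuple[str, int]]:
    """Genes by number of differential incoming edges, descending; ties by id."""
    return sorted(diff.per_gene_counts.items(), key=lambda kv: (-kv[1], kv[0]))


def fisher_go_enrichment(
    targets: set[str],
    term_genes: set[str],
    universe: set[str],
    tf_id: str = "",
    group: str = "",
    term_id: str = "",
) -> EnrichmentTest:
    """One-sided (enrichment) Fisher exact test of targets × gene-set membership."""
    if not universe:
        raise ValueError("empty gene universe")
    targets = targets & universe
    term = term_genes & universe
    a = len(targets & term)
    b = len(targets - term)
    c = len(term - targets)
    d = len(universe) - a - b - c
    odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentTest(
        tf_id=tf_id,
        group=group,
        term_id=term_id,
        table=(a, b, c, d),
        odds_ratio=float(odds),
        p=float(p),
    )


def enrichment_score(tests: list[EnrichmentTest], fdr: float = 0.2) -> float:
    """Proportion of Benjamini–Hochberg-significant tests at the given FDR.

    Flags each test's ``fdr_significant`` in place and returns
    (#significant)/(#tests).
    """
    if not tests:
        raise ValueError("no enrichment tests to summarize")
    pvals = np.array([t.p for t in tests])
    reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    for t, r in zip(tests, reject):
        t.fdr_significant = bool(r)
    return float(reject.sum() / len(tests))


def rank_set_enrichment(
    gene_scores: dict[str, float],
    target_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """GSEA-style enrichment of a target set in a scored gene ranking.

    Genes are ranked by descending score; the running sum gains |score| /
    Σ|score over hits| at target genes and loses 1/(N − n_targets) elsewhere.
    ES = the maximum of the running sum, evaluated only at the boundaries of
    tied-score blocks (the order within a tie block is arbitrary, so the
    statistic must not depend on it; with all scores equal the ES is 0);
    p = add-one fraction of gene-label permutations with ES ≥ observed.
    """
    if not target_set:
        raise ValueError("empty target set")
    missing = target_set - set(gene_scores)
    if missing:
        raise ValueError(f"target genes without scores: {sorted(missing)[:5]}")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    genes = sorted(gene_scores, key=lambda g: (-gene_scores[g], g))
    weights = np.abs(np.array([gene_scores[g] for g in genes]))
    hits = np.array([g in target_set for g in genes])
    ordered_scores = np.array([gene_scores[g] for g in genes])
    # running sum is read only where the score strictly drops (tie-block ends)
    block_end = np.append(ordered_scores[:-1] != ordered_scores[1:], True)

    def es(hit_mask: np.ndarray) -> float:
        hit_w = weights * hit_mask
        total = hit_w.sum()
        if total == 0:  # all-zero scores: flat running sum
            gain = hit_mask / max(hit_mask.sum(), 1)
        else:
            gain = hit_w / total
        n_miss = len(genes) - int(hit_mask.sum())
        loss = (~hit_mask.astype(bool)).astype(float) / max(n_miss, 1)
        running = np.cumsum(gain - loss)
        return float(running[block_end].max())

    observed = es(hits)
    rng = np.random.default_rng(seed)
    k = int(hits.sum())
    count = 0
    for _ in range(n_perm):
        perm = np.zeros(len(genes), dtype=bool)
        perm[rng.choice(len(genes), size=k, replace=False)] = True
        if es(perm) >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return observed, p


def hclust_average(dist: np.ndarray, labels: list[str]) -> str:
    """Average-linkage (UPGMA) dendrogram of a distance matrix, as Newick.

    The matrix must be symmetric with a zero diagonal.  Branch lengths follow
    the ultrametric convention: a node at merge height h sits at depth h/2, so
    the path length between two leaves equals their cophenetic distance.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] != dist.shape[1] or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(dist), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if len(labels) != dist.shape[0]:
        raise ValueError("label count does not match matrix size")
    condensed = squareform(dist, checks=False)
    tree = to_tree(linkage(condensed, method="average"))

    def newick(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.get_left(), node.get_right()
        return (
            f"({newick(left)}:{(node.dist - left.dist) / 2:.6g},"
            f"{newick(right)}:{(node.dist - right.dist) / 2:.6g})"
        )

    return newick(tree) + ";"
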