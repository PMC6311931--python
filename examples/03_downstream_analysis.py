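"""Downstream analyses on refined networks.

Merges cell-line networks into tissue networks, compares networks by Jaccard
similarity, clusters cell lines by network distance (UPGMA), and tests a
TF's targets for gene-set enrichment with Fisher's exact test under
Benjamini-Hochberg control.
"""

import numpy as np

from csnets.downstream import (
    degree_summary,
    enrichment_score,
    fisher_go_enrichment,
    hclust_average,
    merge_tissue,
    network_jaccard,
    rank_set_enrichment,
)
from csnets.preliminary import CellLineNetwork, RegulatoryEdge


def net(cell_line, pairs):
    return CellLineNetwork.from_edges(
        cell_line,
        {RegulatoryEdge(tf_id=tf, gene_id=g, cell_line=cell_line, probability=0.9)
         for tf, g in pairs},
    )


# two liver-like and two blood-like cell lines sharing a core program
core = {("TF1", f"g{i}") for i in range(6)}
liver = {("TF2", f"g{i}") for i in range(6, 12)}
blood = {("TF3", f"g{i}") for i in range(12, 18)}
nets = {
    "hepg2": net("hepg2", core | liver),
    "huh7": net("huh7", core | liver | {("TF2", "g20")}),
    "k562": net("k562", core | blood),
    "gm12878": net("gm12878", core | blood | {("TF3", "g21")}),
}

merged = merge_tissue([nets["hepg2"], nets["huh7"]], tissue="liver")
n_nodes, n_edges, mean_in, mean_out = degree_summary(merged)
print(f"liver network: {n_nodes} nodes, {n_edges} edges, "
      f"mean in-degree {mean_in:.2f}, mean out-degree {mean_out:.2f}")

# pairwise network similarity and UPGMA clustering on 1 - Jaccard
names = sorted(nets)
edge_sets = {cl: {(e.tf_id, e.gene_id) for e in nets[cl].edges} for cl in names}
dist = np.zeros((4, 4))
for i, a in enumerate(names):
    for j, b in enumerate(names):
        dist[i, j] = 1.0 - network_jaccard(edge_sets[a], edge_sets[b])
print("\nUPGMA on network Jaccard distance:")
print(" ", hclust_average(dist, names))

# enrichment of TF2's targets in a liver gene set
universe = {f"g{i}" for i in range(30)}
liver_set = {f"g{i}" for i in range(6, 14)}
test = fisher_go_enrichment(
    targets={g for tf, g in liver if tf == "TF2"},
    term_genes=liver_set, universe=universe,
    tf_id="TF2", term_id="LIVER_PROGRAM",
)
score = enrichment_score([test], fdr=0.2)
print(f"\nTF2 targets vs LIVER_PROGRAM: table={test.table}, p={test.p:.2e}, "
      f"enrichment score {score:.2f}")

# GSEA-style test: are TF2 targets concentrated at the top of a ranking?
rng = np.random.default_rng(0)
scores = {g: float(rng.normal()) for g in universe}
for g in list(liver_set)[:6]:
    scores[g] += 3.0  # push the program genes to the top
es, p = rank_set_enrichment(scores, liver_set, n_perm=1000, seed=0)
print(f"rank-set enrichment of LIVER_PROGRAM: ES={es:.3f}, p={p:.4f}")
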