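"""Preliminary per-cell-line TF→gene networks from promoter-mapped binding sites.

Predicted binding sites (with binding probabilities) are assigned to genes
whose promoter window — TSS ± ``halfwidth`` bp, one window per transcript TSS
— they overlap by at least one base.  When several sites of the same TF fall
in a gene's promoter in one cell line, the edge keeps the maximum
probability: the chance of at least one binding event is dominated by the
strongest site and stays in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .io import BindingSiteRecord, GeneModel

__all__ = [
    "PromoterWindow",
    "RegulatoryEdge",
    "CellLineNetwork",
    "promoter_windows",
    "assign_sites_to_promoters",
    "build_preliminary_networks",
    "EPSILON",
]

#: Floor/ceiling for binding probabilities before any ratio is formed.
EPSILON = 1e-6


def clamp_probability(p: float, eps: float = EPSILON) -> float:
    """Clamp a probability to [eps, 1−eps] so P1/P0 ratios stay finite."""
    return min(max(p, eps), 1.0 - eps)


@dataclass(frozen=True)
class PromoterWindow:
    """Promoter interval around one transcript TSS (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    source_tss: int


@dataclass(frozen=True)
class RegulatoryEdge:
    """One TF→gene edge in one cell line with existence probability P(1,i)."""

    tf_id: str
    gene_id: str
    cell_line: str
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"edge probability {self.probability} outside [0, 1]")


@dataclass
class CellLineNetwork:
    """All called/observed regulatory edges of one cell line."""

    cell_line: str
    edges: set[RegulatoryEdge] = field(default_factory=set)
    tf_targets: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_edges(cls, cell_line: str, edges: set[RegulatoryEdge]) -> "CellLineNetwork":
        tf_targets: dict[str, set[str]] = {}
        for e in edges:
            tf_targets.setdefault(e.tf_id, set()).add(e.gene_id)
        return cls(cell_line=cell_line, edges=edges, tf_targets=tf_targets)

    def edge_probabilities(self) -> dict[tuple[str, str], float]:
        return {(e.tf_id, e.gene_id): e.probability for e in self.edges}

    def __len__(self) -> int:
        return len(self.edges)


def promoter_windows(
    genes: list[GeneModel], halfwidth: int = 2000
) -> list[PromoterWindow]:
    """One promoter window per transcript TSS, clipped at chromosome start."""
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    windows = []
    for g in genes:
        for tss in g.transcript_tss_list:
            windows.append(
                PromoterWindow(
                    gene_id=g.gene_id,
                    chrom=g.chrom,
                    start=max(0, tss - halfwidth),
                    end=tss + halfwidth,
                    source_tss=tss,
                )
            )
    return windows


def _window_trees(windows: list[PromoterWindow]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end, w.gene_id)
    return trees


def assign_sites_to_promoters(
    sites: list[BindingSiteRecord], windows: list[PromoterWindow]
) -> list[RegulatoryEdge]:
    """Assign sites to promoter windows (≥1 bp overlap); max probability per edge.

    Output is sorted by (tf, gene, cell line), so it is independent of input
    ordering.
    """
    trees = _window_trees(windows)
    best: dict[tuple[str, str, str], float] = {}
    for s in sites:
        tree = trees.get(s.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(s.start, s.end):
            key = (s.tf_id, hit.data, s.cell_line)
            if s.probability > best.get(key, -1.0):
                best[key] = s.probability
    return [
        RegulatoryEdge(tf_id=tf, gene_id=gene, cell_line=cl, probability=p)
        for (tf, gene, cl), p in sorted(best.items())
    ]


def build_preliminary_networks(
    sites_by_cell_line: dict[str, list[BindingSiteRecord]],
    genes: list[GeneModel],
    halfwidth: int = 2000,
) -> dict[str, CellLineNetwork]:
    """Build one preliminary network per cell line from its binding sites."""
    if not sites_by_cell_line:
        raise ValueError("need at least one cell line")
    windows = promoter_windows(genes, halfwidth=halfwidth)
    networks: dict[str, CellLineNetwork] = {}
    for cell_line in sorted(sites_by_cell_line):
        sites = sites_by_cell_line[cell_line]
        edges = set(assign_sites_to_promoters(sites, windows))
        if not edges:
            warnings.warn(f"cell line {cell_line!r}: no sites in any promoter")
        networks[cell_line] = CellLineNetwork.from_edges(cell_line, edges)
    return networks
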