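"""ChIP-seq-based gold standards and network-improvement statistics.

A gold standard for (TF, cell line) is built by mapping the experiment's
peaks into promoter windows, scoring each candidate target gene by its best
overlapping peak, and truncating the score-ranked candidates at M — the
median of three set sizes: the ChIP candidates, the refined network's
targets, and the preliminary network's targets.  Networks are then scored by
ROC AUC (positives = gold-standard targets, negatives = the remaining
promoter-bearing genes) and by the overlap of their top-M targets with the
gold standard; the relative change (new − old)/old of each criterion
quantifies the refinement's contribution, and one-sided exact binomial tests
ask whether improvements outnumber regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata

from .io import GeneModel, PeakRecord
from .preliminary import promoter_windows, _window_trees

__all__ = [
    "GoldStandard",
    "EvaluationRecord",
    "build_gold_standard",
    "roc_auc",
    "overlap_score",
    "relative_change",
    "binomial_test_one_sided",
    "evaluate_pair",
    "aggregate_tf_level",
    "improvement_summary",
]


@dataclass
class GoldStandard:
    """Top-M ChIP-derived target genes for one (TF, cell line)."""

    tf_id: str
    cell_line: str
    M: int
    positives: set[str]
    candidate_scores: dict[str, float]


@dataclass
class EvaluationRecord:
    """Preliminary-vs-refined comparison for one (TF, cell line)."""

    tf_id: str
    cell_line: str
    auc_prelim: float
    auc_mrf: float
    overlap_prelim: int
    overlap_mrf: int
    rel_change_auc: float | None
    rel_change_overlap: float | None


def rank_genes(scores: dict[str, float]) -> list[str]:
    """Genes by descending score, ties broken by gene id ascending."""
    return [g for g, _ in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))]


def build_gold_standard(
    peaks: list[PeakRecord],
    genes: list[GeneModel],
    mrf_targets: set[str],
    prelim_targets: set[str],
    tf_id: str = "",
    cell_line: str = "",
    halfwidth: int = 2000,
) -> GoldStandard:
    """Gold standard from ChIP peaks mapped to promoter windows.

    Candidate gene score = max score over overlapping peaks; M = median of
    {#candidates, #refined targets, #preliminary targets}; positives = the
    top-M candidates.
    """
    windows = promoter_windows(genes, halfwidth=halfwidth)
    trees = _window_trees(windows)
    scores: dict[str, float] = {}
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(p.start, p.end):
            gene = hit.data
            if p.score > scores.get(gene, -np.inf):
                scores[gene] = p.score
    if not scores:
        raise ValueError("no ChIP peaks overlap any promoter window")
    sizes = sorted([len(scores), len(mrf_targets), len(prelim_targets)])
    m = sizes[1]  # median of three
    positives = set(rank_genes(scores)[:m])
    return GoldStandard(
        tf_id=tf_id, cell_line=cell_line, M=m, positives=positives, candidate_scores=scores
    )


def roc_auc(scores: dict[str, float], positives: set[str], universe: set[str]) -> float:
    """AUC via the rank (Mann–Whitney) statistic with midrank tie handling.

    Genes in the universe without a score get 0; negatives are all universe
    genes outside the positive set.
    """
    pos = positives & universe
    neg = universe - positives
    if not pos or not neg:
        raise ValueError("ROC needs at least one positive and one negative")
    genes = sorted(universe)
    values = np.array([scores.get(g, 0.0) for g in genes])
    is_pos = np.array([g in pos for g in genes])
    ranks = rankdata(values)  # midranks
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    rank_sum = ranks[is_pos].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def overlap_score(network_targets_top_m: set[str], gold: GoldStandard) -> int:
    """Number of genes shared between top-M network targets and the gold standard."""
    return len(network_targets_top_m & gold.positives)


def relative_change(new: float, old: float) -> float | None:
    """(new − old)/old; None when old = 0 (record flagged, excluded from counts)."""
    if old == 0:
        return None
    return (new - old) / old


def binomial_test_one_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact upper-tail P(X ≥ k) for X ~ Binomial(n, p0), summed in log space."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"invalid counts k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    if k == 0:
        return 1.0
    i = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * np.log(p0)
        + (n - i) * np.log1p(-p0)
    )
    return float(np.exp(logsumexp(log_terms)))


def evaluate_pair(
    gold: GoldStandard,
    prelim_scores: dict[str, float],
    mrf_scores: dict[str, float],
    universe: set[str],
) -> EvaluationRecord:
    """AUC and top-M overlap of preliminary vs refined scores for one pair."""
    auc_p = roc_auc(prelim_scores, gold.positives, universe)
    auc_m = roc_auc(mrf_scores, gold.positives, universe)
    top_p = set(rank_genes(prelim_scores)[: gold.M])
    top_m = set(rank_genes(mrf_scores)[: gold.M])
    ov_p = overlap_score(top_p, gold)
    ov_m = overlap_score(top_m, gold)
    return EvaluationRecord(
        tf_id=gold.tf_id,
        cell_line=gold.cell_line,
        auc_prelim=auc_p,
        auc_mrf=auc_m,
        overlap_prelim=ov_p,
        overlap_mrf=ov_m,
        rel_change_auc=relative_change(auc_m, auc_p),
        rel_change_overlap=relative_change(ov_m, ov_p),
    )


def aggregate_tf_level(
    records: list[EvaluationRecord],
) -> dict[str, dict[str, float | None]]:
    """Average each relative-change criterion per TF across its cell lines."""
    by_tf: dict[str, list[EvaluationRecord]] = {}
    for r in records:
        by_tf.setdefault(r.tf_id, []).append(r)
    out: dict[str, dict[str, float | None]] = {}
    for tf, recs in by_tf.items():
        aucs = [r.rel_change_auc for r in recs if r.rel_change_auc is not None]
        ovs = [r.rel_change_overlap for r in recs if r.rel_change_overlap is not None]
        out[tf] = {
            "rel_change_auc": float(np.mean(aucs)) if aucs else None,
            "rel_change_overlap": float(np.mean(ovs)) if ovs else None,
        }
    return out


def improvement_summary(
    rel_changes: list[float | None],
) -> tuple[int, int, float, float]:
    """Count improvements among relative changes.

    Returns (k improved, n comparable, percent improved, one-sided binomial p
    against chance 0.5).  Undefined relative changes (old score 0) are
    excluded.
    """
    valid = [rc for rc in rel_changes if rc is not None]
    n = len(valid)
    if n == 0:
        raise ValueError("no comparable records")
    k = sum(1 for rc in valid if rc > 0)
    percent = 100.0 * k / n
    return k, n, percent, binomial_test_one_sided(k, n, 0.5)
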