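"""Seeded synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the structure the refinement model assumes: cell
lines group into tissues; each cell line's true regulatory network is a
global core edge set, plus edges shared by its tissue, plus a few private
edges; expression follows tissue-level gene programs with Gaussian noise, so
within-tissue cell lines are more similar than between-tissue ones.
Observed binding probabilities are beta-noised versions of the truth — true
edges draw from Beta(0.8·a, 0.2·a) and false candidate ("decoy") edges from
Beta(0.2·a, 0.8·a), where a is a concentration controlling signal-to-noise —
and ChIP-like peaks sit in the promoters of true targets with scores
increasing in a per-edge strength.

A null condition (``null_binding=True``) makes the binding observations pure
noise: the candidate pairs receiving sites are drawn uniformly at random per
cell line (same counts as the signal condition) and every probability is
Uniform(0, 1), so the binding data carry no information about the truth; under
this condition refinement should do no better than the preliminary network
(improvement fraction ≈ 0.5, ties counted as half).

Everything is a deterministic function of the configuration, including the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import roc_auc
from .io import BindingSiteRecord, GeneModel, PeakRecord
from .mrf import MRFInstance, refine_networks
from .preliminary import build_preliminary_networks
from .similarity import CSIConfig, compute_csi

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "simulate_truth",
    "binding_records",
    "gene_models",
    "emit_observations",
    "recovery_experiment",
    "random_mrf_instance",
]

Pair = tuple[str, str]  # (tf, gene)

_GENE_SPACING = 10_000
_GENE_LENGTH = 2_000


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic experiment.

    Defaults give a desk-scale version of the real study: 10 cell lines in 2
    tissues, 5 TFs, 300 genes.  ``core_edge_fraction`` /
    ``tissue_edge_fraction`` / ``private_edge_fraction`` are fractions of all
    TF×gene pairs that are true everywhere / within one tissue / in one cell
    line.  ``binding_beta_concentration`` sets the beta noise on observed
    binding probabilities (larger = cleaner; 5 gives moderate noise).
    ``decoy_sites_per_cell_line`` false pairs also receive binding sites per
    cell line, so preliminary networks differ between cell lines and the TF
    overlap index is informative.
    """

    seed: int
    n_cell_lines: int = 10
    n_tissues: int = 2
    n_tfs: int = 5
    n_genes: int = 300
    core_edge_fraction: float = 0.05
    tissue_edge_fraction: float = 0.05
    private_edge_fraction: float = 0.01
    noise_sd: float = 0.5
    binding_beta_concentration: float = 5.0
    decoy_sites_per_cell_line: int = 50
    null_binding: bool = False

    def __post_init__(self) -> None:
        for name in ("core_edge_fraction", "tissue_edge_fraction", "private_edge_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.n_cell_lines < self.n_tissues or self.n_tissues < 1:
            raise ValueError("need at least one cell line per tissue")
        if self.n_tfs < 1 or self.n_genes < 2:
            raise ValueError("need >= 1 TF and >= 2 genes")


@dataclass
class SyntheticTruth:
    """Ground truth plus the noised observations derived from it."""

    config: GeneratorConfig
    cell_lines: list[str]
    tissues: dict[str, str]
    tf_ids: list[str]
    gene_ids: list[str]
    true_edges: dict[str, set[Pair]]
    expression: pd.DataFrame
    binding_probabilities: dict[str, dict[Pair, float]]
    peak_sets: dict[tuple[str, str], list[PeakRecord]] = field(default_factory=dict)


def _sample_pairs(
    rng: np.random.Generator, pool: list[Pair], count: int
) -> set[Pair]:
    count = min(count, len(pool))
    if count == 0:
        return set()
    idx = rng.choice(len(pool), size=count, replace=False)
    return {pool[i] for i in idx}


def _draw_edge_sets(
    rng: np.random.Generator, cfg: GeneratorConfig, all_pairs: list[Pair],
    cell_lines: list[str], tissues: dict[str, str], tissue_names: list[str],
) -> dict[str, set[Pair]]:
    n_pairs = len(all_pairs)
    core = _sample_pairs(rng, all_pairs, round(cfg.core_edge_fraction * n_pairs))
    non_core = [p for p in all_pairs if p not in core]
    tissue_edges = {
        t: _sample_pairs(rng, non_core, round(cfg.tissue_edge_fraction * n_pairs))
        for t in tissue_names
    }
    true_edges: dict[str, set[Pair]] = {}
    for cl in cell_lines:
        shared = core | tissue_edges[tissues[cl]]
        pool = [p for p in non_core if p not in shared]
        private = _sample_pairs(rng, pool, round(cfg.private_edge_fraction * n_pairs))
        true_edges[cl] = shared | private
    return true_edges


def simulate_truth(cfg: GeneratorConfig) -> SyntheticTruth:
    """Generate ground truth and observations; deterministic in the config."""
    rng = np.random.default_rng(cfg.seed)
    cell_lines = [f"CL{i:02d}" for i in range(cfg.n_cell_lines)]
    tissue_names = [f"T{t}" for t in range(cfg.n_tissues)]
    tissues = {cl: tissue_names[i % cfg.n_tissues] for i, cl in enumerate(cell_lines)}
    tf_ids = [f"TF{t}" for t in range(cfg.n_tfs)]
    gene_ids = [f"G{g:04d}" for g in range(cfg.n_genes)]
    all_pairs: list[Pair] = [(tf, g) for tf in tf_ids for g in gene_ids]

    true_edges = _draw_edge_sets(rng, cfg, all_pairs, cell_lines, tissues, tissue_names)

    # tissue-level gene programs + per-cell-line Gaussian noise
    programs = rng.normal(size=(cfg.n_genes, cfg.n_tissues))
    tissue_idx = {t: i for i, t in enumerate(tissue_names)}
    expr = np.empty((cfg.n_genes, cfg.n_cell_lines))
    for j, cl in enumerate(cell_lines):
        expr[:, j] = programs[:, tissue_idx[tissues[cl]]] + rng.normal(
            scale=cfg.noise_sd, size=cfg.n_genes
        )
    expression = pd.DataFrame(expr, index=gene_ids, columns=cell_lines)

    # beta-noised binding probabilities for true edges plus decoys; under the
    # null condition both the observed pairs and the probabilities are random
    a = cfg.binding_beta_concentration
    binding: dict[str, dict[Pair, float]] = {}
    for cl in cell_lines:
        truth_set = true_edges[cl]
        probs: dict[Pair, float] = {}
        if cfg.null_binding:
            observed = _sample_pairs(
                rng, all_pairs, len(truth_set) + cfg.decoy_sites_per_cell_line
            )
            for pair in sorted(observed):
                probs[pair] = float(rng.beta(1.0, 1.0))
        else:
            false_pool = [p for p in all_pairs if p not in truth_set]
            decoys = _sample_pairs(rng, false_pool, cfg.decoy_sites_per_cell_line)
            for pair in sorted(truth_set):
                probs[pair] = float(rng.beta(0.8 * a, 0.2 * a))
            for pair in sorted(decoys):
                probs[pair] = float(rng.beta(0.2 * a, 0.8 * a))
        binding[cl] = probs

    # ChIP-like peaks over true targets; score increases with edge strength
    tss = {g: _GENE_SPACING * (i + 1) for i, g in enumerate(gene_ids)}
    peak_sets: dict[tuple[str, str], list[PeakRecord]] = {}
    for cl in cell_lines:
        for tf in tf_ids:
            targets = sorted(g for t, g in true_edges[cl] if t == tf)
            strengths = rng.uniform(0.5, 1.0, size=len(targets))
            peak_sets[(tf, cl)] = [
                PeakRecord(
                    chrom="chr1",
                    start=tss[g] - 50,
                    end=tss[g] + 50,
                    score=float(100.0 * s),
                )
                for g, s in zip(targets, strengths)
            ]

    return SyntheticTruth(
        config=cfg,
        cell_lines=cell_lines,
        tissues=tissues,
        tf_ids=tf_ids,
        gene_ids=gene_ids,
        true_edges=true_edges,
        expression=expression,
        binding_probabilities=binding,
        peak_sets=peak_sets,
    )


def random_mrf_instance(
    seed: int, n_max: int = 12, topology: str | None = None
) -> MRFInstance:
    """Seeded random field for inference testing.

    Node probabilities are uniform on (eps, 1−eps); coupling weights uniform
    on (0.5, 1), the range a coupling threshold of c = 0.5 admits.  Topology
    cycles through chain / random tree / random loopy graph with the seed
    unless given explicitly.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    p1 = rng.uniform(1e-6, 1 - 1e-6, n)
    topology = topology or ["chain", "tree", "loopy"][seed % 3]
    edges: list[tuple[int, int, float]] = []
    if topology == "chain":
        edges = [(i, i + 1, float(rng.uniform(0.5, 1.0))) for i in range(n - 1)]
    elif topology == "tree":
        for j in range(1, n):
            i = int(rng.integers(0, j))
            edges.append((i, j, float(rng.uniform(0.5, 1.0))))
    elif topology == "loopy":
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    edges.append((i, j, float(rng.uniform(0.5, 1.0))))
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return MRFInstance(
        tf_id="TF", gene_id="g", cell_lines=[f"c{i}" for i in range(n)], p1=p1, edges=edges
    )


def gene_models(truth: SyntheticTruth) -> list[GeneModel]:
    """Gene models on one synthetic chromosome, evenly spaced, + strand."""
    return [
        GeneModel(
            gene_id=g,
            chrom="chr1",
            strand="+",
            tss=_GENE_SPACING * (i + 1),
        )
        for i, g in enumerate(truth.gene_ids)
    ]


def binding_records(truth: SyntheticTruth) -> dict[str, list[BindingSiteRecord]]:
    """Observed binding sites per cell line (one site per candidate pair)."""
    tss = {g: _GENE_SPACING * (i + 1) for i, g in enumerate(truth.gene_ids)}
    out: dict[str, list[BindingSiteRecord]] = {}
    for cl, probs in truth.binding_probabilities.items():
        sites = [
            BindingSiteRecord(
                tf_id=tf,
                cell_line=cl,
                chrom="chr1",
                start=tss[g] - 100,
                end=tss[g] - 85,
                strand="+",
                probability=p,
            )
            for (tf, g), p in sorted(probs.items())
        ]
        out[cl] = sites
    return out


def emit_observations(truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Write all observations as the plain-text files the readers consume.

    Produces genes.bed (BED6), expression.tsv, one BED of binding sites per
    cell line under sites/, and one BED5 of peaks per (TF, cell line) under
    peaks/.  Output is byte-deterministic for a fixed truth.
    """
    outdir = Path(outdir)
    (outdir / "sites").mkdir(parents=True, exist_ok=True)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genes_path = outdir / "genes.bed"
    with open(genes_path, "w") as fh:
        for g in gene_models(truth):
            fh.write(f"chr1\t{g.tss}\t{g.tss + _GENE_LENGTH}\t{g.gene_id}\t0\t+\n")
    paths["genes"] = genes_path

    expr_path = outdir / "expression.tsv"
    truth.expression.round(6).to_csv(expr_path, sep="\t", index_label="gene")
    paths["expression"] = expr_path

    for cl, sites in binding_records(truth).items():
        p = outdir / "sites" / f"{cl}.bed"
        with open(p, "w") as fh:
            for s in sites:
                fh.write(
                    f"{s.chrom}\t{s.start}\t{s.end}\t{s.tf_id}\t"
                    f"{s.probability:.6f}\t{s.strand}\n"
                )
        paths[f"sites/{cl}"] = p

    for (tf, cl), peaks in sorted(truth.peak_sets.items()):
        p = outdir / "peaks" / f"{tf}__{cl}.bed"
        with open(p, "w") as fh:
            for pk in peaks:
                fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\t{tf}\t{pk.score:.4f}\n")
        paths[f"peaks/{tf}__{cl}"] = p
    return paths


def recovery_experiment(
    cfg: GeneratorConfig,
    c: float = 0.5,
    call_threshold: float = 0.5,
    method: str = "lbp",
    n_dims: int | None = None,
) -> dict:
    """Run the full pipeline on synthetic data and score it against the truth.

    Builds preliminary networks from the noised binding sites, refines them
    with the MRF, and computes per-(TF, cell line) ROC AUCs of the
    preliminary and refined scores against the true target sets (universe =
    all genes).  Reports the fraction of evaluations where refinement raised
    the AUC, counting exact ties — refinement leaving a score vector
    untouched, e.g. when a pair's field has no couplings — as half an
    improvement, the usual paired-comparison convention.

    ``n_dims`` defaults to 4 leading singular dimensions: the truncation must
    discard the noise-dominated trailing dimensions to do its job (at full
    rank the CSI degenerates to the plain correlation of the z-scored
    columns), while 2 dimensions are degenerate for a correlation.
    """
    truth = simulate_truth(cfg)
    genes = gene_models(truth)
    prelim = build_preliminary_networks(binding_records(truth), genes)
    if n_dims is None:
        n_dims = min(4, cfg.n_cell_lines, cfg.n_genes)
    csi = compute_csi(truth.expression, CSIConfig(n_dims=n_dims))
    _, table = refine_networks(
        prelim, csi, c=c, call_threshold=call_threshold, method=method
    )
    mrf_scores: dict[tuple[str, str], dict[str, float]] = {}
    for tf, gene, cl, p in table.itertuples(index=False):
        mrf_scores.setdefault((tf, cl), {})[gene] = p
    universe = set(truth.gene_ids)
    records = []
    for cl in truth.cell_lines:
        prelim_probs = prelim[cl].edge_probabilities()
        for tf in truth.tf_ids:
            positives = {g for t, g in truth.true_edges[cl] if t == tf}
            if not positives or positives == universe:
                continue
            p_scores = {g: p for (t, g), p in prelim_probs.items() if t == tf}
            m_scores = mrf_scores.get((tf, cl), {})
            auc_p = roc_auc(p_scores, positives, universe)
            auc_m = roc_auc(m_scores, positives, universe)
            records.append(
                {
                    "tf": tf,
                    "cell_line": cl,
                    "auc_prelim": auc_p,
                    "auc_mrf": auc_m,
                    "improved": bool(auc_m > auc_p),
                    "tied": bool(auc_m == auc_p),
                }
            )
    n = len(records)
    score = sum(1.0 if r["improved"] else 0.5 if r["tied"] else 0.0 for r in records)
    return {
        "records": records,
        "n": n,
        "fraction_improved": score / n if n else float("nan"),
        "mean_auc_prelim": float(np.mean([r["auc_prelim"] for r in records])) if n else float("nan"),
        "mean_auc_mrf": float(np.mean([r["auc_mrf"] for r in records])) if n else float("nan"),
    }
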