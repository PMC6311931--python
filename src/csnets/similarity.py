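"""Cell-line similarity: expression-based CSI, per-TF TNI, and the coupling graph.

The Cell-line Similarity Index (CSI) measures how alike two cell lines'
transcriptional programs are.  A differentially-expressed gene subset of the
expression matrix is z-scored per gene, decomposed by SVD, and each cell line
is represented by its coordinates in the leading ``n_dims`` singular
dimensions (scaled by the singular values, so dimensions are weighted by
explained variance); CSI is the Pearson correlation of two cell lines'
coordinate vectors.

The TF non-specificity index (TNI) is, per TF, the overlap proportion
(Jaccard by default) of its target-gene sets in two cell lines' preliminary
networks.

The coupling weight between cell lines i and j is w_ij = (CSI_ij + TNI_ij)/2,
and the cell lines are coupled in the Markov random field iff w_ij exceeds
the threshold c (default 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preliminary import CellLineNetwork

__all__ = [
    "CSIConfig",
    "CouplingGraph",
    "zscore_genes",
    "compute_csi",
    "compute_tni",
    "coupling_graph",
]


@dataclass
class CSIConfig:
    """Configuration for the CSI computation.

    Parameters
    ----------
    n_dims
        Number of leading singular dimensions used (default 16).
    de_genes
        Differentially expressed gene ids to restrict the matrix to.  If
        None, the ``n_fallback_genes`` highest-variance genes are used.
    scale_by_singular_values
        If True (default) coordinates are s_k·v_kj; if False, raw v_kj.
    n_fallback_genes
        Size of the variance-ranked fallback gene list (default 592).
    """

    n_dims: int = 16
    de_genes: set[str] | None = None
    scale_by_singular_values: bool = True
    n_fallback_genes: int = 592


@dataclass
class CouplingGraph:
    """Thresholded cell-line coupling for one TF's Markov random fields."""

    tf_id: str
    cell_lines: list[str]
    weights: pd.DataFrame
    threshold: float
    edges: set[tuple[str, str]] = field(default_factory=set)

    @classmethod
    def from_weights(
        cls, tf_id: str, weights: pd.DataFrame, threshold: float
    ) -> "CouplingGraph":
        cell_lines = list(weights.index)
        edges = set()
        for a, i in zip(cell_lines, range(len(cell_lines))):
            for b in cell_lines[i + 1 :]:
                if weights.loc[a, b] > threshold:
                    edges.add((a, b))
        return cls(
            tf_id=tf_id,
            cell_lines=cell_lines,
            weights=weights,
            threshold=threshold,
            edges=edges,
        )

    def weight(self, a: str, b: str) -> float:
        return float(self.weights.loc[a, b])


def zscore_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Normalize each gene row to mean 0, population sd 1.

    Constant rows cannot be scaled and are dropped with a warning.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scoring needs at least two cell lines")
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population sd
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant expression rows")
    keep = ~constant
    z = (values[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(z, index=expr.index[keep], columns=expr.columns)


def _select_genes(expr: pd.DataFrame, cfg: CSIConfig) -> pd.DataFrame:
    if cfg.de_genes is not None:
        present = [g for g in expr.index if g in cfg.de_genes]
        if not present:
            raise ValueError("none of the DE genes are present in the expression table")
        return expr.loc[present]
    if expr.shape[0] <= cfg.n_fallback_genes:
        return expr
    variances = expr.to_numpy(dtype=float).var(axis=1)
    order = np.argsort(-variances, kind="stable")[: cfg.n_fallback_genes]
    return expr.iloc[np.sort(order)]


def compute_csi(expr: pd.DataFrame, cfg: CSIConfig | None = None) -> pd.DataFrame:
    """Cell-line similarity matrix from an expression table (genes × cell lines).

    Returns a symmetric DataFrame with unit diagonal and values in [−1, 1].
    """
    cfg = cfg or CSIConfig()
    sub = _select_genes(expr, cfg)
    z = zscore_genes(sub)
    matrix = z.to_numpy(dtype=float)
    rank = min(matrix.shape)
    if not 1 <= cfg.n_dims <= rank:
        raise ValueError(
            f"n_dims={cfg.n_dims} must be in [1, min(#genes, #cell lines)={rank}]"
        )
    # coordinates of cell line j in the leading singular dimensions: s_k v_kj
    _, s, vt = np.linalg.svd(matrix, full_matrices=False)
    # each singular vector is defined only up to sign, and the sign returned
    # by the decomposition depends on the gene row order; fix it so that each
    # right singular vector's largest-magnitude entry is positive
    pivot = np.argmax(np.abs(vt), axis=1)
    signs = np.sign(vt[np.arange(vt.shape[0]), pivot])
    signs[signs == 0] = 1.0
    vt = signs[:, None] * vt
    coords = vt[: cfg.n_dims]
    if cfg.scale_by_singular_values:
        coords = s[: cfg.n_dims, None] * coords
    csi = np.corrcoef(coords.T)
    csi = np.clip((csi + csi.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(csi, 1.0)
    return pd.DataFrame(csi, index=expr.columns, columns=expr.columns)


def compute_tni(
    networks: dict[str, CellLineNetwork],
    tf_id: str,
    denominator: str = "union",
) -> pd.DataFrame:
    """Per-TF target-set overlap between every pair of cell lines.

    ``denominator="union"`` gives the Jaccard index |T_i ∩ T_j| / |T_i ∪ T_j|;
    ``"min"`` divides by the smaller set instead.  Two empty target sets give 0.
    """
    if denominator not in {"union", "min"}:
        raise ValueError(f"unknown TNI denominator {denominator!r}")
    cell_lines = sorted(networks)
    known = any(tf_id in networks[cl].tf_targets for cl in cell_lines)
    if not known:
        raise KeyError(f"TF {tf_id!r} has no targets in any cell line")
    targets = {cl: networks[cl].tf_targets.get(tf_id, set()) for cl in cell_lines}
    n = len(cell_lines)
    tni = np.zeros((n, n))
    for i, a in enumerate(cell_lines):
        for j in range(i, n):
            b = cell_lines[j]
            ta, tb = targets[a], targets[b]
            inter = len(ta & tb)
            if denominator == "union":
                denom = len(ta | tb)
            else:
                denom = min(len(ta), len(tb))
            tni[i, j] = tni[j, i] = inter / denom if denom else 0.0
    return pd.DataFrame(tni, index=cell_lines, columns=cell_lines)


def coupling_graph(
    csi: pd.DataFrame, tni: pd.DataFrame, c: float = 0.5, tf_id: str = ""
) -> CouplingGraph:
    """Average CSI and TNI into edge weights, keep pairs with w_ij > c."""
    if list(csi.index) != list(tni.index) or list(csi.columns) != list(tni.columns):
        raise ValueError("CSI and TNI cell-line lists do not match")
    weights = (csi + tni) / 2.0
    return CouplingGraph.from_weights(tf_id=tf_id, weights=weights, threshold=c)
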