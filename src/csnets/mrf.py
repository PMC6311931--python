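"""Pairwise binary Markov random field over cell lines for one TF–gene pair.

For a fixed regulatory relationship (TF A → gene B) the field has one binary
variable x_i per cell line: x_i = 1 means the regulation exists in cell line
i.  The node potential favours the label supported by the observed binding
probability P(1,i):

    φ_i(x_i) = P(1,i)/P(0,i)  if P(1,i) > P(0,i) and x_i = 1
             = P(0,i)/P(1,i)  if P(0,i) > P(1,i) and x_i = 0
             = 1              otherwise

with P(0,i) = 1 − P(1,i).  The edge potential couples similar cell lines:
ψ_ij = e^{w_ij} when x_i = x_j and 1 otherwise, where w_ij is the averaged
CSI/TNI similarity weight and only pairs with w_ij above a threshold c are
coupled.  The joint distribution is Pr(X) ∝ Π ψ Π φ, i.e. minus its log is
the pseudo-energy

    E(X) = −γ − Σ_i ln φ_i(x_i) − Σ_(i,j) ln ψ_ij(x_i, x_j),   γ = 0.

Because ln ψ(1,1) + ln ψ(0,0) = 2 w_ij ≥ 0 = ln ψ(1,0) + ln ψ(0,1) whenever
c ≥ 0, the energy is submodular and its exact MAP labeling is a minimum s–t
cut.  Approximate marginals come from loopy belief propagation; iterated
conditional modes is available as a greedy refiner.  An exhaustive
enumeration oracle (n ≤ 20) provides exact MAP and marginals for testing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io import NETWORK_COLUMNS
from .preliminary import EPSILON, CellLineNetwork, RegulatoryEdge, clamp_probability
from .similarity import CouplingGraph, compute_tni

__all__ = [
    "MRFInstance",
    "MarginalTable",
    "node_potential",
    "edge_potential",
    "pseudo_energy",
    "brute_force_infer",
    "map_by_mincut",
    "icm_refine",
    "lbp_marginals",
    "refine_networks",
]


def node_potential(p1: float, p0: float, x: int) -> float:
    """The unary potential φ_i; p0 and p1 must be in (0,1) and sum to 1."""
    if p1 > p0 and x == 1:
        return p1 / p0
    if p0 > p1 and x == 0:
        return p0 / p1
    return 1.0


def edge_potential(w: float, xi: int, xj: int) -> float:
    """The pairwise potential ψ_ij: e^w on label agreement, 1 otherwise."""
    return math.exp(w) if xi == xj else 1.0


@dataclass
class MRFInstance:
    """One TF–gene pair's binary field over cell lines.

    ``edges`` holds index pairs into ``cell_lines`` with their coupling
    weights; all weights must be nonnegative (submodularity), which holds by
    construction when the coupling threshold c ≥ 0.
    """

    tf_id: str
    gene_id: str
    cell_lines: list[str]
    p1: np.ndarray
    edges: list[tuple[int, int, float]] = field(default_factory=list)
    gamma: float = 0.0

    def __post_init__(self) -> None:
        self.p1 = np.clip(np.asarray(self.p1, dtype=float), EPSILON, 1.0 - EPSILON)
        if self.p1.shape != (len(self.cell_lines),):
            raise ValueError("p1 length does not match cell lines")
        self.assert_submodular()

    @property
    def n(self) -> int:
        return len(self.cell_lines)

    @property
    def p0(self) -> np.ndarray:
        return 1.0 - self.p1

    def log_phi(self) -> np.ndarray:
        """(n, 2) array of ln φ_i(x) for x = 0, 1."""
        alpha = np.zeros((self.n, 2))
        ratio = np.log(self.p1) - np.log(self.p0)
        alpha[:, 1] = np.where(ratio > 0, ratio, 0.0)
        alpha[:, 0] = np.where(ratio < 0, -ratio, 0.0)
        return alpha

    def assert_submodular(self) -> None:
        """β(1,1)+β(0,0) ≥ β(1,0)+β(0,1) on every edge, i.e. 2w ≥ 0."""
        for i, j, w in self.edges:
            if 2.0 * w < 0.0:
                raise ValueError(
                    f"edge ({self.cell_lines[i]}, {self.cell_lines[j]}) with weight "
                    f"{w} violates submodularity; coupling threshold must be >= 0"
                )

    @classmethod
    def from_coupling(
        cls,
        tf_id: str,
        gene_id: str,
        p1_by_cell_line: dict[str, float],
        coupling: CouplingGraph,
        eps: float = EPSILON,
    ) -> "MRFInstance":
        """Build the field over the coupling graph's cell lines.

        Cell lines without an observed binding probability enter with
        P(1,i) = eps: regulation not observed, not impossible.
        """
        cell_lines = list(coupling.cell_lines)
        index = {cl: i for i, cl in enumerate(cell_lines)}
        p1 = np.array(
            [clamp_probability(p1_by_cell_line.get(cl, eps), eps) for cl in cell_lines]
        )
        edges = []
        for a, b in sorted(coupling.edges):
            i, j = index[a], index[b]
            edges.append((min(i, j), max(i, j), coupling.weight(a, b)))
        return cls(tf_id=tf_id, gene_id=gene_id, cell_lines=cell_lines, p1=p1, edges=edges)


@dataclass
class MarginalTable:
    """Per-cell-line Pr(x_i = 1) beliefs with convergence diagnostics."""

    pr1: np.ndarray
    converged: bool
    iterations: int


def pseudo_energy(inst: MRFInstance, labeling: np.ndarray) -> float:
    """E(X) = −γ − Σ ln φ − Σ ln ψ for one labeling."""
    x = np.asarray(labeling, dtype=int)
    if x.shape != (inst.n,):
        raise ValueError("labeling length does not match instance")
    alpha = inst.log_phi()
    e = -inst.gamma - float(alpha[np.arange(inst.n), x].sum())
    for i, j, w in inst.edges:
        if x[i] == x[j]:
            e -= w
    return e


def _all_labelings(n: int) -> np.ndarray:
    return np.array(list(itertools.product((0, 1), repeat=n)), dtype=int)


def brute_force_infer(inst: MRFInstance) -> tuple[np.ndarray, MarginalTable]:
    """Exhaustive enumeration: exact MAP labeling and exact marginals.

    MAP ties are broken toward the lexicographically smallest labeling.
    Only feasible for n ≤ 20.
    """
    if inst.n > 20:
        raise ValueError("brute force limited to n <= 20 variables")
    labelings = _all_labelings(inst.n)
    alpha = inst.log_phi()
    energies = -inst.gamma - alpha[np.arange(inst.n), labelings].sum(axis=1)
    for i, j, w in inst.edges:
        energies -= w * (labelings[:, i] == labelings[:, j])
    best = int(np.argmin(energies))  # argmin takes first minimum = lexicographic
    log_weights = -energies
    log_z = logsumexp(log_weights)
    pr1 = np.array(
        [
            math.exp(logsumexp(log_weights[labelings[:, i] == 1]) - log_z)
            for i in range(inst.n)
        ]
    )
    return labelings[best].copy(), MarginalTable(pr1=pr1, converged=True, iterations=1)


def map_by_mincut(inst: MRFInstance) -> np.ndarray:
    """Exact MAP labeling by reduction of the submodular energy to s–t min-cut.

    Each pairwise energy table (A, B; C, D) with A = D = −w, B = C = 0 is
    decomposed into unary shifts (C−A on x_i = 1, D−C on x_j = 1) plus a
    nonnegative capacity B+C−A−D = 2w on the arc i→j, which is cut exactly
    when x_i = 0 and x_j = 1.  A variable is labeled 1 when its node falls on
    the sink side of the minimum cut.
    """
    inst.assert_submodular()
    alpha = inst.log_phi()
    cost1 = -alpha[:, 1].copy()
    cost0 = -alpha[:, 0].copy()
    g = nx.DiGraph()
    g.add_nodes_from(range(inst.n))
    g.add_node("s")
    g.add_node("t")
    for i, j, w in inst.edges:
        cost1[i] += w  # C − A
        cost1[j] -= w  # D − C
        if w > 0:
            g.add_edge(i, j, capacity=2.0 * w)
    for i in range(inst.n):
        diff = cost1[i] - cost0[i]
        if diff > 0:
            g.add_edge("s", i, capacity=diff)
        elif diff < 0:
            g.add_edge(i, "t", capacity=-diff)
    _, (_source_side, sink_side) = nx.minimum_cut(g, "s", "t")
    x = np.zeros(inst.n, dtype=int)
    for node in sink_side:
        if node != "t":
            x[node] = 1
    return x


def _nodewise_argmax(inst: MRFInstance) -> np.ndarray:
    """Label each node by its own potential alone (ties toward 0)."""
    return (inst.p1 > inst.p0).astype(int)


def icm_refine(inst: MRFInstance, init: np.ndarray | None = None) -> np.ndarray:
    """Iterated conditional modes: greedy single-site descent on the energy.

    Sweeps nodes in index order, flipping a label whenever that strictly
    lowers E(X); stops at a local minimum.  Energy is non-increasing.
    """
    x = _nodewise_argmax(inst) if init is None else np.asarray(init, dtype=int).copy()
    alpha = inst.log_phi()
    neighbors: dict[int, list[tuple[int, float]]] = {i: [] for i in range(inst.n)}
    for i, j, w in inst.edges:
        neighbors[i].append((j, w))
        neighbors[j].append((i, w))
    changed = True
    while changed:
        changed = False
        for i in range(inst.n):
            xi = x[i]
            # energy difference of flipping node i (new − old)
            delta = alpha[i, xi] - alpha[i, 1 - xi]
            for j, w in neighbors[i]:
                if x[j] == xi:
                    delta += w  # flip breaks a satisfied edge
                else:
                    delta -= w  # flip satisfies it
            if delta < 0:
                x[i] = 1 - xi
                changed = True
    return x


def lbp_marginals(
    inst: MRFInstance,
    damping: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> MarginalTable:
    """Sum-product loopy belief propagation beliefs Pr(x_i = 1).

    Messages are updated synchronously (flooding schedule), damped, and
    normalized each round; the partition function is never formed.  On
    tree-structured fields the beliefs are the exact marginals.  If the
    message change never drops below ``tol`` the last beliefs are returned
    with ``converged=False``.
    """
    n = inst.n
    alpha = inst.log_phi()
    phi = np.exp(alpha)  # (n, 2)
    if not inst.edges:
        # isolated nodes: φ1/(φ0+φ1) simplifies to p1 exactly
        return MarginalTable(pr1=inst.p1.copy(), converged=True, iterations=0)
    directed = []
    psi = {}
    for i, j, w in inst.edges:
        directed.append((i, j))
        directed.append((j, i))
        m = np.array([[math.exp(w), 1.0], [1.0, math.exp(w)]])
        psi[(i, j)] = m
        psi[(j, i)] = m  # symmetric
    incoming: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for i, j in directed:
        incoming[j].append((i, j))
    messages = {e: np.array([0.5, 0.5]) for e in directed}
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        new_messages = {}
        for i, j in directed:
            prod = phi[i].copy()
            for e in incoming[i]:
                if e[0] != j:
                    prod = prod * messages[e]
            m = psi[(i, j)].T @ prod  # m(x_j) = Σ_{x_i} ψ(x_i,x_j) ...
            m /= m.sum()
            m = damping * messages[(i, j)] + (1.0 - damping) * m
            m /= m.sum()
            new_messages[(i, j)] = m
        delta = max(
            float(np.max(np.abs(new_messages[e] - messages[e]))) for e in directed
        )
        messages = new_messages
        if delta < tol:
            converged = True
            break
    beliefs = np.empty(n)
    for i in range(n):
        if not incoming[i]:  # isolated node: closed form, exactly p1
            beliefs[i] = inst.p1[i]
            continue
        b = phi[i].copy()
        for e in incoming[i]:
            b = b * messages[e]
        beliefs[i] = b[1] / b.sum()
    return MarginalTable(pr1=beliefs, converged=converged, iterations=iterations)


def refine_networks(
    prelim: dict[str, CellLineNetwork],
    csi: pd.DataFrame,
    tni_by_tf: dict[str, pd.DataFrame] | None = None,
    c: float = 0.5,
    call_threshold: float = 0.5,
    method: str = "lbp",
    eps: float = EPSILON,
    observed_cell_lines_only: bool = False,
    tni_denominator: str = "union",
    lbp_kwargs: dict | None = None,
) -> tuple[dict[str, CellLineNetwork], pd.DataFrame]:
    """Refine preliminary networks by MRF inference across cell lines.

    For every (TF, gene) pair present in at least one preliminary network an
    MRF instance is built over all cell lines (unobserved cell lines enter
    with P(1,i) = eps, or are excluded when ``observed_cell_lines_only``),
    coupled by the TF's thresholded (CSI+TNI)/2 graph, and solved by the
    chosen method: ``"lbp"`` (refined probability = belief), ``"mincut"`` or
    ``"icm"`` (refined probability = MAP label as 0/1).  An edge is called in
    cell line i iff its refined probability exceeds ``call_threshold``.

    Returns the refined networks and a long-format table of refined
    probabilities (tf, gene, cell_line, probability).
    """
    if method not in {"lbp", "mincut", "icm"}:
        raise ValueError(f"unknown inference method {method!r}")
    cell_lines = sorted(prelim)
    if list(csi.index) != cell_lines:
        csi = csi.loc[cell_lines, cell_lines]
    pair_probs: dict[str, dict[str, dict[str, float]]] = {}
    for cl in cell_lines:
        for edge in prelim[cl].edges:
            pair_probs.setdefault(edge.tf_id, {}).setdefault(edge.gene_id, {})[
                cl
            ] = edge.probability
    if not pair_probs:
        raise ValueError("empty preliminary edge universe")
    lbp_kwargs = lbp_kwargs or {}
    rows = []
    called: dict[str, set[RegulatoryEdge]] = {cl: set() for cl in cell_lines}
    for tf_id in sorted(pair_probs):
        tni = (
            tni_by_tf[tf_id]
            if tni_by_tf is not None
            else compute_tni(prelim, tf_id, denominator=tni_denominator)
        )
        weights = (csi + tni.loc[cell_lines, cell_lines]) / 2.0
        coupling = CouplingGraph.from_weights(tf_id=tf_id, weights=weights, threshold=c)
        for gene_id in sorted(pair_probs[tf_id]):
            observed = pair_probs[tf_id][gene_id]
            if observed_cell_lines_only:
                keep = sorted(observed)
                sub = weights.loc[keep, keep]
                local_coupling = CouplingGraph.from_weights(tf_id, sub, c)
            else:
                local_coupling = coupling
            inst = MRFInstance.from_coupling(
                tf_id, gene_id, observed, local_coupling, eps=eps
            )
            if method == "lbp":
                refined = lbp_marginals(inst, **lbp_kwargs).pr1
            elif method == "mincut":
                refined = map_by_mincut(inst).astype(float)
            else:
                refined = icm_refine(inst).astype(float)
            for cl, p in zip(inst.cell_lines, refined):
                p = float(p)
                rows.append((tf_id, gene_id, cl, p))
                if p > call_threshold:
                    called[cl].add(
                        RegulatoryEdge(
                            tf_id=tf_id, gene_id=gene_id, cell_line=cl, probability=p
                        )
                    )
    refined_networks = {
        cl: CellLineNetwork.from_edges(cl, edges) for cl, edges in called.items()
    }
    table = pd.DataFrame(rows, columns=NETWORK_COLUMNS)
    return refined_networks, table
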