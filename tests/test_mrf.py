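"""Markov random field potentials, energy, and the three inference routes."""

import math

import numpy as np
import pandas as pd
import pytest

from csnets.simulate import random_mrf_instance
from csnets.mrf import (
    brute_force_infer,
    edge_potential,
    icm_refine,
    lbp_marginals,
    map_by_mincut,
    node_potential,
    pseudo_energy,
    refine_networks,
)
from csnets.preliminary import CellLineNetwork, RegulatoryEdge


class TestPotentials:
    @pytest.mark.parametrize(
        "p1,p0,x,expected",
        [(0.8, 0.2, 1, 4.0), (0.8, 0.2, 0, 1.0), (0.5, 0.5, 1, 1.0), (0.2, 0.8, 0, 4.0)],
    )
    def test_node_potential_branches(self, p1, p0, x, expected):
        assert node_potential(p1, p0, x) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "w,xi,xj,expected",
        [(0.5, 1, 1, math.e**0.5), (0.5, 0, 1, 1.0), (1.0, 0, 0, math.e)],
    )
    def test_edge_potential_branches(self, w, xi, xj, expected):
        assert edge_potential(w, xi, xj) == pytest.approx(expected)


class TestPseudoEnergy:
    def test_uninformative_field_has_zero_energy(self, make_instance):
        inst = make_instance([0.5, 0.5, 0.5])
        assert pseudo_energy(inst, np.zeros(3)) == 0.0

    def test_two_node_example(self, make_instance):
        inst = make_instance([0.9, 0.45], edges=[(0, 1, 0.9)])
        assert pseudo_energy(inst, np.array([1, 1])) == pytest.approx(-(math.log(9) + 0.9))

    def test_breaking_a_satisfied_edge_raises_energy_by_its_weight(self, make_instance):
        inst = make_instance([0.5, 0.5], edges=[(0, 1, 0.7)])
        e_same = pseudo_energy(inst, np.array([1, 1]))
        e_diff = pseudo_energy(inst, np.array([1, 0]))
        assert e_diff - e_same == pytest.approx(0.7)

    def test_gamma_shifts_energy_uniformly(self, make_instance):
        inst = make_instance([0.9, 0.45], edges=[(0, 1, 0.9)])
        inst.gamma = 2.5
        shifted = pseudo_energy(inst, np.array([1, 1]))
        inst.gamma = 0.0
        base = pseudo_energy(inst, np.array([1, 1]))
        assert shifted == pytest.approx(base - 2.5)


class TestBruteForce:
    @pytest.mark.parametrize("p1,expected", [(0.9, 0.9), (0.3, 0.3), (0.5, 0.5)])
    def test_isolated_node_marginal_equals_p1(self, make_instance, p1, expected):
        _, marg = brute_force_infer(make_instance([p1]))
        assert marg.pr1[0] == pytest.approx(expected, abs=1e-12)

    def test_two_node_map_is_all_ones(self, make_instance):
        lab, _ = brute_force_infer(make_instance([0.9, 0.45], edges=[(0, 1, 0.9)]))
        assert lab.tolist() == [1, 1]

    def test_size_limit(self, make_instance):
        with pytest.raises(ValueError):
            brute_force_infer(make_instance([0.5] * 21))


class TestMinCut:
    def test_no_edges_reduces_to_nodewise_argmax(self, make_instance):
        lab = map_by_mincut(make_instance([0.9, 0.2, 0.7]))
        assert lab.tolist() == [1, 0, 1]

    def test_two_node_example_matches_brute_force(self, make_instance):
        inst = make_instance([0.9, 0.45], edges=[(0, 1, 0.9)])
        assert map_by_mincut(inst).tolist() == brute_force_infer(inst)[0].tolist()

    def test_energy_equals_enumeration_minimum_on_random_instances(self):
        for seed in range(60):
            inst = random_mrf_instance(seed)
            e_bf = pseudo_energy(inst, brute_force_infer(inst)[0])
            e_mc = pseudo_energy(inst, map_by_mincut(inst))
            assert e_mc == pytest.approx(e_bf, abs=1e-9)

    def test_negative_weight_rejected_as_non_submodular(self, make_instance):
        with pytest.raises(ValueError, match="submodular"):
            make_instance([0.5, 0.5], edges=[(0, 1, -0.1)])


class TestICM:
    def test_fixed_at_global_minimum(self, make_instance):
        inst = make_instance([0.9, 0.45], edges=[(0, 1, 0.9)])
        map_lab = map_by_mincut(inst)
        assert icm_refine(inst, init=map_lab).tolist() == map_lab.tolist()

    def test_isolated_nodes_reach_nodewise_argmax_from_any_init(self, make_instance):
        inst = make_instance([0.9, 0.2, 0.7])
        assert icm_refine(inst, init=np.array([0, 1, 0])).tolist() == [1, 0, 1]

    def test_descent_property_on_random_instances(self):
        for seed in range(20):
            inst = random_mrf_instance(seed)
            rng = np.random.default_rng(seed)
            init = rng.integers(0, 2, inst.n)
            final = icm_refine(inst, init=init)
            assert pseudo_energy(inst, final) <= pseudo_energy(inst, init) + 1e-12


class TestLBP:
    def test_isolated_node_belief_is_p1(self, make_instance):
        marg = lbp_marginals(make_instance([0.8]))
        assert marg.pr1[0] == pytest.approx(0.8, abs=1e-12) and marg.converged

    def test_tree_beliefs_match_exact_marginals(self):
        for seed in range(25):
            inst = random_mrf_instance(seed, topology="tree")
            _, exact = brute_force_infer(inst)
            lbp = lbp_marginals(inst, tol=1e-10, max_iter=2000)
            assert lbp.converged
            np.testing.assert_allclose(lbp.pr1, exact.pr1, atol=1e-6)

    def test_positive_coupling_pulls_weak_node_up(self, make_instance):
        inst = make_instance([0.9, 0.45], edges=[(0, 1, 0.9)])
        marg = lbp_marginals(inst, tol=1e-10, max_iter=2000)
        assert marg.pr1[1] > 0.45
        _, exact = brute_force_infer(inst)
        np.testing.assert_allclose(marg.pr1, exact.pr1, atol=1e-6)

    def test_beliefs_always_in_unit_interval(self):
        for seed in range(15):
            inst = random_mrf_instance(seed, topology="loopy")
            pr1 = lbp_marginals(inst).pr1
            assert ((pr1 >= 0) & (pr1 <= 1)).all()


def _prelim_from_probs(probs_by_cell: dict[str, dict[tuple[str, str], float]]):
    nets = {}
    for cl, probs in probs_by_cell.items():
        edges = {
            RegulatoryEdge(tf_id=tf, gene_id=g, cell_line=cl, probability=p)
            for (tf, g), p in probs.items()
        }
        nets[cl] = CellLineNetwork.from_edges(cl, edges)
    return nets


def _uniform_csi(cells, value):
    m = np.full((len(cells), len(cells)), value)
    np.fill_diagonal(m, 1.0)
    return pd.DataFrame(m, index=cells, columns=cells)


class TestRefineNetworks:
    def test_single_cell_line_reduces_to_nodewise_calls(self):
        prelim = _prelim_from_probs({"A": {("TF1", "g1"): 0.9, ("TF1", "g2"): 0.3}})
        refined, table = refine_networks(prelim, _uniform_csi(["A"], 1.0))
        assert refined["A"].tf_targets == {"TF1": {"g1"}}
        probs = dict(zip(table["gene"], table["probability"]))
        assert probs["g1"] == pytest.approx(0.9, abs=1e-9)

    def test_smoothing_calls_weakly_supported_edge_in_coupled_cell_line(self):
        # pair strongly observed in 9 mutually coupled cell lines and weak
        # (0.45) in a 10th coupled to all: smoothing calls it everywhere,
        # matching exact inference on the 10-node field
        cells = [f"C{i}" for i in range(10)]
        probs = {cl: {("TF1", "g1"): 0.9} for cl in cells[:9]}
        probs[cells[9]] = {("TF1", "g1"): 0.45}
        prelim = _prelim_from_probs(probs)
        # identical target sets -> TNI = 1; set CSI so w = (CSI+1)/2 > 0.5
        refined, table = refine_networks(prelim, _uniform_csi(cells, 0.8))
        assert "g1" in refined[cells[9]].tf_targets.get("TF1", set())
        from csnets.mrf import MRFInstance

        inst = MRFInstance(
            "TF1", "g1", cells, np.array([0.9] * 9 + [0.45]),
            edges=[(i, j, 0.9) for i in range(10) for j in range(i + 1, 10)],
        )
        lab, _ = brute_force_infer(inst)
        assert lab.tolist() == [1] * 10

    def test_threshold_one_makes_refinement_identity_up_to_thresholding(self):
        prelim = _prelim_from_probs(
            {
                "A": {("TF1", "g1"): 0.9, ("TF1", "g2"): 0.2},
                "B": {("TF1", "g1"): 0.8},
            }
        )
        refined, table = refine_networks(prelim, _uniform_csi(["A", "B"], 1.0), c=1.0)
        assert refined["A"].tf_targets == {"TF1": {"g1"}}
        assert refined["B"].tf_targets == {"TF1": {"g1"}}
        got = {
            (r.tf, r.gene, r.cell_line): r.probability for r in table.itertuples(index=False)
        }
        assert got[("TF1", "g2", "A")] == pytest.approx(0.2, abs=1e-9)

    def test_map_methods_agree_with_lbp_calls_on_strong_signal(self):
        cells = ["A", "B", "C"]
        probs = {cl: {("TF1", "g1"): 0.95, ("TF1", "g2"): 0.05} for cl in cells}
        prelim = _prelim_from_probs(probs)
        csi = _uniform_csi(cells, 0.9)
        for method in ("lbp", "mincut", "icm"):
            refined, _ = refine_networks(prelim, csi, method=method)
            for cl in cells:
                assert refined[cl].tf_targets == {"TF1": {"g1"}}

    def test_cell_line_permutation_equivariance(self):
        probs = {
            "A": {("TF1", "g1"): 0.9, ("TF1", "g2"): 0.6},
            "B": {("TF1", "g1"): 0.4},
            "C": {("TF1", "g2"): 0.7},
        }
        prelim = _prelim_from_probs(probs)
        csi = _uniform_csi(["A", "B", "C"], 0.8)
        _, t1 = refine_networks(prelim, csi)
        perm = ["C", "A", "B"]
        _, t2 = refine_networks(prelim, csi.loc[perm, perm])
        k1 = {(r.tf, r.gene, r.cell_line): r.probability for r in t1.itertuples(index=False)}
        k2 = {(r.tf, r.gene, r.cell_line): r.probability for r in t2.itertuples(index=False)}
        assert set(k1) == set(k2)
        for key in k1:
            assert k1[key] == pytest.approx(k2[key], abs=1e-9)

    def test_empty_universe_rejected(self):
        prelim = {"A": CellLineNetwork.from_edges("A", set())}
        with pytest.raises(ValueError):
            refine_networks(prelim, _uniform_csi(["A"], 1.0))
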