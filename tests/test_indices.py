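"""Per-node indices: H-index family, k-shell peeling, constraint, masses."""

import math

import networkx as nx
import numpy as np
import pytest

from hvgc import (
    Graph,
    constraint,
    degree,
    eigenvector_centrality,
    gg_mass,
    h_index,
    hv_index,
    k_shell,
    k_shell_decomposition,
    local_clustering,
    spreading_entropy,
)

from conftest import random_er, to_networkx


def brute_h_index(g, u):
    degs = sorted((g.degree(v) for v in g.neighbors(u)), reverse=True)
    return max([0] + [h for h in range(1, len(degs) + 1) if degs[h - 1] >= h])


class TestDegreeFamily:
    def test_toy_degrees(self, toy_graph):
        d = degree(toy_graph)
        assert (d["5"], d["10"]) == (4, 1)

    def test_isolated_node_zero(self):
        g = Graph([("a", "b")])
        g.add_node("c")
        assert degree(g)["c"] == 0
        assert h_index(g)["c"] == 0

    def test_toy_h_index_published_values(self, toy_graph):
        h = h_index(toy_graph)
        assert all(h[u] == 3 for u in ("5", "7", "8"))
        assert all(h[u] == 2 for u in ("6", "9"))
        assert all(h[u] == 1 for u in ("1", "2", "3", "4", "10"))

    def test_star_center_h_is_one(self, star4):
        assert h_index(star4)["hub"] == 1

    def test_triangle_h_is_two(self, triangle):
        assert all(v == 2 for v in h_index(triangle).values())

    @pytest.mark.parametrize("seed", range(10))
    def test_h_index_matches_brute_force_and_degree_bound(self, seed):
        g = random_er(seed)
        h = h_index(g)
        for u in g:
            assert h[u] == brute_h_index(g, u)
            assert 0 <= h[u] <= g.degree(u)

    def test_toy_hv_published_values(self, toy_graph):
        hv = hv_index(toy_graph)
        assert hv["6"] == 8
        assert hv["5"] == 11
        assert hv["9"] == 7
        assert hv["3"] == 7  # table value; the running text's "4" is a typo

    def test_triangle_hv(self, triangle):
        assert all(v == 4 for v in hv_index(triangle).values())

    @pytest.mark.parametrize("seed", range(5))
    def test_hv_lower_bound(self, seed):
        # at least H(i) neighbors of degree >= H(i) contribute, each >= H(i)
        g = random_er(seed)
        h, hv = h_index(g), hv_index(g)
        for u in g:
            if g.degree(u) > 0:
                assert hv[u] >= h[u] ** 2


class TestKShell:
    def test_clique_k4(self):
        g = Graph([(i, j) for i in range(4) for j in range(i + 1, 4)])
        dec = k_shell_decomposition(g)
        assert all(dec.shell[u] == 3 for u in g)
        assert all(dec.iteration[u] == 1 for u in g)
        assert dec.passes[3] == 1

    def test_toy_shells(self, toy_graph):
        ks = k_shell(toy_graph)
        assert ks["5"] == 2
        assert ks["3"] == 1

    def test_path_of_five_removal_waves(self):
        g = Graph([(1, 2), (2, 3), (3, 4), (4, 5)])
        dec = k_shell_decomposition(g)
        assert all(s == 1 for s in dec.shell.values())
        assert dec.iteration == {1: 1, 5: 1, 2: 2, 4: 2, 3: 3}
        assert dec.passes[1] == 3

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_networkx_core_number(self, seed):
        g = random_er(seed, n=25, p=0.2)
        assert k_shell(g).scores == {
            u: float(c) for u, c in nx.core_number(to_networkx(g)).items()
        }

    @pytest.mark.parametrize("seed", range(10))
    def test_improved_index_stays_within_shell_band(self, seed):
        g = random_er(seed)
        dec = k_shell_decomposition(g)
        imp = dec.improved()
        max_deg = max(g.degree(u) for u in g)
        assert max(dec.shell.values()) <= max_deg
        for u in g:
            assert dec.shell[u] <= imp[u] < dec.shell[u] + 1


class TestClusteringAndConstraint:
    def test_triangle_clustering_one(self, triangle):
        assert all(v == 1 for v in local_clustering(triangle).values())

    def test_star_center_zero(self, star4):
        assert local_clustering(star4)["hub"] == 0

    def test_toy_node5_third(self, toy_graph):
        assert local_clustering(toy_graph)["5"] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_clustering_matches_networkx(self, seed):
        g = random_er(seed)
        ours = local_clustering(g)
        theirs = nx.clustering(to_networkx(g))
        for u in g:
            assert ours[u] == pytest.approx(theirs[u])

    def test_degree_one_constraint_is_one(self, star4):
        c = constraint(star4)
        assert all(c[u] == pytest.approx(1.0) for u in ("l1", "l2", "l3"))

    def test_triangle_constraint(self, triangle):
        # each neighbor term: (1/2 + 1/2 * 1/2)^2 = 9/16; two neighbors
        assert all(v == pytest.approx(1.125) for v in constraint(triangle).values())

    def test_toy_node3_constraint(self, toy_graph):
        # neighbors 1,2,4,5 share no common neighbor with 3: 4 * (1/4)^2
        assert constraint(toy_graph)["3"] == pytest.approx(0.25)

    def test_isolated_node_convention(self):
        g = Graph([("a", "b")])
        g.add_node("z")
        assert constraint(g)["z"] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_constraint_matches_networkx(self, seed):
        g = random_er(seed)
        ours = constraint(g)
        theirs = nx.constraint(to_networkx(g))
        for u in g:
            if g.degree(u) > 0:
                assert ours[u] == pytest.approx(theirs[u], rel=1e-9)

    def test_constraint_permutes_with_labels(self, toy_graph):
        mapping = {u: f"x{u}" for u in toy_graph.nodes}
        c1 = constraint(toy_graph)
        c2 = constraint(toy_graph.relabel(mapping))
        for u in toy_graph:
            assert c2[mapping[u]] == pytest.approx(c1[u])


class TestEigenvector:
    def test_regular_graph_uniform(self):
        g = Graph([(i, (i + 1) % 6) for i in range(6)])
        x = eigenvector_centrality(g)
        assert all(v == pytest.approx(1 / 6, rel=1e-6) for v in x.values())

    def test_star_center_dominates(self, star4):
        x = eigenvector_centrality(star4)
        assert x["hub"] > max(x[u] for u in ("l1", "l2", "l3"))

    def test_toy_matches_dense_eigendecomposition(self, toy_graph):
        x = eigenvector_centrality(toy_graph, tol=1e-13, max_iter=5000)
        nodes = toy_graph.nodes
        a = np.zeros((10, 10))
        idx = {u: i for i, u in enumerate(nodes)}
        for u, v in toy_graph.edges():
            a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
        w, vecs = np.linalg.eigh(a)
        lead = np.abs(vecs[:, np.argmax(w)])
        lead /= lead.sum()
        for u in nodes:
            assert x[u] == pytest.approx(lead[idx[u]], rel=1e-6)

    def test_nonconvergence_raises(self, toy_graph):
        with pytest.raises(RuntimeError, match="converge"):
            eigenvector_centrality(toy_graph, tol=1e-15, max_iter=2)


class TestMasses:
    def test_triangle_spreading_entropy(self, triangle):
        assert all(v == pytest.approx(4.0) for v in spreading_entropy(triangle).values())

    def test_path3_spreading_entropy(self, path3):
        # I(a)=I(c)=1/2, I(b)=1; E(ends)=0, E(b)=ln 2
        se = spreading_entropy(path3)
        assert se["a"] == pytest.approx(1.0)
        assert se["b"] == pytest.approx(4.0)

    def test_isolated_entropy_zero(self):
        g = Graph([("a", "b")])
        g.add_node("z")
        assert spreading_entropy(g)["z"] == 0.0

    def test_gg_mass_leaves_undamped(self, star4):
        assert gg_mass(star4)["hub"] == pytest.approx(3.0)  # C=0 => S_p = k

    def test_gg_mass_triangle(self, triangle):
        assert all(
            v == pytest.approx(2 * math.exp(-2)) for v in gg_mass(triangle).values()
        )

    def test_gg_mass_toy_node5(self, toy_graph):
        assert gg_mass(toy_graph)["5"] == pytest.approx(4 * math.exp(-2 / 3))

    @pytest.mark.parametrize("seed", range(5))
    def test_gg_mass_bounded_by_degree(self, seed):
        g = random_er(seed)
        sp = gg_mass(g)
        c = local_clustering(g)
        for u in g:
            assert sp[u] <= g.degree(u) + 1e-12
            if c[u] == 0:
                assert sp[u] == pytest.approx(g.degree(u))
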