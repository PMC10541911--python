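"""Per-node scalar indices used as masses or modifiers in gravity centralities.

Everything here returns a :class:`CentralityMap`: a method id, a node→score
mapping whose domain is exactly the node set of the input graph, and the
parameters that produced it.  All indices are deterministic for a fixed graph
and parameter set, and invariant under relabeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Hashable, Iterator, Mapping

import numpy as np

from .graph import Graph

Label = Hashable

__all__ = [
    "CentralityMap",
    "KShellDecomposition",
    "degree",
    "h_index",
    "hv_index",
    "k_shell",
    "k_shell_decomposition",
    "local_clustering",
    "constraint",
    "eigenvector_centrality",
    "spreading_entropy",
    "gg_mass",
]


@dataclass
class CentralityMap:
    """Node → real-valued score for one method, plus the parameters used."""

    method_id: str
    scores: dict[Label, float]
    params: dict[str, object] = field(default_factory=dict)

    def __getitem__(self, node: Label) -> float:
        return self.scores[node]

    def __iter__(self) -> Iterator[Label]:
        return iter(self.scores)

    def __len__(self) -> int:
        return len(self.scores)

    def items(self):
        return self.scores.items()

    def values(self):
        return self.scores.values()

    def ranking(self) -> list[Label]:
        """Nodes by descending score; ties broken by node input order."""
        order = {u: i for i, u in enumerate(self.scores)}
        return sorted(self.scores, key=lambda u: (-self.scores[u], order[u]))

    def write_tsv(self, stream: IO[str]) -> None:
        stream.write(f"# method: {self.method_id}\n")
        for key, value in self.params.items():
            stream.write(f"# {key}: {value}\n")
        stream.write("node\tscore\n")
        for node, score in self.scores.items():
            stream.write(f"{node}\t{score:.6g}\n")


# ---------------------------------------------------------------------------
# Degree-family indices
# ---------------------------------------------------------------------------

def degree(g: Graph) -> CentralityMap:
    """Degree centrality DC(i) = k(i)."""
    return CentralityMap("DC", {u: float(g.degree(u)) for u in g})


def h_index(g: Graph) -> CentralityMap:
    """Largest h such that at least h neighbors of i have degree >= h.

    Isolated nodes get 0; 0 <= H(i) <= k(i) always.
    """
    scores: dict[Label, float] = {}
    for u in g:
        neigh_degs = sorted((g.degree(v) for v in g.neighbors(u)), reverse=True)
        h = 0
        for rank, d in enumerate(neigh_degs, start=1):
            if d >= rank:
                h = rank
            else:
                break
        scores[u] = float(h)
    return CentralityMap("H", scores)


def hv_index(g: Graph) -> CentralityMap:
    """Neighbor-mass index: HV(i) sums the degrees of first-order neighbors
    whose degree is at least H(i), capturing the collective weight of the
    strong part of i's neighborhood rather than just its size."""
    h = h_index(g)
    scores: dict[Label, float] = {}
    for u in g:
        hu = h[u]
        scores[u] = float(
            sum(g.degree(v) for v in g.neighbors(u) if g.degree(v) >= hu)
        )
    return CentralityMap("HV", scores)


# ---------------------------------------------------------------------------
# k-shell decomposition
# ---------------------------------------------------------------------------

@dataclass
class KShellDecomposition:
    """Shell index plus the removal bookkeeping needed by the refined index.

    ``iteration[i]`` (p) is the 1-based pass within i's shell at which i was
    peeled — one pass removes, simultaneously, every node whose residual
    degree is <= the current shell level — and ``passes[k]`` (q) counts the
    passes shell k took.  The refined index k* = k + p/(q+1) orders nodes
    within a shell by how early the peeling reached them; it always stays in
    [k, k+1).
    """

    shell: dict[Label, int]
    iteration: dict[Label, int]
    passes: dict[int, int]

    def improved(self) -> dict[Label, float]:
        return {
            u: self.shell[u] + self.iteration[u] / (self.passes[self.shell[u]] + 1)
            for u in self.shell
        }


def k_shell_decomposition(g: Graph) -> KShellDecomposition:
    residual = {u: g.degree(u) for u in g}
    remaining = set(g.nodes)
    shell: dict[Label, int] = {}
    iteration: dict[Label, int] = {}
    passes: dict[int, int] = {}
    k = 0
    order = g.nodes  # stable wave order
    while remaining:
        current_min = min(residual[u] for u in remaining)
        if current_min > k:
            k = current_min
        pass_no = 0
        while True:
            wave = [u for u in order if u in remaining and residual[u] <= k]
            if not wave:
                break
            pass_no += 1
            for u in wave:
                shell[u] = k
                iteration[u] = pass_no
                remaining.discard(u)
            for u in wave:
                for v in g.neighbors(u):
                    if v in remaining:
                        residual[v] -= 1
        passes[k] = pass_no
    return KShellDecomposition(shell=shell, iteration=iteration, passes=passes)


def k_shell(g: Graph) -> CentralityMap:
    """Classic k-shell (coreness) values from iterative peeling."""
    dec = k_shell_decomposition(g)
    return CentralityMap("KS", {u: float(dec.shell[u]) for u in g})


# ---------------------------------------------------------------------------
# Clustering, structural holes, eigenvector
# ---------------------------------------------------------------------------

def local_clustering(g: Graph) -> CentralityMap:
    """C_i = 2 n_i / (k_i (k_i - 1)); degree <= 1 nodes get 0 by convention."""
    scores: dict[Label, float] = {}
    for u in g:
        nbrs = g.neighbors(u)
        k = len(nbrs)
        if k < 2:
            scores[u] = 0.0
            continue
        links = 0
        for a in range(k):
            for b in range(a + 1, k):
                if g.has_edge(nbrs[a], nbrs[b]):
                    links += 1
        scores[u] = 2.0 * links / (k * (k - 1))
    return CentralityMap("C", scores)


def constraint(g: Graph) -> CentralityMap:
    """Burt's network constraint coefficient.

    c(i) = Σ_{j∈Γ(i)} (p_ij + Σ_{w∈Γ(i)∩Γ(j)} p_iw p_wj)², with
    p_ij = 1/k(i) on an unweighted graph.  Low c(i) marks structural-hole
    spanners: nodes whose ties reach otherwise-unconnected parts of the
    network.  Degree-0 nodes get c = 1 by convention (their gravity score is
    zero regardless).
    """
    inv_deg = {u: (1.0 / g.degree(u) if g.degree(u) else 0.0) for u in g}
    scores: dict[Label, float] = {}
    for i in g:
        nbrs_i = g.neighbors(i)
        if not nbrs_i:
            scores[i] = 1.0
            continue
        p_i = inv_deg[i]
        total = 0.0
        set_i = set(nbrs_i)
        for j in nbrs_i:
            indirect = sum(
                p_i * inv_deg[w] for w in g.neighbors(j) if w in set_i and w != i
            )
            total += (p_i + indirect) ** 2
        scores[i] = total
    return CentralityMap("c", scores)


def eigenvector_centrality(
    g: Graph, tol: float = 1e-10, max_iter: int = 1000
) -> CentralityMap:
    """Leading-eigenvector centrality by power iteration.

    Iterates the shifted operator (I + A) from a uniform positive start — the
    shift leaves the leading eigenvector unchanged but removes the period-2
    oscillation plain iteration exhibits on bipartite graphs.  Scores are
    normalized to unit sum; convergence is successive-iterate max-norm < tol.
    """
    nodes = g.nodes
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    neigh = [np.array([idx[v] for v in g.neighbors(u)], dtype=np.intp) for u in nodes]
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = x.copy()
        for i in range(n):
            if len(neigh[i]):
                x_new[i] += x[neigh[i]].sum()
        x_new /= x_new.sum()
        if np.max(np.abs(x_new - x)) < tol:
            return CentralityMap(
                "EC",
                {u: float(x_new[idx[u]]) for u in nodes},
                params={"tol": tol, "max_iter": max_iter},
            )
        x = x_new
    raise RuntimeError(
        f"eigenvector centrality failed to converge in {max_iter} iterations "
        f"on graph with N={n}"
    )


# ---------------------------------------------------------------------------
# Entropy and clustering-damped masses
# ---------------------------------------------------------------------------

def spreading_entropy(g: Graph) -> CentralityMap:
    """Entropy-weighted degree mass SE(i) = e^{E(i)} k(i).

    I(j) = k(j) / Σ_{w∈Γ(j)} k(w) is each node's share of its own
    neighborhood's degree, and E(i) = −Σ_{j∈Γ(i)} I(j) ln I(j) aggregates the
    neighbors' shares.  I is evaluated globally at each neighbor (not
    renormalized within Γ(i)).  Isolated nodes score 0.
    """
    share: dict[Label, float] = {}
    for u in g:
        denom = sum(g.degree(v) for v in g.neighbors(u))
        share[u] = g.degree(u) / denom if denom else 0.0
    scores: dict[Label, float] = {}
    for u in g:
        if g.degree(u) == 0:
            scores[u] = 0.0
            continue
        e = -sum(share[j] * math.log(share[j]) for j in g.neighbors(u) if share[j] > 0)
        scores[u] = math.exp(e) * g.degree(u)
    return CentralityMap("SE", scores)


def gg_mass(g: Graph, alpha: float = 2.0) -> CentralityMap:
    """Clustering-damped degree mass S_p(i) = e^{−α C_i} k(i).

    Dense local neighborhoods (high C_i) waste spreading attempts on already
    reached nodes, so the mass shrinks with clustering; alpha controls the
    damping strength (default 2).
    """
    c = local_clustering(g)
    scores = {u: math.exp(-alpha * c[u]) * g.degree(u) for u in g}
    return CentralityMap("S_p", scores, params={"alpha": alpha})
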