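"""Discrete-time SIR Monte-Carlo simulation of spreading capacity.

The spreading capacity F(i) of a node is the mean final fraction of recovered
nodes when i is the single initially infected node.  It is the ground truth
against which centrality rankings are scored: a good influence measure orders
nodes the way F does.

Dynamics are synchronous: at each step every infected node independently
tries to infect each currently susceptible neighbor with probability beta,
then recovers with probability lam (lam = 1 means every infected node gets
exactly one round of infection attempts).  A node infected at step t starts
transmitting at step t+1.  The process stops when no infected nodes remain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable

import numpy as np

from .graph import Graph, degree_moments

Label = Hashable

__all__ = ["SIRConfig", "SIRResult", "epidemic_threshold", "sir_run", "spreading_capacity"]


@dataclass
class SIRConfig:
    """Infection probability, recovery probability, replicate count, RNG seed."""

    beta: float
    lam: float = 1.0
    runs: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass
class SIRResult:
    """Per-node mean spreading capacity F(i) = E[N_r]/N and run metadata."""

    capacity: dict[Label, float]
    runs: int
    beta: float
    lam: float
    mean_steps: float
    max_steps: int

    def ranking(self) -> list[Label]:
        order = {u: i for i, u in enumerate(self.capacity)}
        return sorted(self.capacity, key=lambda u: (-self.capacity[u], order[u]))


def epidemic_threshold(g: Graph) -> float:
    """Degree-moment estimate of the SIR threshold, β_c ≈ ⟨k⟩/(⟨k²⟩−⟨k⟩)."""
    k1, k2 = degree_moments(g)
    if k2 <= k1:
        raise ValueError("epidemic threshold undefined: <k^2> <= <k>")
    return k1 / (k2 - k1)


def sir_run(
    g: Graph,
    seed_node: Label,
    beta: float,
    lam: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """One realization from a single seed; returns (recovered count, steps)."""
    if seed_node not in g:
        raise KeyError(f"unknown seed node {seed_node!r}")
    susceptible = set(g.nodes)
    susceptible.discard(seed_node)
    infected = [seed_node]
    recovered: set[Label] = set()
    steps = 0
    while infected:
        steps += 1
        newly_infected: list[Label] = []
        for u in infected:
            for v in g.neighbors(u):
                if v in susceptible and rng.random() < beta:
                    susceptible.discard(v)
                    newly_infected.append(v)
        still_infected: list[Label] = []
        for u in infected:
            if lam >= 1.0 or rng.random() < lam:
                recovered.add(u)
            else:
                still_infected.append(u)
        infected = still_infected + newly_infected
    return len(recovered), steps


def spreading_capacity(g: Graph, cfg: SIRConfig) -> SIRResult:
    """Mean F(i) over ``cfg.runs`` replicates for every node as seed.

    Each (node, replicate) pair gets its own RNG substream derived from
    (rng_seed, node index, replicate index), so results do not depend on
    iteration order and are reproducible replicate-by-replicate.
    """
    n = g.number_of_nodes
    capacity: dict[Label, float] = {}
    total_steps = 0
    max_steps = 0
    for node_index, node in enumerate(g.nodes):
        acc = 0
        for rep in range(cfg.runs):
            rng = np.random.default_rng(
                np.random.SeedSequence(cfg.rng_seed, spawn_key=(node_index, rep))
            )
            n_r, steps = sir_run(g, node, cfg.beta, cfg.lam, rng)
            acc += n_r
            total_steps += steps
            max_steps = max(max_steps, steps)
        capacity[node] = acc / (cfg.runs * n)
    return SIRResult(
        capacity=capacity,
        runs=cfg.runs,
        beta=cfg.beta,
        lam=cfg.lam,
        mean_steps=total_steps / (n * cfg.runs),
        max_steps=max_steps,
    )
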