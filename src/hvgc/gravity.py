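"""Truncated gravity-sum centralities: HVGC and the ten baseline models.

Every model is an instance of one template: the score of node i accumulates
coupling(i,j) · mass(i) · mass(j) / d(i,j)² over all nodes j within a
truncation radius R of i (shortest-path distance).  The models differ only in
which per-node index plays the mass and in the coupling factor:

=======  =============================================  =====================
model    mass                                           coupling
=======  =============================================  =====================
G        k-shell (both sides, fixed neighborhood d<=3)  1
G+       neighbor sum of G                              —
IGC      k-shell(i) · degree(j)                         1
IGC+     neighbor sum of IGC                            —
LGM      degree                                         1
GGC      e^{−αC_i} k(i)  (clustering-damped degree)     1
KSGC     degree                                         e^{(ks_i−ks_j)/(ks_max−ks_min)}
DKGM     k(i) + k*(i)  (degree + refined k-shell)       1
MCGM     k/k_max + α ks/ks_max + x/x_max                1
SEGM     e^{E(i)} k(i)  (entropy-weighted degree)       1
HVGC     HV (H-index-filtered neighbor degree mass)     e^{−c(i)}
=======  =============================================  =====================

HVGC couples the HV mass with the focal node's Burt constraint c(i): bridges
between communities have low constraint, so e^{−c(i)} boosts exactly the
nodes whose k-shell and degree understate their reach.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from statistics import median
from typing import Callable, Hashable, Mapping

from . import indices as _ix
from .graph import Graph, mean_distance, shortest_distances

logger = logging.getLogger(__name__)

Label = Hashable

MODEL_IDS = (
    "G",
    "G+",
    "IGC",
    "IGC+",
    "LGM",
    "GGC",
    "KSGC",
    "DKGM",
    "MCGM",
    "SEGM",
    "HVGC",
)

__all__ = [
    "MODEL_IDS",
    "GravityConfig",
    "optimal_radius",
    "gravity_sum",
    "neighbor_sum",
    "hvgc",
    "baseline",
    "gravity_centrality",
    "mcgm_alpha",
]


@dataclass
class GravityConfig:
    """Model choice plus truncation radius ("auto" resolves to ~half the
    network's mean distance before any scoring)."""

    model_id: str = "HVGC"
    radius: int | str = "auto"
    params: dict[str, float] = field(default_factory=dict)

    def resolve_radius(self, g: Graph) -> int:
        if self.radius == "auto":
            return optimal_radius(g)
        r = int(self.radius)
        if r < 1:
            raise ValueError(f"truncation radius must be >= 1, got {r}")
        return r


def optimal_radius(g: Graph) -> int:
    """Heuristic truncation radius R* ≈ ⟨d⟩/2, rounded half-up, floored at 1."""
    return max(1, math.floor(mean_distance(g) / 2.0 + 0.5))


# ---------------------------------------------------------------------------
# The shared gravity template
# ---------------------------------------------------------------------------

def gravity_sum(
    g: Graph,
    mass_i: Mapping[Label, float],
    mass_j: Mapping[Label, float],
    radius: int,
    coupling: Callable[[Label, Label], float] | None = None,
) -> dict[Label, float]:
    """score(i) = Σ_{j≠i, 1<=d(i,j)<=R} coupling(i,j)·mass_i(i)·mass_j(j)/d²(i,j).

    Unreachable pairs contribute nothing, so disconnected graphs are handled
    without special cases.
    """
    if radius < 1:
        raise ValueError(f"truncation radius must be >= 1, got {radius}")
    scores: dict[Label, float] = {}
    for i in g:
        mi = mass_i[i]
        total = 0.0
        for j, d in shortest_distances(g, i, radius=radius).items():
            if d == 0:
                continue
            c = coupling(i, j) if coupling is not None else 1.0
            total += c * mi * mass_j[j] / (d * d)
        scores[i] = total
    return scores


def neighbor_sum(g: Graph, base: Mapping[Label, float]) -> dict[Label, float]:
    """First-order neighborhood aggregation used by the '+' variants."""
    return {i: float(sum(base[j] for j in g.neighbors(i))) for i in g}


# ---------------------------------------------------------------------------
# HVGC
# ---------------------------------------------------------------------------

def hvgc(g: Graph, radius: int | str = "auto") -> _ix.CentralityMap:
    """H-index-based gravity centrality.

    Mass is the HV index on both sides; the whole sum for node i is damped by
    e^{−c(i)} where c(i) is i's Burt constraint — the focal node's coupling
    only, so the measure is asymmetric by construction.
    """
    r = GravityConfig("HVGC", radius).resolve_radius(g)
    hv = _ix.hv_index(g)
    con = _ix.constraint(g)
    damp = {i: math.exp(-con[i]) for i in g}
    scores = gravity_sum(g, hv.scores, hv.scores, r, coupling=lambda i, j: damp[i])
    return _ix.CentralityMap("HVGC", scores, params={"radius": r})


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def mcgm_alpha(g: Graph, x: Mapping[Label, float] | None = None) -> float:
    """Weight on the k-shell term: α = max(k_mid/k_max, x_mid/x_max) / (ks_mid/ks_max).

    Medians use the midpoint convention for even N.
    """
    if x is None:
        x = _ix.eigenvector_centrality(g).scores
    degs = [g.degree(u) for u in g]
    ks = list(_ix.k_shell(g).values())
    xs = [x[u] for u in g]
    k_term = median(degs) / max(degs)
    x_term = median(xs) / max(xs)
    ks_term = median(ks) / max(ks)
    if ks_term == 0:
        raise ValueError(
            "MCGM alpha undefined: median k-shell is 0 "
            "(at least half of the nodes are isolated)"
        )
    return max(k_term, x_term) / ks_term


def _baseline_g(g: Graph) -> dict[Label, float]:
    ks = _ix.k_shell(g).scores
    return gravity_sum(g, ks, ks, radius=3)


def _baseline_igc(g: Graph, radius: int) -> dict[Label, float]:
    ks = _ix.k_shell(g).scores
    deg = _ix.degree(g).scores
    return gravity_sum(g, ks, deg, radius=radius)


def baseline(model_id: str, g: Graph, radius: int | str = "auto") -> _ix.CentralityMap:
    """Dispatch one of the ten baseline gravity centralities.

    G fixes its neighborhood at distance <= 3 regardless of the configured
    radius; the '+' variants post-process their base model by a first-order
    neighbor sum.
    """
    if model_id not in MODEL_IDS or model_id == "HVGC":
        raise ValueError(f"unknown baseline model {model_id!r}")
    params: dict[str, object] = {}
    if model_id in ("G", "G+"):
        r = 3  # fixed neighborhood, by definition
    else:
        r = GravityConfig(model_id, radius).resolve_radius(g)
    params["radius"] = r

    if model_id == "G":
        scores = _baseline_g(g)
    elif model_id == "G+":
        scores = neighbor_sum(g, _baseline_g(g))
    elif model_id == "IGC":
        scores = _baseline_igc(g, r)
    elif model_id == "IGC+":
        scores = neighbor_sum(g, _baseline_igc(g, r))
    elif model_id == "LGM":
        deg = _ix.degree(g).scores
        scores = gravity_sum(g, deg, deg, r)
    elif model_id == "GGC":
        sp = _ix.gg_mass(g, alpha=2.0).scores
        params["alpha"] = 2.0
        scores = gravity_sum(g, sp, sp, r)
    elif model_id == "KSGC":
        deg = _ix.degree(g).scores
        ks = _ix.k_shell(g).scores
        ks_min, ks_max = min(ks.values()), max(ks.values())
        if ks_max == ks_min:
            logger.info("KSGC: single k-shell value, coupling fixed at 1")
            coupling = None
        else:
            spread = ks_max - ks_min

            def coupling(i: Label, j: Label) -> float:
                return math.exp((ks[i] - ks[j]) / spread)

        scores = gravity_sum(g, deg, deg, r, coupling=coupling)
    elif model_id == "DKGM":
        dec = _ix.k_shell_decomposition(g)
        ks_star = dec.improved()
        dk = {u: g.degree(u) + ks_star[u] for u in g}
        scores = gravity_sum(g, dk, dk, r)
    elif model_id == "MCGM":
        x = _ix.eigenvector_centrality(g).scores
        alpha = mcgm_alpha(g, x)
        params["alpha"] = alpha
        deg = _ix.degree(g).scores
        ks = _ix.k_shell(g).scores
        k_max = max(deg.values())
        ks_max = max(ks.values())
        x_max = max(x.values())
        mass = {
            u: deg[u] / k_max + alpha * ks[u] / ks_max + x[u] / x_max for u in g
        }
        scores = gravity_sum(g, mass, mass, r)
    elif model_id == "SEGM":
        se = _ix.spreading_entropy(g).scores
        scores = gravity_sum(g, se, se, r)
    else:  # pragma: no cover - guarded above
        raise ValueError(model_id)
    return _ix.CentralityMap(model_id, scores, params=params)


def gravity_centrality(
    g: Graph, model_id: str, radius: int | str = "auto"
) -> _ix.CentralityMap:
    """Uniform entry point over HVGC and all baselines."""
    if model_id == "HVGC":
        return hvgc(g, radius)
    return baseline(model_id, g, radius)
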