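"""Ranking-quality measures: Kendall tau, top-k Jaccard, monotonicity.

Two tau variants are exposed.  The default counts a pair as concordant or
discordant only when both lists order it strictly, divides by the full pair
count N(N-1)/2 (doubled in the numerator convention), and simply drops tied
pairs from the numerator — ties lower |tau|.  The tau-b variant (scipy)
additionally corrects the denominator for ties and is reported alongside for
comparison with other tools, since tie-heavy indices such as degree or
k-shell make the two differ materially.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps

Label = Hashable

__all__ = [
    "RankingComparison",
    "kendall_tau",
    "jaccard_top_k",
    "monotonicity",
    "top_k_nodes",
    "compare_rankings",
]


def _as_arrays(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 2:
        raise ValueError("need at least two paired observations")
    return xa, ya


def kendall_tau(x: Sequence[float], y: Sequence[float], variant: str = "literal") -> float:
    """Rank correlation between two paired score lists.

    variant="literal": tau = 2(n+ − n−)/(N(N−1)) with tied pairs contributing
    to neither count.  variant="b": scipy's tau-b (tie-corrected denominator).
    """
    xa, ya = _as_arrays(x, y)
    if variant == "b":
        return float(_sps.kendalltau(xa, ya, variant="b").statistic)
    if variant != "literal":
        raise ValueError(f"unknown tau variant {variant!r}")
    n = xa.size
    dx = np.sign(xa[:, None] - xa[None, :])
    dy = np.sign(ya[:, None] - ya[None, :])
    prod = dx * dy
    iu = np.triu_indices(n, k=1)
    n_plus = int((prod[iu] > 0).sum())
    n_minus = int((prod[iu] < 0).sum())
    return 2.0 * (n_plus - n_minus) / (n * (n - 1))


def top_k_nodes(
    scores: Mapping[Label, float], k: int, include_boundary_ties: bool = False
) -> set[Label]:
    """Top-k node set by descending score; ties at the k boundary broken by
    node input order, or all boundary-tied nodes included when requested."""
    n = len(scores)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    order = {u: i for i, u in enumerate(scores)}
    ranked = sorted(scores, key=lambda u: (-scores[u], order[u]))
    top = ranked[:k]
    if include_boundary_ties:
        cutoff = scores[top[-1]]
        top = [u for u in ranked if scores[u] > cutoff] + [
            u for u in ranked if scores[u] == cutoff
        ]
    return set(top)


def jaccard_top_k(
    x_scores: Mapping[Label, float],
    y_scores: Mapping[Label, float],
    k: int,
    include_boundary_ties: bool = False,
) -> float:
    """|X ∩ Y| / |X ∪ Y| for the two top-k node sets."""
    if set(x_scores) != set(y_scores):
        raise ValueError("score maps must share an identical node domain")
    xs = top_k_nodes(x_scores, k, include_boundary_ties)
    ys = top_k_nodes(y_scores, k, include_boundary_ties)
    return len(xs & ys) / len(xs | ys)


def monotonicity(values: Sequence[float]) -> float:
    """Resolution of a ranking: M = [1 − Σ_c N_c(N_c−1) / (N(N−1))]².

    1 when all values are distinct, 0 when all coincide.  Depends only on the
    multiset of tie-class sizes (classes formed by exact value equality).
    """
    vals = list(values)
    n = len(vals)
    if n < 2:
        raise ValueError("monotonicity needs at least two values")
    tie_sum = sum(c * (c - 1) for c in Counter(vals).values())
    return (1.0 - tie_sum / (n * (n - 1))) ** 2


@dataclass
class RankingComparison:
    """Summary of one centrality against the SIR ground truth."""

    method_id: str
    tau: float
    tau_b: float
    monotonicity: float
    jaccard_curve: dict[int, float] = field(default_factory=dict)


def compare_rankings(
    method_id: str,
    scores: Mapping[Label, float],
    reference: Mapping[Label, float],
    jaccard_ks: Sequence[int] = (),
) -> RankingComparison:
    """Tau (both variants), monotonicity of ``scores``, and a top-k Jaccard
    curve against the reference ranking, aligned on the reference node order."""
    if set(scores) != set(reference):
        raise ValueError("score maps must share an identical node domain")
    nodes = list(reference)
    x = [scores[u] for u in nodes]
    y = [reference[u] for u in nodes]
    return RankingComparison(
        method_id=method_id,
        tau=kendall_tau(x, y),
        tau_b=kendall_tau(x, y, variant="b"),
        monotonicity=monotonicity(x),
        jaccard_curve={k: jaccard_top_k(scores, reference, k) for k in jaccard_ks},
    )
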