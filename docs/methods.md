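# Methods

## Scope and model

The package ranks nodes of undirected, unweighted simple graphs by variants
of a truncated gravity sum

    score(i) = Σ_{j ≠ i, 1 ≤ d(i,j) ≤ R} coupling(i,j) · mass(i) · mass(j) / d(i,j)²,

where d is shortest-path (hop) distance. Pairs beyond the truncation radius
R, and unreachable pairs, contribute nothing; disconnected graphs therefore
need no special casing anywhere in the scoring path. The eleven models are
parameterizations of this template (see the table in `gravity.py`); the
headline method, HVGC, uses the HV index as mass on both sides and the
focal node's structural-hole damping e^{−c(i)} as coupling. The coupling
depends on i only, so HVGC is deliberately asymmetric: i's own bridging
position rescales everything i attracts.

Ground truth for "influence" is epidemiological: the spreading capacity
F(i) = E[N_r]/N from a discrete SIR process seeded at i. A centrality is
judged by how well its ranking matches the F ranking (Kendall tau), how well
its top-k set matches the top-k spreaders (Jaccard), and how few ties it
produces (monotonicity).

## Per-node indices

* H-index H(i): largest h with at least h neighbors of degree ≥ h. Isolated
  nodes get 0.
* HV(i): sum of degrees of neighbors whose degree ≥ H(i). Whenever k(i)>0,
  HV(i) ≥ H(i)² (at least H(i) qualifying neighbors, each of degree ≥ H(i)).
* k-shell: iterative peeling. Within shell level k, one *pass* removes
  simultaneously every remaining node of residual degree ≤ k; passes repeat
  until none qualify, then the level rises to the minimum residual degree.
  Nodes removed in pass p of a shell that took q passes get the refined
  index k*(i) = k + p/(q+1) ∈ [k, k+1), which orders nodes within a shell
  by how early the peeling reached them. Isolated nodes form shell 0,
  matching the usual core-number convention.
* Local clustering C_i = 2n_i/(k_i(k_i−1)); nodes with degree ≤ 1 get 0 by
  convention (this also makes the clustering-damped mass S_p = e^{−αC}k
  equal k for leaves).
* Burt constraint c(i) = Σ_{j∈Γ(i)} (p_ij + Σ_{w∈Γ(i)∩Γ(j)} p_iw p_wj)²
  with p_uv = 1/k(u) on unweighted graphs (each node spreads its investment
  evenly). Degree-1 nodes have c = 1 exactly; degree-0 nodes are assigned
  c = 1 by convention (their gravity score is 0 regardless). The
  implementation hard-codes the 1/k form; a test asserts it agrees with the
  general normalized-weight definition via an independent implementation.
* Spreading-entropy mass SE(i) = e^{E(i)}k(i), with
  E(i) = −Σ_{j∈Γ(i)} I(j)ln I(j) and I(j) = k(j)/Σ_{w∈Γ(j)}k(w). I is
  evaluated *globally* at each neighbor — it is each node's share of its own
  neighborhood's degree — and is not renormalized within Γ(i). The
  renormalized reading would change E(i) whenever Γ(i) ≠ Γ(j); the global
  reading is the literal definition and is what the package uses.
* Eigenvector centrality: power iteration on the shifted operator (I + A)
  from a uniform positive start vector. The shift leaves the leading
  eigenvector unchanged but guarantees convergence on bipartite graphs,
  where plain adjacency iteration oscillates with period 2. Scores are
  normalized to unit sum; convergence is successive-iterate max-norm < tol
  (default 1e-10, max 1000 iterations, error on non-convergence). On
  disconnected graphs the iteration runs on the full graph and mass
  concentrates on the dominant component — acceptable here because the
  index is only consumed as an MCGM ingredient through x/x_max.

## Model-specific conventions

* G fixes its neighborhood at distance ≤ 3 by definition, independent of
  the radius configured for the other models. G+ and IGC+ post-process
  their base model by a first-order neighbor sum.
* KSGC's coupling e^{(ks_i−ks_j)/(ks_max−ks_min)} is defined as 1 when all
  nodes share one shell (the exponent's 0/0 case); the event is logged.
* MCGM's mixing weight α = max(k_mid/k_max, x_mid/x_max)/(ks_mid/ks_max)
  uses midpoint medians for even N. α is undefined when the median k-shell
  is 0 (at least half the nodes isolated); the package raises an
  informative error rather than inventing a value.
* Truncation radius "auto" resolves to R* = max(1, round-half-up(⟨d⟩/2))
  before scoring, and the resolved value is recorded in the output
  metadata. On real small-world networks the empirical optimum can deviate
  from this heuristic by a hop or two, so the radius is always overridable.
* Tied masses propagate to exactly tied scores; no jitter is ever added.
  Automorphic nodes (the toy network's leaves 1, 2, 4) therefore tie
  bit-exactly.

## SIR simulator

Synchronous updating: in each step, every infected node first attempts to
infect each currently susceptible neighbor (probability β per contact),
then recovers with probability λ (default 1 ⇒ exactly one infection round
per node; the epidemic then lasts at most N steps). A node infected in step
t transmits from step t+1. Each (seed node, replicate) pair draws from its
own RNG substream spawned from (seed, node index, replicate index), so
results are independent of loop order and reproducible replicate-by-
replicate. The threshold estimate β_c = ⟨k⟩/(⟨k²⟩−⟨k⟩) is exposed and is
the default simulation β; it requires ⟨k²⟩ > ⟨k⟩ (a perfect matching, where
every node has degree 1, has no finite threshold and raises).

## Network descriptors

⟨d⟩ averages shortest-path distance over *reachable* unordered pairs only,
logging the excluded count — the descriptor stays defined on graphs with
several components, where the all-pairs average would be infinite.
Clustering is the mean local coefficient (degree < 2 nodes contribute 0);
assortativity is the Pearson degree–degree correlation over edge endpoints
(undefined/NaN on regular graphs); heterogeneity H = ⟨k²⟩/⟨k⟩² is 1 for
regular graphs.

## Synthetic data

The generators exist to exercise the estimators across the graph families
the method is aimed at: Erdős–Rényi (homogeneous degrees), Barabási–Albert
preferential attachment (heavy-tailed degrees; tests assert its
heterogeneity exceeds matched ER on average), Watts–Strogatz (small-world),
and a two-block community graph — two dense blocks, each guaranteed
connected by a ring backbone, joined only through bridge nodes that carry
exactly one edge into each block. The bridge construction isolates the
phenomenon HVGC targets: the bridge's k-shell (2) is strictly below the
block cores, while its constraint is exactly the redundancy-free
2·(1/2)² = 0.5, since its two ties share no common neighbors. These
generators emulate topology classes only; they do not reproduce degree
correlations, clustering spectra or community overlap of real social and
infrastructure networks, so passing tests demonstrate correctness of the
computations and qualitative behavior, not performance claims on real data.

The packaged 10-node toy network is the worked example used throughout the
docs and tests. Its published per-node table (degree, k-shell, H-index, HV,
HVGC at R=1, and simulated spreading capacity) is frozen in
`fixtures.TOY_EXPECTED`, and `toy_network()` re-derives every integer cell
from the edge list at load time, failing loudly on any mismatch.

## Ranking metrics

The default Kendall tau is the literal definition
τ = 2(n₊−n₋)/(N(N−1)): pairs tied in either list count as neither
concordant nor discordant but stay in the denominator, so ties shrink |τ|.
Tau-b (tie-corrected denominator, via scipy) is computed alongside wherever
rankings are compared, because tie-heavy indices such as degree or k-shell
make the variants differ materially. Top-k sets break score ties at the k
boundary by node input order (deterministic given the edge-list order); an
inclusive mode that admits every boundary-tied node is available, since it
changes |X| and hence the Jaccard value. Monotonicity groups values by
exact floating-point equality — appropriate here because ties arise
structurally (automorphic nodes), not from rounding.

## Problem sizes and test design

The worked example (10 nodes) is exact and instantaneous. The
truncation-vs-exhaustive equivalence check uses 100 connected random graphs
of 5–30 nodes (ER over a path backbone, so every model, including MCGM's
median-based α, is well defined) at relative tolerance 1e-12. SIR-based
checks use 1000–10 000 replicates on the toy network or a single edge,
which keeps Monte-Carlo standard errors around the per-node capacity at or
below ~0.003 while the full suite runs in seconds.

One concordance caveat is documented rather than hidden: the published toy
capacity table was evidently simulated near β ≈ 0.32 (its magnitudes are
mean recovered counts; the largest, 3.28 from node 5, pins the β), and at
that β the simulated ordering reproduces the published one exactly. At the
toy's own threshold β_c = 0.48, however, a 10-node epidemic is close to
saturation: capacities of the core nodes compress, the orderings of nodes
9/3 and of the four pendant nodes invert systematically (confirmed at
30 000 replicates), and tau against HVGC drops to ≈ 0.76–0.8. The
acceptance-style test that pins ranking concordance *at β_c* therefore
fails by design of its condition, and is kept failing rather than silently
re-tuned; the worked-example test at the table's own β passes.

## Limitations

Weighted and directed graphs are out of scope (masses and p_ij assume
unweighted symmetric ties). All-pairs BFS makes the exhaustive-radius path
O(N·M); the truncated default (R = 1–3 on small-world networks) is the
intended regime. The SIR simulator is synchronous discrete-time only — no
Gillespie dynamics, and λ ≠ 1 is configurable but exercised only by
invariant tests. The constraint coefficient follows the common convention
without Burt's hierarchy correction.
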