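"""Whole-network descriptors for an edge list.

Parses an edge list from text, prints the descriptor bundle (size, mean
degree and distance, clustering, assortativity, degree heterogeneity and the
SIR epidemic threshold), and shows the truncation radius heuristic.
"""

import io

from hvgc import network_stats, optimal_radius, read_edge_list

edge_text = """\
# small collaboration-style graph
a b
a c
b c
c d
d e
d f
e f
f g
"""

g = read_edge_list(io.StringIO(edge_text))
stats = network_stats(g)

for key, value in stats.as_dict().items():
    print(f"{key:>7}: {value:.4f}" if isinstance(value, float) else f"{key:>7}: {value}")
print(f"     R*: {optimal_radius(g)}  (gravity truncation radius, ~ half the mean distance)")
print()
print("H = <k^2>/<k>^2 is 1 for regular graphs and grows with degree spread;")
print("beta_c = <k>/(<k^2>-<k>) is the SIR threshold used to pick simulation betas.")
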