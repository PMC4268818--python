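"""Classical Hadamard conjugation, binary-symmetric model, five taxa.

Builds a random five-leaf tree with random edge rates, computes the exact
site-pattern distribution, and inverts it back to the edge-length
spectrum — demonstrating that pattern probabilities and edge rates are in
exact one-to-one correspondence.
"""

import numpy as np

from groupphylo import (
    edges_from_newick,
    invert_tensor,
    make_fixture,
    make_group,
    phylo_tensor,
)

group = make_group("binary")
newick, rates = make_fixture(n=5, group=group, seed=42)
print(f"tree: {newick}")

edges = edges_from_newick(newick, 5)
P = phylo_tensor(group, edges, rates)
print(f"pattern tensor: {P.values.size} probabilities summing to {P.values.sum():.6f}")

spectrum = invert_tensor(P)
print(f"{'edge subset':>14} {'true rate':>10} {'recovered':>12}")
for e in sorted(edges.edge_subsets, key=lambda s: (len(s), sorted(s))):
    true = rates.rates[e][(1,)]
    rec = spectrum.get(e, (1,))
    print(f"{str(sorted(e)):>14} {true:>10.6f} {rec:>12.9f}")
print(f"lambda (total rate): true {rates.total_rate:.6f}, "
      f"recovered {spectrum.lambda_total:.9f}")

worst = max(
    abs(spectrum.get(e, (1,)) - rates.rates[e][(1,)]) for e in edges.edge_subsets
)
print(f"worst rate error: {worst:.2e}")
print("-> the inversion reproduces every per-edge substitution rate to "
      "machine precision: the conjugation is exact, not an estimate.")
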