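"""Seeded fixture generation and multinomial site-pattern simulation.

The fixture generator emulates the inputs of the method itself: a random
binary tree topology on ``n`` labelled leaves (uniform sequential edge
attachment) and independent per-edge, per-channel rates drawn uniformly
on ``(0, max_rate]``.  Site patterns are sampled i.i.d. from the model
tensor — a single multinomial draw — so simulated data is exactly
group-based and stationary by construction; real alignments are not, and
empirical spectra recovered from them may carry negative components.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError
from .groups import AbelianGroup
from .io import PatternTable
from .model import PhyloTensor, RateSpec, edges_from_newick

__all__ = ["random_tree_newick", "make_fixture", "simulate_patterns"]

#: Default per-channel rate ceiling: a moderate expected number of
#: substitutions per edge channel, far from log saturation at the tensor
#: sizes this package targets.
DEFAULT_MAX_RATE = 0.2


def random_tree_newick(n: int, rng: np.random.Generator) -> str:
    """Uniform-random binary tree on leaves ``1..n`` by sequential
    attachment: each new leaf subdivides a uniformly chosen edge."""
    if n < 2:
        raise DomainError("need n >= 2 leaves")
    next_node = n + 1
    # adjacency over node ids; leaves are 1..n
    adj: dict[int, set[int]] = {1: {2}, 2: {1}}
    edges = [(1, 2)]
    for leaf in range(3, n + 1):
        a, b = edges[int(rng.integers(len(edges)))]
        mid = next_node
        next_node += 1
        adj[a].discard(b)
        adj[b].discard(a)
        adj[a].add(mid)
        adj[b].add(mid)
        adj[mid] = {a, b, leaf}
        adj[leaf] = {mid}
        edges.remove((a, b))
        edges.extend([(a, mid), (mid, b), (mid, leaf)])

    def newick(node: int, parent: int | None) -> str:
        children = [c for c in adj[node] if c != parent]
        if not children:
            return str(node)
        return "(" + ",".join(newick(c, node) for c in children) + ")"

    if n == 2:
        return "(1,2);"
    # write rooted at the internal neighbor of leaf n (leaf n appears as
    # a child), which is the rooting convention of the edge labelling
    anchor = next(iter(adj[n]))
    return newick(anchor, None) + ";"


def make_fixture(
    n: int,
    group: AbelianGroup,
    seed: int | np.random.Generator,
    max_rate: float = DEFAULT_MAX_RATE,
) -> tuple[str, RateSpec]:
    """Seeded random (Newick tree, RateSpec) pair.

    Every edge subset of the tree gets an independent rate in
    ``(0, max_rate]`` for each non-identity group element.  Reproducible:
    a fixed seed yields an identical fixture.
    """
    if n < 3:
        raise DomainError("fixtures need n >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    newick = random_tree_newick(n, rng)
    edges = edges_from_newick(newick, n)
    rates = {
        e: {
            sigma: float(max_rate * (1.0 - rng.random()))  # (0, max_rate]
            for sigma in group.non_identity()
        }
        for e in edges.edge_subsets
    }
    return newick, RateSpec(group, rates)


def simulate_patterns(
    P: PhyloTensor, sites: int, seed: int | np.random.Generator
) -> PatternTable:
    """Draw ``sites`` i.i.d. site patterns from a probability tensor.

    One multinomial draw with the tensor entries as cell probabilities;
    deterministic given the seed.  ``sites=0`` yields an all-zero table.
    """
    if sites < 0:
        raise DomainError("sites must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = P.real_probabilities().reshape(-1)
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum()
    counts = rng.multinomial(sites, probs) if sites else np.zeros(probs.size, int)
    return PatternTable(P.group, P.n, counts.astype(float), kind="count")
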