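"""Rate matrices, tree edge labellings and phylogenetic pattern tensors.

A phylogenetic tensor is the ``d^n`` array of joint probabilities of
observing each assignment of group elements to the ``n`` leaves.  Rooting
the tree at taxon ``n`` and labelling every edge by the subset
``e subset {1..n-1}`` of leaves whose path to taxon ``n`` crosses it, the
tensor factorizes as a single exponential of commuting edge generators
acting on the star-tree distribution:

    P = exp(-lambda) * exp( sum_{e, sigma} alpha_e^sigma K_sigma^(e) ) . delta^{n-1} pi

with uniform root distribution ``pi = (1/d, ..., 1/d)``.  Because the
subsets need not be tree-compatible, the same formula defines a valid
distribution for arbitrary split systems ("network mode").

This module evaluates the exponential in the spectral (character) basis,
where every ``K_sigma^(e)`` is diagonal, and also provides a classical
pruning implementation (:func:`oracle_tree_tensor`) that never touches the
spectral machinery and serves as an independent oracle on trees.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

from .errors import DomainError, InputFormatError
from .groups import AbelianGroup, regular_representation

__all__ = [
    "RateSpec",
    "TreeEdges",
    "PhyloTensor",
    "rate_matrix",
    "edges_from_newick",
    "star_tensor",
    "spectral_star_values",
    "phylo_tensor",
    "apply_branching",
    "oracle_tree_tensor",
]

Element = tuple[int, ...]
Subset = frozenset[int]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class RateSpec:
    """Per-edge-subset, per-group-element substitution rates.

    ``rates[e][sigma]`` is the rate ``alpha_e^sigma >= 0`` of the
    substitution channel ``sigma`` (a non-identity residue tuple) on the
    edge labelled by the nonempty subset ``e`` of ``{1..n-1}``.
    """

    group: AbelianGroup
    rates: dict[Subset, dict[Element, float]] = field(default_factory=dict)

    def __post_init__(self):
        clean: dict[Subset, dict[Element, float]] = {}
        for e, chan in self.rates.items():
            e = frozenset(int(i) for i in e)
            if not e:
                raise DomainError("edge subsets must be nonempty")
            if any(i < 1 for i in e):
                raise DomainError(f"edge subset {sorted(e)} has non-positive leaf ids")
            if e in clean:
                raise DomainError(f"duplicate edge subset {sorted(e)}")
            clean[e] = {}
            for sigma, a in chan.items():
                sigma = self.group._check(sigma)
                if sigma == self.group.identity:
                    raise DomainError("rates may not be keyed by the identity element")
                a = float(a)
                if not np.isfinite(a) or a < 0:
                    raise DomainError(f"rate {a} for {sigma} on {sorted(e)} invalid")
                clean[e][sigma] = a
        self.rates = clean

    @property
    def total_rate(self) -> float:
        """``lambda``: the sum of all edge-channel rates."""
        return float(sum(a for chan in self.rates.values() for a in chan.values()))

    def max_leaf(self) -> int:
        return max((max(e) for e in self.rates), default=0)

    def items(self):
        return self.rates.items()

    # -- JSON round trip ----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "group": list(self.group.factor_orders),
            "edges": [
                {
                    "subset": sorted(e),
                    "rates": {
                        ",".join(map(str, sigma)): a for sigma, a in chan.items()
                    },
                }
                for e, chan in sorted(self.rates.items(), key=lambda kv: sorted(kv[0]))
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str, group: AbelianGroup | None = None) -> "RateSpec":
        from .groups import make_group

        try:
            payload = json.loads(text)
            if group is None:
                group = make_group(payload["group"])
            rates: dict[Subset, dict[Element, float]] = {}
            for entry in payload["edges"]:
                e = frozenset(entry["subset"])
                chan = {
                    tuple(int(x) for x in key.split(",")): float(a)
                    for key, a in entry["rates"].items()
                }
                rates[e] = chan
        except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
            if isinstance(exc, DomainError):
                raise
            raise InputFormatError(f"malformed rates JSON: {exc}") from exc
        return cls(group, rates)


@dataclass
class TreeEdges:
    """Edge subsets of ``{1..n-1}`` for a tree rooted at taxon ``n``.

    By default the subsets must form a laminar family (any two nested or
    disjoint), i.e. be realizable on a tree.  Arbitrary subset lists —
    split systems — are permitted with ``network=True``.
    """

    n: int
    edge_subsets: list[Subset]
    network: bool = False

    def __post_init__(self):
        if self.n < 1:
            raise DomainError("need n >= 1 leaves")
        subsets = []
        seen = set()
        for e in self.edge_subsets:
            e = frozenset(int(i) for i in e)
            if not e or not e <= set(range(1, self.n)):
                raise DomainError(
                    f"edge subset {sorted(e)} is not a nonempty subset of "
                    f"{{1..{self.n - 1}}}"
                )
            if e in seen:
                raise DomainError(f"duplicate edge subset {sorted(e)}")
            seen.add(e)
            subsets.append(e)
        self.edge_subsets = subsets
        if not self.network and not self.is_laminar():
            raise DomainError(
                "edge subsets are not tree-compatible (laminar); "
                "pass network=True for split systems"
            )

    def is_laminar(self) -> bool:
        subs = self.edge_subsets
        for i, a in enumerate(subs):
            for b in subs[i + 1 :]:
                if a & b and not (a <= b or b <= a):
                    return False
        return True


@dataclass
class PhyloTensor:
    """A ``d^n`` site-pattern array, in the standard or spectral basis.

    ``values[i_1, ..., i_n]`` is the probability of observing element
    index ``i_k`` at leaf ``k`` (standard basis), or the corresponding
    character-transformed component (spectral basis).
    """

    group: AbelianGroup
    values: np.ndarray
    basis: str = "standard"

    def __post_init__(self):
        if self.basis not in ("standard", "spectral"):
            raise DomainError(f"unknown basis {self.basis!r}")
        self.values = np.asarray(self.values)
        d = self.group.order
        if self.values.ndim < 1 or set(self.values.shape) != {d}:
            raise DomainError(
                f"tensor shape {self.values.shape} is not (d,)*n for d={d}"
            )

    @property
    def n(self) -> int:
        """Number of leaves."""
        return self.values.ndim

    def real_probabilities(self, imag_tol: float = 1e-10) -> np.ndarray:
        """Standard-basis values as a real array, discarding a sub-``imag_tol``
        imaginary residue (raising if it is larger)."""
        if self.basis != "standard":
            raise DomainError("tensor is not in the standard basis")
        v = self.values
        if np.iscomplexobj(v):
            resid = float(np.abs(v.imag).max()) if v.size else 0.0
            if resid > imag_tol:
                raise DomainError(f"imaginary residue {resid:.2e} exceeds {imag_tol}")
            v = v.real
        return v


# ---------------------------------------------------------------------------
# operations


def rate_matrix(group: AbelianGroup, rates: Mapping[Element, float]) -> np.ndarray:
    """Doubly stochastic generator ``Q = -lambda 1 + sum alpha^sigma K_sigma``.

    ``rates`` maps non-identity elements to nonnegative rates; rows and
    columns of the result sum to zero, hence the uniform distribution is
    stationary.
    """
    d = group.order
    Q = np.zeros((d, d))
    lam = 0.0
    for sigma, a in rates.items():
        sigma = group._check(sigma)
        if sigma == group.identity:
            raise DomainError("rate supplied for the identity element")
        a = float(a)
        if not np.isfinite(a) or a < 0:
            raise DomainError(f"invalid rate {a} for element {sigma}")
        Q += a * regular_representation(group, sigma)
        lam += a
    Q -= lam * np.eye(d)
    return Q


def _adjacency_from_newick(newick: str, n: int):
    """Parse Newick text into an undirected adjacency map with degree-2
    vertices suppressed; returns (adjacency, leaf-node map)."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise InputFormatError(f"could not parse Newick tree: {exc}") from exc

    if any(
        edge.length is not None
        for edge in tree.preorder_edge_iter()
        if edge.tail_node is not None
    ):
        warnings.warn(
            "branch lengths in Newick input are ignored; edge rates come "
            "from the rate specification",
            stacklevel=3,
        )

    labels: dict[int, object] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else leaf.label
        try:
            idx = int(str(label))
        except (TypeError, ValueError):
            raise InputFormatError(f"leaf label {label!r} is not an integer")
        if idx in labels:
            raise InputFormatError(f"duplicate leaf label {idx}")
        labels[idx] = leaf
    if set(labels) != set(range(1, n + 1)):
        raise InputFormatError(
            f"tree leaves {sorted(labels)} != expected labels 1..{n}"
        )

    adj: dict[object, set] = {}
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        adj.setdefault(edge.tail_node, set()).add(edge.head_node)
        adj.setdefault(edge.head_node, set()).add(edge.tail_node)
    # suppress degree-2 vertices (e.g. a rooted bifurcation read unrooted)
    for node in list(adj):
        if node in labels.values():
            continue
        while node in adj and len(adj[node]) == 2:
            a, b = adj.pop(node)
            adj[a].discard(node)
            adj[b].discard(node)
            adj[a].add(b)
            adj[b].add(a)
            break
    if n == 1:
        adj.setdefault(labels[1], set())
    return adj, labels


def _leaves_below(adj, labels_inv, node, parent) -> set[int]:
    if node in labels_inv:
        return {labels_inv[node]}
    out: set[int] = set()
    for child in adj[node]:
        if child is not parent:
            out |= _leaves_below(adj, labels_inv, child, node)
    return out


def edges_from_newick(newick: str, n: int) -> TreeEdges:
    """Edge subsets of a Newick tree with leaves labelled ``1..n``.

    Each edge is labelled by the set of leaves ``i`` whose path to taxon
    ``n`` crosses it — the leaf set on the side of the edge away from
    taxon ``n``.  The pendant edge at taxon ``n`` is labelled
    ``{1..n-1}``.  Multifurcations are allowed.
    """
    adj, labels = _adjacency_from_newick(newick, n)
    labels_inv = {node: idx for idx, node in labels.items()}
    root = labels[n]
    subsets: list[Subset] = []

    def walk(node, parent):
        for child in adj[node]:
            if child is parent:
                continue
            below = _leaves_below(adj, labels_inv, child, node)
            subsets.append(frozenset(below))
            walk(child, node)

    walk(root, None)
    subsets.sort(key=lambda e: (len(e), sorted(e)))
    return TreeEdges(n=n, edge_subsets=subsets)


def star_tensor(n: int, group: AbelianGroup) -> PhyloTensor:
    """Zero-edge-length star-tree distribution: mass ``1/d`` on each of
    the ``d`` constant patterns."""
    if n < 1:
        raise DomainError("need n >= 1")
    d = group.order
    values = np.zeros((d,) * n)
    for i in range(d):
        values[(i,) * n] = 1.0 / d
    return PhyloTensor(group, values, basis="standard")


def _total_element_index(group: AbelianGroup, n: int, leaves: Sequence[int]) -> np.ndarray:
    """Element index of ``sum_{j in leaves} i_j`` as an array broadcast over
    the ``(d,)*n`` pattern grid."""
    d = group.order
    add = group.addition_table
    tau = np.zeros((1,) * n, dtype=np.intp)
    for leaf in leaves:
        axis_idx = np.arange(d, dtype=np.intp).reshape(
            (1,) * (leaf - 1) + (d,) + (1,) * (n - leaf)
        )
        tau = add[tau, axis_idx]
    return tau


def spectral_star_values(n: int, group: AbelianGroup) -> np.ndarray:
    """Character transform of the star tensor: the 0/1 support indicator.

    Entry at pattern ``mu`` is 1 exactly when the pattern's symbols sum to
    the identity (per cyclic factor: weighted block sizes = 0 mod r_k),
    and 0 otherwise.
    """
    total = _total_element_index(group, n, range(1, n + 1))
    return (np.broadcast_to(total, (group.order,) * n) == 0).astype(float)


def phylo_tensor(
    group: AbelianGroup, edges: TreeEdges, rates: RateSpec
) -> PhyloTensor:
    """Pattern-probability tensor of a group-based model (spectral path).

    Every ``K_sigma^(e)`` is diagonal in the character basis with entries
    ``chi(sum_{j in e} i_j, sigma)``, so the edge-generator exponential is
    an elementwise exponential; the result is transformed back to the
    standard basis.  ``edges`` may be any split system (``network=True``);
    an empty edge list returns the star tensor.
    """
    from .transform import inverse_transform

    n, d = edges.n, group.order
    allowed = set(edges.edge_subsets)
    for e in rates.rates:
        if e not in allowed:
            raise DomainError(
                f"rates keyed by {sorted(e)}, which is not among the edge subsets"
            )
    chi = group.character_values

    log_factors = np.zeros((d,) * n, dtype=complex)
    for e, chan in rates.items():
        if not chan:
            continue
        tau = _total_element_index(group, n, sorted(e))
        for sigma, a in chan.items():
            if a == 0.0:
                continue
            log_factors = log_factors + a * chi[tau, group.index(sigma)]
    lam = rates.total_rate
    spectral = np.exp(log_factors - lam) * spectral_star_values(n, group)
    P = inverse_transform(PhyloTensor(group, spectral, basis="spectral"))
    return P


def apply_branching(v: np.ndarray) -> np.ndarray:
    """Branching (copy) operator ``delta``: embeds a state distribution on
    one taxon as the diagonal of a two-taxon joint distribution."""
    v = np.asarray(v)
    if v.ndim != 1:
        raise DomainError("apply_branching expects a vector")
    return np.diag(v)


def oracle_tree_tensor(
    group: AbelianGroup, newick: str, rates: RateSpec
) -> PhyloTensor:
    """Pattern probabilities by classical pruning — the independent oracle.

    Roots the tree at taxon ``n`` with the uniform distribution, assigns
    the substitution matrix ``M_e = expm(Q_e)`` to each edge, and
    marginalizes internal-node states in post-order.  No spectral
    machinery is used.  Tree input only.
    """
    try:
        probe = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        n = len(probe.leaf_nodes())
    except Exception as exc:
        raise InputFormatError(f"could not parse Newick tree: {exc}") from exc

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adj, labels = _adjacency_from_newick(newick, n)
    labels_inv = {node: idx for idx, node in labels.items()}
    d = group.order

    tree_subsets: set[Subset] = set()

    def collect(node, parent):
        for child in adj[node]:
            if child is parent:
                continue
            tree_subsets.add(frozenset(_leaves_below(adj, labels_inv, child, node)))
            collect(child, node)

    root = labels[n]
    collect(root, None)
    stray = set(rates.rates) - tree_subsets
    if stray:
        raise DomainError(
            f"rate subsets {sorted(map(sorted, stray))} are not edges of the tree; "
            "the pruning oracle refuses non-tree edge sets"
        )

    def edge_matrix(subset: Subset) -> np.ndarray:
        chan = rates.rates.get(subset, {})
        if not chan:
            return np.eye(d)
        return expm(rate_matrix(group, chan))

    def down(node, parent):
        """Return (leaf_order, msg) with msg shape (d**k, d): joint partial
        likelihood of the k leaves below ``node`` given the state at the
        parent end of the edge above ``node``."""
        if node in labels_inv:
            below = [labels_inv[node]]
            partial = np.eye(d)  # [own state, state at node]
        else:
            below = []
            partial = np.ones((1, d))
            for child in adj[node]:
                if child is parent:
                    continue
                c_below, c_msg = down(child, node)
                partial = np.einsum("as,bs->abs", partial, c_msg).reshape(-1, d)
                below.extend(c_below)
        M = edge_matrix(frozenset(below))
        # message to parent: sum over this node's state
        return below, partial @ M

    below, msg = down(next(iter(adj[root])), root)
    # root is leaf n with uniform prior over its state
    full = (msg / d).reshape((d,) * (len(below) + 1))
    order = below + [n]
    perm = [order.index(i) for i in range(1, n + 1)]
    values = np.transpose(full, axes=perm)
    return PhyloTensor(group, values, basis="standard")
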