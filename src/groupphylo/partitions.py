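"""Ordered partitions: the index bookkeeping for spectral components.

A length-``m`` string over the alphabet ``{0, ..., r-1}`` is equivalently
an *ordered-r-partition* ``mu = mu_0 : mu_1 : ... : mu_{r-1}`` of the
ground set ``{1..m}``: position ``j`` belongs to block ``mu_k`` exactly
when symbol ``j`` of the string is ``k``.  Blocks may be empty and the
order of blocks matters ("01010" and "10101" are different partitions).

The gamma completion selects, for a partition of the reduced set
``{1..n-1}``, the unique final symbol whose appended string has weighted
block sizes summing to 0 mod r — precisely the support condition of the
transformed star-tree tensor, hence of every group-based model tensor.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator, Sequence

from .errors import DomainError

__all__ = [
    "OrderedPartition",
    "string_to_partition",
    "partition_to_string",
    "gamma_completion",
    "gamma_completion_string",
    "enumerate_partitions",
    "string_rank",
]

_ENUMERATION_GUARD = 10**8


@dataclass(frozen=True)
class OrderedPartition:
    """An ordered tuple of ``r`` disjoint blocks covering ``{1..m}``.

    Attributes
    ----------
    blocks : tuple of frozenset of int
        Pairwise-disjoint subsets whose union is exactly ``{1..m}``;
        empty blocks are allowed.
    ground_size : int
        ``m``, the size of the ground set (may be 0).
    """

    blocks: tuple[frozenset[int], ...]
    ground_size: int

    def __post_init__(self):
        blocks = tuple(frozenset(b) for b in self.blocks)
        object.__setattr__(self, "blocks", blocks)
        ground = set(range(1, self.ground_size + 1))
        seen: set[int] = set()
        for b in blocks:
            if b & seen:
                raise DomainError("ordered-partition blocks are not disjoint")
            seen |= b
        if seen != ground:
            raise DomainError(
                f"blocks cover {sorted(seen)}, expected {{1..{self.ground_size}}}"
            )

    @property
    def r(self) -> int:
        """Number of blocks (the alphabet size of the state string)."""
        return len(self.blocks)

    def block_of(self, j: int) -> int:
        for k, b in enumerate(self.blocks):
            if j in b:
                return k
        raise DomainError(f"{j} not in ground set of size {self.ground_size}")

    def __str__(self) -> str:
        return ":".join(
            "{" + ",".join(map(str, sorted(b))) + "}" if b else "()"
            for b in self.blocks
        )


def string_to_partition(symbols: Sequence[int], r: int) -> OrderedPartition:
    """Ordered-r-partition of ``{1..m}`` equivalent to a state string.

    Position ``j`` (1-based) lands in block ``symbols[j-1]``.

    Examples
    --------
    >>> str(string_to_partition([0, 0, 1, 1, 0], 2))
    '{1,2,5}:{3,4}'
    """
    blocks: list[set[int]] = [set() for _ in range(r)]
    for j, s in enumerate(symbols, start=1):
        s = int(s)
        if not 0 <= s < r:
            raise DomainError(f"symbol {s} at position {j} out of range for r={r}")
        blocks[s].add(j)
    return OrderedPartition(tuple(frozenset(b) for b in blocks), len(symbols))


def partition_to_string(mu: OrderedPartition) -> tuple[int, ...]:
    """State string of an ordered partition (inverse of string_to_partition)."""
    out = [0] * mu.ground_size
    for k, b in enumerate(mu.blocks):
        for j in b:
            out[j - 1] = k
    return tuple(out)


def _weighted_sum(symbols: Sequence[int]) -> int:
    # sum_k k*|mu_k| equals the plain sum of string symbols
    return sum(int(s) for s in symbols)


def gamma_completion(u: OrderedPartition, r: int | None = None) -> int:
    """The unique residue making ``u`` extend to a zero-weight string.

    For ``u`` an ordered-r-partition of ``{1..n-1}``,
    ``gamma(u) = r - (0|u_0| + 1|u_1| + ... + (r-1)|u_{r-1}|) mod r``,
    reduced into ``{0..r-1}``.  Appending ``gamma(u)`` to the state string
    of ``u`` gives the length-``n`` index of the one potentially non-zero
    spectral tensor entry associated with ``u``.
    """
    if r is None:
        r = u.r
    elif r != u.r:
        raise DomainError(f"partition has {u.r} blocks, expected r={r}")
    return gamma_completion_string(partition_to_string(u), r)


def gamma_completion_string(symbols: Sequence[int], r: int) -> int:
    """Gamma completion computed directly from a state string."""
    for s in symbols:
        if not 0 <= int(s) < r:
            raise DomainError(f"symbol {s} out of range for r={r}")
    return (-_weighted_sum(symbols)) % r


def string_rank(symbols: Sequence[int], r: int) -> int:
    """Lexicographic rank of a state string: its base-``r`` integer value,
    first position most significant.  Defines the row order of all
    spectral vectors and of the F/G inversion matrices."""
    rank = 0
    for s in symbols:
        rank = rank * r + int(s)
    return rank


def enumerate_partitions(m: int, r: int) -> Iterator[OrderedPartition]:
    """All ``r^m`` ordered-r-partitions of ``{1..m}``, in lexicographic
    order of their state strings (so position == string_rank)."""
    if m < 0 or r < 2:
        raise DomainError(f"need m >= 0 and r >= 2, got m={m}, r={r}")
    if r**m > _ENUMERATION_GUARD:
        raise DomainError(f"r^m = {r}^{m} exceeds enumeration guard")
    for symbols in product(range(r), repeat=m):
        yield string_to_partition(symbols, r)
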