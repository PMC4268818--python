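"""Finite abelian groups, regular representations and character tables.

A group-based substitution model on a finite abelian group ``G`` assigns a
rate to each non-identity element; the rate matrix is a linear combination
of the permutation matrices of the regular representation.  Because every
irreducible representation of an abelian group is one-dimensional, the
character table of ``G`` — a generalized Hadamard matrix — simultaneously
diagonalizes all of these permutation matrices, which is what makes the
conjugation between pattern probabilities and edge rates invertible.

Groups are specified as ordered products of cyclic factors,
``G = Z_{r_1} x ... x Z_{r_q}``.  Elements are residue tuples
``(i_1, ..., i_q)`` enumerated in lexicographic order, the identity
``(0, ..., 0)`` first; this ordering fixes every matrix row/column
convention in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Sequence

import numpy as np

from .errors import DomainError, InvalidGroupError

__all__ = [
    "AbelianGroup",
    "make_group",
    "prime_power_refine",
    "regular_representation",
    "character_table",
    "character_inverse",
    "diagonal_character",
    "GROUP_ALIASES",
]

#: Named group aliases accepted anywhere a factor list is (config, CLI).
GROUP_ALIASES: dict[str, tuple[int, ...]] = {
    "binary": (2,),
    "Z2": (2,),
    "Z3": (3,),
    "K3ST": (2, 2),
}


@dataclass(frozen=True)
class AbelianGroup:
    """A finite abelian group as an ordered product of cyclic factors.

    Attributes
    ----------
    factor_orders : tuple of int
        Cyclic factor orders ``(r_1, ..., r_q)``, each >= 2.
    """

    factor_orders: tuple[int, ...]
    _tables: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def q(self) -> int:
        """Number of cyclic factors."""
        return len(self.factor_orders)

    @property
    def order(self) -> int:
        """Group order ``d``."""
        d = 1
        for r in self.factor_orders:
            d *= r
        return d

    @property
    def elements(self) -> tuple[tuple[int, ...], ...]:
        """All elements as residue tuples, lexicographic, identity first."""
        if "elements" not in self._tables:
            self._tables["elements"] = tuple(
                product(*(range(r) for r in self.factor_orders))
            )
        return self._tables["elements"]

    @property
    def identity(self) -> tuple[int, ...]:
        return (0,) * self.q

    def index(self, sigma: Sequence[int]) -> int:
        """Mixed-radix index of an element in the lexicographic enumeration."""
        sigma = self._check(sigma)
        idx = 0
        for s, r in zip(sigma, self.factor_orders):
            idx = idx * r + s
        return idx

    def element(self, index: int) -> tuple[int, ...]:
        """Element at a given enumeration index."""
        if not 0 <= index < self.order:
            raise DomainError(f"element index {index} out of range for d={self.order}")
        return self.elements[index]

    def add(self, a: Sequence[int], b: Sequence[int]) -> tuple[int, ...]:
        """Componentwise addition mod the factor orders."""
        a, b = self._check(a), self._check(b)
        return tuple((x + y) % r for x, y, r in zip(a, b, self.factor_orders))

    def neg(self, a: Sequence[int]) -> tuple[int, ...]:
        """Group inverse."""
        a = self._check(a)
        return tuple((-x) % r for x, r in zip(a, self.factor_orders))

    def contains(self, sigma: Sequence[int]) -> bool:
        try:
            self._check(sigma)
        except DomainError:
            return False
        return True

    def _check(self, sigma: Sequence[int]) -> tuple[int, ...]:
        sigma = tuple(int(s) for s in sigma)
        if len(sigma) != self.q or any(
            not 0 <= s < r for s, r in zip(sigma, self.factor_orders)
        ):
            raise DomainError(f"{sigma} is not an element of Z{self.factor_orders}")
        return sigma

    # -- cached dense tables -------------------------------------------------

    @property
    def addition_table(self) -> np.ndarray:
        """``d x d`` int array: index of ``elements[i] + elements[j]``."""
        if "add" not in self._tables:
            d = self.order
            tab = np.empty((d, d), dtype=np.intp)
            for i, a in enumerate(self.elements):
                for j, b in enumerate(self.elements):
                    tab[i, j] = self.index(self.add(a, b))
            self._tables["add"] = tab
        return self._tables["add"]

    @property
    def negation_table(self) -> np.ndarray:
        """Length-``d`` int array: index of the inverse of each element."""
        if "neg" not in self._tables:
            self._tables["neg"] = np.array(
                [self.index(self.neg(a)) for a in self.elements], dtype=np.intp
            )
        return self._tables["neg"]

    @property
    def character_values(self) -> np.ndarray:
        """``d x d`` complex array ``chi[i, j] = prod_k omega_k^(i_k j_k)``.

        Row i is the character indexed by element i evaluated across the
        group; the array is symmetric and equals :func:`character_table`.
        """
        if "chi" not in self._tables:
            self._tables["chi"] = character_table(self)
        return self._tables["chi"]

    def non_identity(self) -> tuple[tuple[int, ...], ...]:
        """All non-identity elements, in enumeration order."""
        return self.elements[1:]


def make_group(factor_orders: Sequence[int]) -> AbelianGroup:
    """Build the abelian group ``Z_{r_1} x ... x Z_{r_q}``.

    Parameters
    ----------
    factor_orders : sequence of int
        Cyclic factor orders, each an integer >= 2.  Named aliases in
        :data:`GROUP_ALIASES` ("binary", "Z3", "K3ST") are also accepted.

    Examples
    --------
    >>> make_group([2, 2]).elements
    ((0, 0), (0, 1), (1, 0), (1, 1))
    """
    if isinstance(factor_orders, str):
        try:
            factor_orders = GROUP_ALIASES[factor_orders]
        except KeyError:
            raise InvalidGroupError(f"unknown group alias {factor_orders!r}")
    orders = []
    for r in factor_orders:
        if isinstance(r, bool) or not isinstance(r, (int, np.integer)):
            raise InvalidGroupError(f"factor order {r!r} is not an integer")
        if r < 2:
            raise InvalidGroupError(f"factor order {r} < 2")
        orders.append(int(r))
    if not orders:
        raise InvalidGroupError("at least one cyclic factor is required")
    return AbelianGroup(tuple(orders))


def _prime_power_parts(r: int) -> list[int]:
    parts = []
    p = 2
    while p * p <= r:
        if r % p == 0:
            pk = 1
            while r % p == 0:
                r //= p
                pk *= p
            parts.append(pk)
        p += 1
    if r > 1:
        parts.append(r)
    return parts


def prime_power_refine(factor_orders: Sequence[int]) -> list[int]:
    """Rewrite a factor list so every order is a prime power.

    By the fundamental theorem of finite abelian groups the refined list
    presents an isomorphic group, and isomorphic groups define the same
    substitution model, so either list may be used interchangeably.

    Examples
    --------
    >>> prime_power_refine([6])
    [2, 3]
    >>> prime_power_refine([12])
    [4, 3]
    """
    group = make_group(factor_orders)  # validates
    refined: list[int] = []
    for r in group.factor_orders:
        refined.extend(_prime_power_parts(r))
    return refined


def regular_representation(group: AbelianGroup, sigma: Sequence[int]) -> np.ndarray:
    """Permutation matrix ``K_sigma`` of the regular representation.

    ``K[j, i] = 1`` iff ``elements[j] = sigma + elements[i]`` (column i,
    row j), so ``K_sigma`` acts on probability column vectors.  The
    identity element maps to the identity matrix.
    """
    sigma = group._check(sigma)
    d = group.order
    K = np.zeros((d, d), dtype=np.int64)
    for i, a in enumerate(group.elements):
        j = group.index(group.add(sigma, a))
        K[j, i] = 1
    return K


@lru_cache(maxsize=None)
def _character_table_cached(factor_orders: tuple[int, ...]) -> np.ndarray:
    f = np.ones((1, 1), dtype=complex)
    for r in factor_orders:
        omega = np.exp(2j * np.pi / r)
        jj, ii = np.meshgrid(np.arange(r), np.arange(r), indexing="ij")
        f_r = omega ** (ii * jj)
        f = np.kron(f, f_r)
    f.setflags(write=False)
    return f


def character_table(group: AbelianGroup) -> np.ndarray:
    """The ``d x d`` character table (generalized Hadamard matrix).

    Entry at row j, column i is ``prod_k omega_k^(i_k j_k)`` with
    ``omega_k = exp(2 pi i / r_k)``; equivalently the Kronecker product of
    the cyclic-factor Fourier matrices.  First row and column are all ones.
    Computed from the closed form, never by numerical diagonalization.
    """
    return _character_table_cached(group.factor_orders)


def character_inverse(group: AbelianGroup) -> np.ndarray:
    """Exact inverse of :func:`character_table`: ``(1/d) conj(f)``.

    (``f`` is symmetric, so the conjugate transpose equals the conjugate.)
    """
    return character_table(group).conj() / group.order


def diagonal_character(group: AbelianGroup, sigma: Sequence[int]) -> np.ndarray:
    """Diagonal of ``f K_sigma f^{-1}`` as a length-``d`` vector.

    Entry at element index i is ``prod_k omega_k^(i_k s_k)`` — the value of
    the i-th character at ``sigma``.  This is simply column ``sigma`` of
    the character table; no matrix product is performed.
    """
    sigma = group._check(sigma)
    return character_table(group)[:, group.index(sigma)].copy()
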