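"""The n-fold character transform of pattern tensors and its inverse.

For a group of order ``d`` with character table ``f``, the transform
``P -> f^(n) P`` applies ``f`` along each of the ``n`` leaf axes (it is
never materialized as a ``d^n x d^n`` Kronecker matrix).  In the
transformed basis every edge generator ``K_sigma^(e)`` is diagonal, with
entries given by :func:`diagonal_generator_entry`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import DomainError, ModelViolationError
from .groups import AbelianGroup, character_inverse, character_table
from .model import PhyloTensor

__all__ = [
    "forward_transform",
    "inverse_transform",
    "diagonal_generator_entry",
    "apply_axiswise",
]


def apply_axiswise(values: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Apply a ``d x d`` matrix along every axis of a ``(d,)*n`` array.

    Equivalent to multiplying by the n-fold Kronecker power of ``matrix``
    on the flattened array, at ``O(n d^{n+1})`` cost instead of ``d^{2n}``
    memory.
    """
    values = np.asarray(values, dtype=complex)
    for axis in range(values.ndim):
        values = np.moveaxis(
            np.tensordot(matrix, values, axes=(1, axis)), 0, axis
        )
    return values


def forward_transform(P: PhyloTensor) -> PhyloTensor:
    """Character transform ``P_hat = f^(n) . P`` (standard -> spectral).

    The entry at the all-zeros pattern of the result equals the total
    probability.  For the binary group this is the classical n-fold
    Walsh-Hadamard transform.
    """
    if P.basis != "standard":
        raise DomainError("forward_transform expects a standard-basis tensor")
    f = character_table(P.group)
    return PhyloTensor(P.group, apply_axiswise(P.values, f), basis="spectral")


def inverse_transform(P_hat: PhyloTensor, imag_tol: float = 1e-10) -> PhyloTensor:
    """Inverse character transform (spectral -> standard).

    The result of transforming a valid spectral tensor is real; an
    imaginary residue below ``imag_tol`` (relative to the tensor's scale)
    is discarded, a larger one signals corrupted spectral input and
    raises :class:`ModelViolationError`.
    """
    if P_hat.basis != "spectral":
        raise DomainError("inverse_transform expects a spectral-basis tensor")
    finv = character_inverse(P_hat.group)
    values = apply_axiswise(P_hat.values, finv)
    scale = max(1.0, float(np.abs(values).max())) if values.size else 1.0
    resid = float(np.abs(values.imag).max()) if values.size else 0.0
    if resid > imag_tol * scale:
        raise ModelViolationError(
            f"imaginary residue {resid:.3e} after inverse transform exceeds "
            f"{imag_tol}; spectral input is not the transform of a real tensor"
        )
    return PhyloTensor(P_hat.group, values.real, basis="standard")


def diagonal_generator_entry(
    group: AbelianGroup,
    e: Sequence[int] | frozenset[int],
    mu: Sequence[Sequence[int] | int],
    sigma: Sequence[int],
) -> complex:
    """Diagonal entry ``[K_hat_sigma^(e)]_mu^mu`` of an edge generator.

    ``mu`` is a pattern (one group element per leaf, as residue tuples or
    element indices); the entry is ``chi(sum_{j in e} mu_j, sigma)`` —
    for a single cyclic factor ``r`` and ``sigma = s`` this is
    ``omega^(s * sum_k k |mu_k ∩ e|)``, and for the binary group it
    reduces to ``(-1)^(|e ∩ mu_1|)``.
    """
    sigma = group._check(sigma)
    total = group.identity
    for j in e:
        j = int(j)
        if not 1 <= j <= len(mu):
            raise DomainError(f"leaf {j} in subset but pattern has {len(mu)} symbols")
        sym = mu[j - 1]
        if isinstance(sym, (int, np.integer)):
            sym = group.element(int(sym))
        total = group.add(total, sym)
    return complex(group.character_values[group.index(total), group.index(sigma)])
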