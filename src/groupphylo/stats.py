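"""Sampling-error propagation for inverted spectra.

When the inversion is applied to empirical pattern frequencies from ``N``
i.i.d. sites, the recovered rates inherit multinomial sampling noise.
Each rate is a smooth function of the frequency vector, so the delta
method gives first-order standard errors: if ``w`` is the gradient of a
recovered rate with respect to the pattern frequencies, then

    Var(alpha_hat) ~= ( sum_x p_x w_x^2  -  (sum_x p_x w_x)^2 ) / N.

The gradient chains the linear recovery step through the elementwise
logarithm and the character transform, and is evaluated matrix-free.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError
from .groups import character_table
from .inversion import collapse, subsets_in_order
from .model import PhyloTensor, _total_element_index
from .transform import apply_axiswise, forward_transform

__all__ = ["recovery_standard_errors"]


def recovery_standard_errors(
    P: PhyloTensor, sites: int
) -> dict[tuple[frozenset[int], tuple[int, ...]], float]:
    """Delta-method standard errors of every recovered rate.

    ``P`` is the standard-basis probability tensor at which to linearize
    (the empirical frequencies, or the true model when known) and
    ``sites`` the number of i.i.d. sites behind it.
    """
    if sites <= 0:
        raise DomainError("sites must be positive")
    group, n = P.group, P.n
    d = group.order
    p_flat = P.real_probabilities().reshape(-1)
    # empirical frequencies are fine here: noise off the support does not
    # enter the linearization
    pvec = collapse(forward_transform(P), vanish_tol=None).values
    chi = group.character_values
    f = character_table(group)

    # gamma-completion index of each partition grid point (as in expand)
    tau_all = _total_element_index(group, n - 1, range(1, n))
    gamma = group.negation_table[np.broadcast_to(tau_all, (d,) * (n - 1))]

    out: dict[tuple[frozenset[int], tuple[int, ...]], float] = {}
    for e in subsets_in_order(n - 1):
        if not e:
            continue
        tau_e = _total_element_index(group, n - 1, sorted(e))
        tau_e = np.broadcast_to(tau_e, (d,) * (n - 1))
        for sigma in group.non_identity():
            g_grid = chi[tau_e, group.index(sigma)].conj() / d ** (n - 1)
            z = np.zeros((d,) * n, dtype=complex)
            np.put_along_axis(
                z, gamma[..., None], (g_grid / pvec)[..., None], axis=-1
            )
            w = apply_axiswise(z, f).reshape(-1)
            w = w.real  # conjugate-pair symmetry cancels the imaginary part
            mean = float(p_flat @ w)
            var = (float(p_flat @ w**2) - mean**2) / sites
            out[(e, sigma)] = float(np.sqrt(max(var, 0.0)))
    return out
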