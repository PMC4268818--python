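"""Generalized Hadamard conjugation: pattern probabilities <-> edge rates.

The inversion runs in two parts.  First, the spectral tensor of a valid
group-based model is supported only on patterns whose symbols sum to the
identity (per cyclic factor), so it collapses losslessly to a vector
``P_u`` indexed by ordered partitions ``u`` of ``{1..n-1}`` via the gamma
completion; taking logarithms gives ``theta_u = ln P_u = eta_u - lambda``.
Second, ``eta`` is linear in the rates, ``eta = sum_s F_s alpha_s`` with
``F_s`` built from character-table entries, and the matching ``G_s``
matrices (rows of the inverse character transform) satisfy
``G_s F_{s'} = delta_{ss'} 1`` on nonempty subsets, so each channel's
rates are read off as ``alpha_s = G_s theta`` and the unknown total rate
drops out: the empty-subset coordinate of ``G_s theta`` equals
``-lambda`` for every channel.

The ``F``/``G`` matrices are available densely (mirroring the printed
rectangular-matrix formulation, useful for tests) and matrix-free (one
inverse axiswise transform plus index gathering), which is how
:func:`recover` and :func:`forward_spectrum` work by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ModelViolationError, SaturationError
from .groups import AbelianGroup, character_inverse
from .model import (
    PhyloTensor,
    RateSpec,
    _total_element_index,
    spectral_star_values,
)
from .transform import apply_axiswise, forward_transform

__all__ = [
    "SpectralVector",
    "EdgeSpectrum",
    "InversionMatrices",
    "collapse",
    "expand",
    "log_step",
    "build_FG",
    "recover",
    "forward_spectrum",
    "invert_tensor",
    "tensor_from_spectrum",
    "subsets_in_order",
]

Element = tuple[int, ...]
Subset = frozenset[int]

_FG_MEMORY_GUARD = 10**8


def subsets_in_order(m: int) -> list[Subset]:
    """All subsets of ``{1..m}`` ordered by binary value (bit ``i-1`` for
    leaf ``i``), the empty set first.  Fixes the column order of every
    ``F_s`` and row order of every ``G_s``."""
    out = []
    for code in range(2**m):
        out.append(frozenset(i for i in range(1, m + 1) if code >> (i - 1) & 1))
    return out


@dataclass
class SpectralVector:
    """Values indexed by ordered partitions of ``{1..n-1}``.

    Stored as a ``(d,)*(n-1)`` array whose axis ``j`` carries the group
    element at leaf ``j+1``; C-order flattening therefore matches the
    lexicographic string order used by the dense F/G matrices.

    ``kind`` is ``"probability"`` for the collapsed components ``P_u`` or
    ``"log"`` for ``theta_u = ln(P_u)`` (the shifted logarithm
    ``eta = theta + lambda`` is never stored: lambda is recovered
    downstream).
    """

    group: AbelianGroup
    values: np.ndarray
    kind: str = "probability"

    def __post_init__(self):
        if self.kind not in ("probability", "log"):
            raise DomainError(f"unknown spectral-vector kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=complex)
        d = self.group.order
        if self.values.ndim and set(self.values.shape) != {d}:
            raise DomainError(
                f"spectral-vector shape {self.values.shape} is not (d,)*(n-1)"
            )

    @property
    def n(self) -> int:
        """Leaf count of the underlying tensor (ground set size + 1)."""
        return self.values.ndim + 1

    @property
    def flat(self) -> np.ndarray:
        """Values flattened in lexicographic string order."""
        return self.values.reshape(-1)


@dataclass
class EdgeSpectrum:
    """Per-edge-subset, per-channel rates plus the total rate ``lambda``.

    The inversion's output.  Values recovered from data that is not a
    valid group-based model tensor may be negative; they are flagged via
    :attr:`has_negative_rates`, never rejected.
    """

    group: AbelianGroup
    n: int
    rates: dict[tuple[Subset, Element], float] = field(default_factory=dict)
    lambda_total: float = 0.0

    def __post_init__(self):
        clean = {}
        for (e, sigma), a in self.rates.items():
            e = frozenset(e)
            sigma = self.group._check(sigma)
            if not e or not e <= set(range(1, self.n)):
                raise DomainError(f"subset {sorted(e)} invalid for n={self.n}")
            if sigma == self.group.identity:
                raise DomainError("identity element has no rate channel")
            clean[(e, sigma)] = float(a)
        self.rates = clean

    @property
    def rate_sum(self) -> float:
        return float(sum(self.rates.values()))

    @property
    def rate_residual(self) -> float:
        """``lambda_total - sum(rates)``; ~0 for a valid model spectrum."""
        return self.lambda_total - self.rate_sum

    @property
    def has_negative_rates(self) -> bool:
        return any(a < 0 for a in self.rates.values())

    def get(self, e: Subset, sigma: Element) -> float:
        return self.rates.get((frozenset(e), tuple(sigma)), 0.0)

    def to_rate_spec(self) -> RateSpec:
        """Convert to a forward-direction RateSpec (requires rates >= 0)."""
        by_edge: dict[Subset, dict[Element, float]] = {}
        for (e, sigma), a in self.rates.items():
            by_edge.setdefault(e, {})[sigma] = a
        return RateSpec(self.group, by_edge)

    @classmethod
    def from_rate_spec(cls, spec: RateSpec, n: int) -> "EdgeSpectrum":
        rates = {
            (e, sigma): a
            for e, chan in spec.items()
            for sigma, a in chan.items()
        }
        return cls(spec.group, n, rates, lambda_total=spec.total_rate)

    # -- TSV round trip -----------------------------------------------------

    def to_tsv(self) -> str:
        lines = ["subset\tchannel\trate"]
        for (e, sigma), a in sorted(
            self.rates.items(), key=lambda kv: (sorted(kv[0][0]), kv[0][1])
        ):
            lines.append(
                ",".join(map(str, sorted(e)))
                + "\t"
                + ",".join(map(str, sigma))
                + f"\t{a!r}"
            )
        lines.append(f"-\t-\t{self.lambda_total!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, group: AbelianGroup, n: int) -> "EdgeSpectrum":
        from .errors import InputFormatError

        rates: dict[tuple[Subset, Element], float] = {}
        lam = 0.0
        lines = [ln for ln in text.splitlines() if ln.strip()]
        try:
            for line in lines[1:]:
                sub_s, chan_s, rate_s = line.split("\t")
                if sub_s == "-":
                    lam = float(rate_s)
                    continue
                e = frozenset(int(x) for x in sub_s.split(","))
                sigma = tuple(int(x) for x in chan_s.split(","))
                rates[(e, sigma)] = float(rate_s)
        except ValueError as exc:
            raise InputFormatError(f"malformed edge-spectrum TSV: {exc}") from exc
        return cls(group, n, rates, lambda_total=lam)


@dataclass
class InversionMatrices:
    """Dense ``F_s`` / ``G_s`` pairs, one per non-identity channel.

    ``F[s]`` has one row per ordered-partition tuple ``u`` (lexicographic
    string order) and one column per subset ``e`` of ``{1..n-1}``
    including the empty set (binary-value order, empty first); ``G[s]``
    is the transposed shape.  ``G_s F_{s'} = delta_{ss'} 1`` on the
    nonempty-subset block, and the empty-set column of every ``F_s`` is
    all ones.
    """

    group: AbelianGroup
    n: int
    channels: tuple[Element, ...]
    subsets: list[Subset]
    F: dict[Element, np.ndarray]
    G: dict[Element, np.ndarray]


def collapse(P_hat: PhyloTensor, vanish_tol: float | None = 1e-8) -> SpectralVector:
    """Read the non-vanishing spectral components ``P_u = P_hat[u . gamma(u)]``.

    Every entry not selected is provably zero for a group-based stationary
    model (the support condition); if one exceeds ``vanish_tol`` in
    magnitude the input is not such a model and
    :class:`ModelViolationError` is raised.  Empirical frequency tensors
    carry multinomial noise of order ``1/sqrt(N)`` on those components, so
    for such input pass ``vanish_tol=None`` to project the noise away
    silently (which is what dropping the components amounts to).
    """
    if P_hat.basis != "spectral":
        raise DomainError("collapse expects a spectral-basis tensor")
    group, n = P_hat.group, P_hat.n
    if n < 2:
        raise DomainError("collapse needs n >= 2 leaves")
    values = np.asarray(P_hat.values, dtype=complex)

    support = spectral_star_values(n, group).astype(bool)
    discarded = values[~support]
    if vanish_tol is not None and discarded.size and float(np.abs(discarded).max()) > vanish_tol:
        raise ModelViolationError(
            f"spectral mass {np.abs(discarded).max():.3e} on provably-vanishing "
            "components: input is not a stationary group-based model tensor"
        )

    # gamma(u) per factor == group inverse of the symbol sum of u
    tau = _total_element_index(group, n - 1, range(1, n))
    gamma = group.negation_table[np.broadcast_to(tau, values.shape[:-1])]
    collapsed = np.take_along_axis(values, gamma[..., None], axis=-1)[..., 0]
    return SpectralVector(group, collapsed, kind="probability")


def expand(p: SpectralVector) -> PhyloTensor:
    """Scatter collapsed components back into a full spectral tensor,
    zeros on the vanishing components (inverse of :func:`collapse`)."""
    if p.kind != "probability":
        raise DomainError("expand expects a probability-kind spectral vector")
    group, n = p.group, p.n
    d = group.order
    values = np.zeros((d,) * n, dtype=complex)
    tau = _total_element_index(group, n - 1, range(1, n))
    gamma = group.negation_table[np.broadcast_to(tau, (d,) * (n - 1))]
    np.put_along_axis(values, gamma[..., None], p.values[..., None], axis=-1)
    return PhyloTensor(group, values, basis="spectral")


def log_step(p: SpectralVector, min_magnitude: float = 1e-12) -> SpectralVector:
    """Principal-branch elementwise logarithm: ``theta_u = ln(P_u)``.

    Raises :class:`SaturationError` on (near-)zero components — edge rates
    too large, or degenerate data.  Components on or near the negative
    real axis sit at the principal-branch cut, where the inversion is no
    longer guaranteed; a warning is emitted.
    """
    if p.kind != "probability":
        raise DomainError("log_step expects a probability-kind spectral vector")
    mags = np.abs(p.values)
    if p.values.size and float(mags.min()) <= min_magnitude:
        raise SaturationError(
            f"spectral component magnitude {mags.min():.3e} at or below "
            f"{min_magnitude}: edge rates too large or data degenerate"
        )
    near_cut = np.abs(np.abs(np.angle(p.values)) - np.pi) < 0.02 * np.pi
    if bool(near_cut.any()):
        warnings.warn(
            "spectral component(s) near the negative real axis: principal "
            "log branch is ambiguous there and recovered rates may be wrong",
            stacklevel=2,
        )
    return SpectralVector(p.group, np.log(p.values), kind="log")


def _channel_index_string(
    group: AbelianGroup, n: int, e: Subset, sigma: Element
) -> tuple[int, ...]:
    """Index of ``f^{-1(n-1)} theta`` holding channel ``sigma``'s rate for
    subset ``e``: symbol ``sigma`` at positions in ``e``, identity
    elsewhere (the ``e^c : ... : e : ... :`` row of the dense G)."""
    s_idx = group.index(sigma)
    return tuple(s_idx if j in e else 0 for j in range(1, n))


def build_FG(group: AbelianGroup, n: int) -> InversionMatrices:
    """Dense inversion matrices for every non-identity channel.

    ``F_s[u, e] = chi(sum_{j in e} u_j, sigma_s)`` — the diagonal entry of
    ``K_hat_sigma^(e)`` at ``u . gamma(u)`` — and
    ``G_s = conj(F_s)^T / d^(n-1)``.
    """
    if n < 2:
        raise DomainError("build_FG needs n >= 2")
    d = group.order
    n_rows, n_cols = d ** (n - 1), 2 ** (n - 1)
    if n_rows * n_cols * (d - 1) > _FG_MEMORY_GUARD:
        raise DomainError(
            "dense F/G would exceed the memory guard; use the matrix-free "
            "path (recover / forward_spectrum call it by default)"
        )
    subsets = subsets_in_order(n - 1)
    chi = group.character_values
    channels = group.non_identity()

    taus = np.empty((n_rows, n_cols), dtype=np.intp)
    for col, e in enumerate(subsets):
        tau = _total_element_index(group, n - 1, sorted(e))
        taus[:, col] = np.broadcast_to(tau, (d,) * (n - 1)).reshape(-1)

    F: dict[Element, np.ndarray] = {}
    G: dict[Element, np.ndarray] = {}
    for sigma in channels:
        Fs = chi[taus, group.index(sigma)]
        F[sigma] = Fs
        G[sigma] = Fs.conj().T / n_rows
    return InversionMatrices(group, n, channels, subsets, F, G)


def recover(
    theta: SpectralVector,
    dense: bool = False,
    imag_tol: float = 1e-9,
    lambda_tol: float = 1e-6,
) -> EdgeSpectrum:
    """Second inversion part: rates ``alpha_s = G_s theta`` and ``lambda``.

    The empty-subset coordinate of ``G_s theta`` equals ``-lambda`` for
    every channel ``s`` (the empty row of ``G_s`` annihilates all
    nonempty-subset columns, which is how the unknown shift in
    ``eta = theta + lambda`` drops out); channel estimates of ``lambda``
    disagreeing beyond ``lambda_tol`` signal non-model input.

    By default the matrix-free path is used: one inverse axiswise
    character transform of ``theta`` followed by index gathering; the
    dense path multiplies by the ``G_s`` of :func:`build_FG`.
    """
    if theta.kind != "log":
        raise DomainError("recover expects a log-kind spectral vector")
    group, n = theta.group, theta.n
    channels = group.non_identity()
    nonempty = [e for e in subsets_in_order(n - 1) if e]

    raw: dict[Element, dict[Subset, complex]] = {}
    lam_by_channel: dict[Element, complex] = {}
    if dense:
        mats = build_FG(group, n)
        flat = theta.flat
        for sigma in channels:
            g_theta = mats.G[sigma] @ flat
            lam_by_channel[sigma] = -g_theta[0]
            raw[sigma] = {
                e: g_theta[col]
                for col, e in enumerate(mats.subsets)
                if e
            }
    else:
        T = apply_axiswise(theta.values, character_inverse(group))
        for sigma in channels:
            lam_by_channel[sigma] = -complex(T[(0,) * (n - 1)])
            raw[sigma] = {
                e: complex(T[_channel_index_string(group, n, e, sigma)])
                for e in nonempty
            }

    scale = max(1.0, float(np.abs(theta.values).max()))
    values = list(lam_by_channel.values()) + [
        v for chan in raw.values() for v in chan.values()
    ]
    worst_imag = max((abs(v.imag) for v in values), default=0.0)
    if worst_imag > imag_tol * scale:
        raise ModelViolationError(
            f"imaginary residue {worst_imag:.3e} in recovered spectrum "
            "(log-branch failure or corrupted input)"
        )
    lams = np.array([v.real for v in lam_by_channel.values()])
    if lams.size and float(lams.max() - lams.min()) > lambda_tol:
        raise ModelViolationError(
            f"per-channel lambda estimates disagree by "
            f"{lams.max() - lams.min():.3e} (> {lambda_tol})"
        )

    rates = {
        (e, sigma): v.real
        for sigma, chan in raw.items()
        for e, v in chan.items()
    }
    return EdgeSpectrum(group, n, rates, lambda_total=float(lams.mean()))


def forward_spectrum(spec: EdgeSpectrum) -> SpectralVector:
    """Forward map on the collapsed components:
    ``P_u = exp(-lambda) exp(eta_u)`` with ``eta = sum_s F_s alpha_s``
    (computed matrix-free).  Composing with the full inverse pipeline is
    the identity on edge spectra."""
    group, n = spec.group, spec.n
    d = group.order
    chi = group.character_values
    eta = np.zeros((d,) * (n - 1), dtype=complex)
    for (e, sigma), a in spec.rates.items():
        if a == 0.0:
            continue
        tau = _total_element_index(group, n - 1, sorted(e))
        eta = eta + a * chi[tau, group.index(sigma)]
    p = np.exp(eta - spec.lambda_total)
    return SpectralVector(group, p, kind="probability")


def invert_tensor(
    P: PhyloTensor, vanish_tol: float | None = 1e-8, **kwargs
) -> EdgeSpectrum:
    """Full inversion pipeline on a standard-basis probability tensor:
    transform, collapse, log, recover.  Use ``vanish_tol=None`` for
    empirical frequency input (see :func:`collapse`)."""
    return recover(
        log_step(collapse(forward_transform(P), vanish_tol=vanish_tol)), **kwargs
    )


def tensor_from_spectrum(spec: EdgeSpectrum) -> PhyloTensor:
    """Standard-basis probability tensor of an edge spectrum (forward
    conjugation evaluated through the collapsed components)."""
    from .transform import inverse_transform

    return inverse_transform(expand(forward_spectrum(spec)))
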