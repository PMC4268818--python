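"""Pattern tables: the on-disk form of site-pattern distributions.

A pattern string encodes one group element per leaf.  For a single
cyclic factor of order r it is simply n digits over ``0..r-1``; for a
product group the per-factor strings are separated by ``|`` (the K3ST
pattern ``"01|10"`` means leaf 1 is ``(0,1)`` and leaf 2 is ``(1,0)``).
Tables are TSV with columns ``pattern`` and ``value`` and hold either
probabilities (summing to 1) or nonnegative integer counts; missing
patterns are imputed as zero.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InputFormatError
from .groups import AbelianGroup
from .model import PhyloTensor

__all__ = [
    "PatternTable",
    "format_pattern",
    "parse_pattern",
    "K3ST_NUCLEOTIDE_MAP",
    "pattern_counts_from_sequences",
]

#: Conventional Kimura-style assignment of nucleotides to Z2 x Z2 elements:
#: A<->G and C<->T differ by (0,1) (transitions); the two transversion
#: classes are (1,0) and (1,1).  This mapping is a convention, not part of
#: the model; confirm it suits your data before using nucleotide I/O.
K3ST_NUCLEOTIDE_MAP: dict[str, tuple[int, int]] = {
    "A": (0, 0),
    "G": (0, 1),
    "C": (1, 0),
    "T": (1, 1),
}


def format_pattern(group: AbelianGroup, states: Sequence[Sequence[int]]) -> str:
    """Pattern string of a leaf-state assignment (residue tuples)."""
    states = [group._check(s) for s in states]
    parts = []
    for k in range(group.q):
        parts.append("".join(str(s[k]) for s in states))
    return "|".join(parts)


def parse_pattern(group: AbelianGroup, text: str, n: int) -> tuple[tuple[int, ...], ...]:
    """Leaf-state assignment encoded by a pattern string."""
    parts = text.strip().split("|")
    if len(parts) != group.q or any(len(p) != n for p in parts):
        raise InputFormatError(
            f"pattern {text!r} does not have {group.q} factor string(s) of length {n}"
        )
    states = []
    for j in range(n):
        residues = []
        for k, (part, r) in enumerate(zip(parts, group.factor_orders)):
            try:
                v = int(part[j])
            except ValueError:
                raise InputFormatError(f"non-digit symbol in pattern {text!r}")
            if not 0 <= v < r:
                raise InputFormatError(
                    f"symbol {v} out of range for factor order {r} in {text!r}"
                )
            residues.append(v)
        states.append(tuple(residues))
    return tuple(states)


@dataclass
class PatternTable:
    """Site-pattern strings with probabilities or counts."""

    group: AbelianGroup
    n: int
    values: np.ndarray  # flat, length d**n, C-order over leaf element indices
    kind: str = "probability"  # or "count"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        d = self.group.order
        if self.values.shape != (d**self.n,):
            raise DomainError(
                f"expected {d**self.n} values for d={d}, n={self.n}"
            )
        if self.kind not in ("probability", "count"):
            raise DomainError(f"unknown table kind {self.kind!r}")
        if self.kind == "probability":
            total = float(self.values.sum())
            if abs(total - 1.0) > 1e-8:
                raise DomainError(f"probabilities sum to {total}, not 1")
        else:
            if np.any(self.values < 0) or np.any(self.values != np.round(self.values)):
                raise DomainError("counts must be nonnegative integers")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def patterns(self) -> list[str]:
        """All d**n pattern strings in flat (lexicographic) order."""
        group, n, d = self.group, self.n, self.group.order
        out = []
        for flat in range(d**n):
            idx = np.unravel_index(flat, (d,) * n)
            out.append(format_pattern(group, [group.element(i) for i in idx]))
        return out

    def to_tensor(self) -> PhyloTensor:
        """Probability tensor (counts are normalized to frequencies)."""
        d = self.group.order
        vals = self.values
        if self.kind == "count":
            if vals.sum() <= 0:
                raise DomainError("cannot normalize an empty count table")
            vals = vals / vals.sum()
        return PhyloTensor(self.group, vals.reshape((d,) * self.n), basis="standard")

    @classmethod
    def from_tensor(cls, P: PhyloTensor, imag_tol: float = 1e-10) -> "PatternTable":
        vals = P.real_probabilities(imag_tol=imag_tol).reshape(-1)
        vals = np.where(np.abs(vals) < 1e-15, 0.0, vals)  # tidy -0.0 noise
        return cls(P.group, P.n, vals, kind="probability")

    # -- TSV ----------------------------------------------------------------

    def to_tsv(self, include_zero: bool = True) -> str:
        df = pd.DataFrame({"pattern": self.patterns(), "value": self.values})
        if not include_zero:
            df = df[df["value"] != 0.0]
        buf = _io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()

    @classmethod
    def from_tsv(
        cls,
        text: str,
        group: AbelianGroup,
        n: int,
        kind: str | None = None,
    ) -> "PatternTable":
        """Parse a TSV table; missing patterns are imputed as zero.

        ``kind=None`` auto-detects: all-integer values summing above 1 are
        treated as counts, anything else as probabilities.
        """
        try:
            df = pd.read_csv(_io.StringIO(text), sep="\t", dtype={"pattern": str})
        except Exception as exc:
            raise InputFormatError(f"malformed pattern TSV: {exc}") from exc
        if not {"pattern", "value"} <= set(df.columns):
            raise InputFormatError("pattern TSV needs columns 'pattern' and 'value'")
        d = group.order
        values = np.zeros(d**n)
        for pat, val in zip(df["pattern"], df["value"]):
            states = parse_pattern(group, str(pat), n)
            flat = np.ravel_multi_index(
                tuple(group.index(s) for s in states), (d,) * n
            )
            values[flat] += float(val)
        if kind is None:
            total = values.sum()
            is_int = np.all(values == np.round(values))
            kind = "count" if (is_int and total > 1 + 1e-9) else "probability"
        return cls(group, n, values, kind=kind)


def pattern_counts_from_sequences(
    sequences: Mapping[int, str],
    group: AbelianGroup,
    mapping: Mapping[str, Sequence[int]],
) -> PatternTable:
    """Count site patterns in aligned sequences keyed by leaf label 1..n.

    A minimal preprocessing helper: ``mapping`` sends each sequence letter
    to a group element (e.g. :data:`K3ST_NUCLEOTIDE_MAP`); columns with
    unmapped letters are skipped.
    """
    n = len(sequences)
    if set(sequences) != set(range(1, n + 1)):
        raise InputFormatError(f"sequences must be keyed 1..{n}")
    seqs = [str(sequences[i]).upper() for i in range(1, n + 1)]
    if len({len(s) for s in seqs}) != 1:
        raise InputFormatError("sequences are not aligned (unequal lengths)")
    d = group.order
    counts = np.zeros(d**n)
    for col in zip(*seqs):
        try:
            idx = tuple(group.index(mapping[c]) for c in col)
        except KeyError:
            continue
        counts[np.ravel_multi_index(idx, (d,) * n)] += 1
    return PatternTable(group, n, counts, kind="count")
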