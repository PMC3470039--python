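"""Alignment-derived statistics: site coverage filtering and percent identity.

Two operations that routinely precede phylogenetic work on a protein
family: (1) removing unreliable alignment columns by *site coverage* (the
fraction of sequences with a residue, rather than a gap, at the column);
(2) summarising pairwise percent identity between all family members as a
symmetric matrix.

Percent identity from a multiple alignment is ambiguous in its
denominator, and published tables rarely state the convention. All four
common conventions are selectable; the default ``pair_columns`` divides by
the columns where at least one of the two sequences has a residue, which
excludes mutual-gap columns (those would deflate identity between two
short sequences embedded in a long family alignment) and matches
ClustalW-style reporting most closely.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import LookupError_, ValidationError
from .genome_io import GAP, Msa

IDENTITY_MODES = ("pair_columns", "msa_length", "min_seq_length", "aligned_pairs")


@dataclass(frozen=True)
class FilterParams:
    """Minimum site coverage a column needs to be kept, as a fraction."""

    min_coverage: float = 0.80

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_coverage <= 1.0):
            raise ValidationError("min_coverage must be in [0, 1]")


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity table over the alignment's sequences."""

    ids: list[str]
    values: np.ndarray  # full precision, percent scale
    mode: str

    def rounded(self) -> np.ndarray:
        """Integer percents, rounded half-up (presentation convention)."""
        round_half_up = np.vectorize(
            lambda x: int(Decimal(repr(float(x))).quantize(0, rounding=ROUND_HALF_UP))
        )
        return round_half_up(self.values)

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        data = self.rounded() if rounded else self.values
        return pd.DataFrame(data, index=self.ids, columns=self.ids)

    def get(self, id_i: str, id_j: str) -> float:
        return float(self.values[self.ids.index(id_i), self.ids.index(id_j)])


def column_coverage(msa: Msa, col: int) -> float:
    """Fraction of sequences with a non-gap character at the column.

    X counts as a residue: coverage measures data presence, not certainty.
    """
    if not (0 <= col < msa.n_columns):
        raise IndexError(f"column {col} out of range 0..{msa.n_columns - 1}")
    present = sum(1 for row in msa.rows if row[col] != GAP)
    return present / len(msa.rows)


def filter_columns(msa: Msa, p: FilterParams) -> tuple[Msa, list[int]]:
    """Keep exactly the columns with coverage >= min_coverage.

    Column order is preserved and the kept 0-based indices are returned;
    applying the filter twice changes nothing. An empty result raises
    rather than returning a degenerate alignment.
    """
    arr = np.array([list(row) for row in msa.rows])
    coverage = (arr != GAP).mean(axis=0)
    kept = [int(c) for c in np.nonzero(coverage >= p.min_coverage)[0]]
    if not kept:
        raise ValidationError(
            f"no column reaches {p.min_coverage:.0%} site coverage; empty alignment"
        )
    rows = ["".join(arr[r, kept]) for r in range(len(msa.rows))]
    return Msa(list(msa.ids), rows), kept


def pairwise_identity(msa: Msa, id_i: str, id_j: str, mode: str = "pair_columns") -> float:
    """Percent identity between two rows of an alignment (full precision).

    Identities are columns where both rows carry the same residue, X
    excluded. The denominator depends on ``mode``:

    - ``pair_columns``: columns where at least one row has a residue
    - ``msa_length``: all alignment columns
    - ``min_seq_length``: the shorter of the two ungapped sequences
    - ``aligned_pairs``: columns where both rows have a residue
    """
    if mode not in IDENTITY_MODES:
        raise ValidationError(f"unknown identity mode {mode!r}; use one of {IDENTITY_MODES}")
    try:
        row_i, row_j = msa.row(id_i), msa.row(id_j)
    except LookupError_:
        raise
    identities = 0
    pair_cols = 0
    both = 0
    for x, y in zip(row_i, row_j):
        gi, gj = x == GAP, y == GAP
        if not (gi and gj):
            pair_cols += 1
        if not gi and not gj:
            both += 1
            if x == y and x != "X":
                identities += 1
    if mode == "pair_columns":
        denom = pair_cols
    elif mode == "msa_length":
        denom = msa.n_columns
    elif mode == "min_seq_length":
        denom = min(
            sum(1 for c in row_i if c != GAP), sum(1 for c in row_j if c != GAP)
        )
    else:
        denom = both
    if denom == 0:
        return 0.0
    return 100.0 * identities / denom


def identity_matrix(msa: Msa, mode: str = "pair_columns") -> IdentityMatrix:
    """All-pairs percent identity; symmetric with a 100 diagonal."""
    if len(msa.ids) < 2:
        raise ValidationError("identity matrix needs at least two sequences")
    n = len(msa.ids)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v = pairwise_identity(msa, msa.ids[i], msa.ids[j], mode)
            values[i, j] = values[j, i] = v
    return IdentityMatrix(ids=list(msa.ids), values=values, mode=mode)
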