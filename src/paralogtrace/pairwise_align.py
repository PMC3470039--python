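"""Exact pairwise protein alignment with a Karlin–Altschul E-value model.

This is the homology engine for the neighborhood comparisons: optimal
Smith–Waterman (local) and Needleman–Wunsch (global, end gaps penalized)
alignment with affine gap costs, scored by a substitution matrix. Exact
dynamic programming replaces heuristic seeded search: the gene windows
being compared are small (at most a few hundred proteins), so optimality
is affordable and removes heuristic nondeterminism. The dynamic programming
itself is delegated to Biopython's C ``PairwiseAligner``.

Gap costs follow the NCBI convention: a gap of length ``k`` costs
``gap_open + k * gap_extend`` (defaults 11 + k, the blastp default for
BLOSUM62). Significance uses the Karlin–Altschul formula

    E = K * m * n * exp(-lambda * S)

with the published gapped BLOSUM62-11-1 constants lambda = 0.267 and
K = 0.041. The unknown residue X scores 0 against everything and never
counts as an identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ValidationError

#: Published gapped Karlin–Altschul parameters for BLOSUM62 with gap costs 11/1.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


@lru_cache(maxsize=8)
def load_matrix(name_or_path: str = "BLOSUM62"):
    """Load a substitution matrix by name or from an NCBI matrix text file.

    The X row and column are forced to zero so that unknown residues are
    neutral: they neither reward nor penalize an alignment.
    """
    if Path(name_or_path).is_file():
        with open(name_or_path) as fh:
            matrix = substitution_matrices.read(fh)
    else:
        matrix = substitution_matrices.load(name_or_path)
    matrix = matrix.copy()
    if "X" in matrix.alphabet:
        for other in matrix.alphabet:
            matrix["X", other] = 0.0
            matrix[other, "X"] = 0.0
    return matrix


@dataclass(frozen=True)
class AlignParams:
    """Alignment scoring parameters (matrix plus affine gap costs)."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValidationError("require gap_open >= gap_extend >= 1")
        m = self.matrix
        for a in m.alphabet:
            for b in m.alphabet:
                if m[a, b] != m[b, a]:
                    raise ValidationError("substitution matrix is not symmetric")

    @property
    def matrix(self):
        return load_matrix(self.matrix_name)


@dataclass(frozen=True)
class EvalueParams:
    """Karlin–Altschul statistical parameters for gapped alignment scores."""

    lam: float = DEFAULT_LAMBDA
    K: float = DEFAULT_K

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValidationError("lambda and K must be strictly positive")


@dataclass(frozen=True)
class HomologyHit:
    """One scored pairwise match between two proteins.

    Spans are 1-based inclusive residue intervals; ``(0, 0)`` marks an
    empty local alignment (score 0, nothing aligned).
    """

    query_id: str
    subject_id: str
    raw_score: int
    bitscore: float
    evalue: float
    identities: int
    aln_length: int
    q_span: tuple[int, int]
    s_span: tuple[int, int]
    gap_opens: int = 0
    gap_columns: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.identities <= max(self.aln_length, 0)):
            raise ValidationError("identities outside [0, aln_length]")
        if self.evalue < 0:
            raise ValidationError("negative E-value")


@lru_cache(maxsize=8)
def _aligner(params: AlignParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = params.matrix
    # NCBI convention: gap of length k costs open + k*extend.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = mode
    return aligner


def raw_align_score(a_res: str, b_res: str, params: AlignParams, mode: str = "local") -> int:
    """Optimal alignment score only (no traceback) — the fast path."""
    if not a_res or not b_res:
        raise ValidationError("cannot align empty sequence")
    return int(_aligner(params, mode).score(a_res, b_res))


def _hit_from_alignment(a, b, alignment, mode: str, ev: EvalueParams, m: int, n: int) -> HomologyHit:
    a_res, b_res = a.residues, b.residues
    blocks_a, blocks_b = alignment.aligned
    identities = 0
    aligned_cols = 0
    gap_opens = 0
    gap_cols = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        aligned_cols += ae - as_
        for x, y in zip(a_res[as_:ae], b_res[bs:be]):
            if x == y and x != "X":
                identities += 1
    for k in range(1, len(blocks_a)):
        da = blocks_a[k][0] - blocks_a[k - 1][1]
        db = blocks_b[k][0] - blocks_b[k - 1][1]
        if da > 0:
            gap_opens += 1
            gap_cols += da
        if db > 0:
            gap_opens += 1
            gap_cols += db
    if len(blocks_a) == 0:
        q_span = s_span = (0, 0)
        aln_length = 0
    elif mode == "global":
        lead = blocks_a[0][0] + blocks_b[0][0]
        trail = (len(a_res) - blocks_a[-1][1]) + (len(b_res) - blocks_b[-1][1])
        gap_cols += lead + trail
        gap_opens += int(blocks_a[0][0] > 0) + int(blocks_b[0][0] > 0)
        gap_opens += int(blocks_a[-1][1] < len(a_res)) + int(blocks_b[-1][1] < len(b_res))
        aln_length = aligned_cols + gap_cols
        q_span = (1, len(a_res))
        s_span = (1, len(b_res))
    else:
        aln_length = aligned_cols + gap_cols
        q_span = (int(blocks_a[0][0]) + 1, int(blocks_a[-1][1]))
        s_span = (int(blocks_b[0][0]) + 1, int(blocks_b[-1][1]))
    score = int(alignment.score)
    return HomologyHit(
        query_id=a.id,
        subject_id=b.id,
        raw_score=score,
        bitscore=bitscore(score, ev),
        evalue=evalue(score, m, n, ev),
        identities=identities,
        aln_length=aln_length,
        q_span=q_span,
        s_span=s_span,
        gap_opens=gap_opens,
        gap_columns=gap_cols,
    )


def local_align(a, b, params: AlignParams = AlignParams(), ev: EvalueParams = EvalueParams(),
                n_db: int | None = None) -> HomologyHit:
    """Optimal Smith–Waterman local alignment of two proteins.

    ``n_db`` is the database residue count used in the E-value (defaults to
    ``len(b)`` — a single-sequence database). The first optimal traceback
    reported by the aligner is used, which is deterministic for fixed
    inputs and parameters.
    """
    if not a.residues or not b.residues:
        raise ValidationError("cannot align empty sequence")
    alignment = _aligner(params, "local").align(a.residues, b.residues)[0]
    return _hit_from_alignment(a, b, alignment, "local", ev, len(a.residues),
                               n_db if n_db is not None else len(b.residues))


def global_align(a, b, params: AlignParams = AlignParams(), ev: EvalueParams = EvalueParams(),
                 n_db: int | None = None) -> HomologyHit:
    """Optimal Needleman–Wunsch global alignment with end gaps penalized."""
    if not a.residues or not b.residues:
        raise ValidationError("cannot align empty sequence")
    alignment = _aligner(params, "global").align(a.residues, b.residues)[0]
    return _hit_from_alignment(a, b, alignment, "global", ev, len(a.residues),
                               n_db if n_db is not None else len(b.residues))


def evalue(raw_score: int, m: int, n: int, ev: EvalueParams = EvalueParams()) -> float:
    """Karlin–Altschul expected number of chance hits: K*m*n*exp(-lambda*S)."""
    if m < 1 or n < 1:
        raise ValidationError("sequence/database lengths must be >= 1")
    return ev.K * m * n * math.exp(-ev.lam * raw_score)


def bitscore(raw_score: int, ev: EvalueParams = EvalueParams()) -> float:
    """Normalized score: (lambda*S - ln K) / ln 2, so E = m*n*2^(-bitscore)."""
    return (ev.lam * raw_score - math.log(ev.K)) / math.log(2)
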