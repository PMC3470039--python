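"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: alignment scoring is
done by exhaustively enumerating every gapped alignment, and chain finding
by enumerating every valid chain of matrix hits. Exponential, so only
usable at toy sizes — which is the point.
"""

from __future__ import annotations

from itertools import combinations


def enumerate_alignments(la: int, lb: int):
    """Yield every global alignment of sequences of lengths la, lb as a
    list of columns: ('M', i, j), ('A', i) = residue of a vs gap, ('B', j)."""

    def rec(i: int, j: int, cols):
        if i == la and j == lb:
            yield list(cols)
            return
        if i < la and j < lb:
            cols.append(("M", i, j))
            yield from rec(i + 1, j + 1, cols)
            cols.pop()
        if i < la:
            cols.append(("A", i))
            yield from rec(i + 1, j, cols)
            cols.pop()
        if j < lb:
            cols.append(("B", j))
            yield from rec(i, j + 1, cols)
            cols.pop()

    yield from rec(0, 0, [])


def score_alignment(cols, a: str, b: str, matrix, gap_open: int, gap_extend: int) -> float:
    """Affine score of one enumerated alignment.

    A run of k consecutive gap columns of one kind costs open + k*extend
    (NCBI convention). Adjacent runs of different kinds each pay open.
    """
    score = 0.0
    run_kind = None
    for col in cols:
        if col[0] == "M":
            _, i, j = col
            score += matrix[a[i], b[j]]
            run_kind = None
        else:
            if col[0] != run_kind:
                score -= gap_open
                run_kind = col[0]
            score -= gap_extend
    return score


def global_score_oracle(a: str, b: str, matrix, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Best global score by exhaustive enumeration (end gaps penalized)."""
    return max(
        score_alignment(cols, a, b, matrix, gap_open, gap_extend)
        for cols in enumerate_alignments(len(a), len(b))
    )


def local_score_oracle(a: str, b: str, matrix, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Best local score: max over all substring pairs, floored at 0."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = global_score_oracle(a[i1:i2], b[j1:j2], matrix, gap_open, gap_extend)
                    best = max(best, s)
    return best


def enumerate_chains(hits, max_gap: int, orientation: str):
    """Yield every valid chain (as a tuple of hit indices) of length >= 1.

    ``hits`` is a list of (row, col, value). A successor must advance the
    row by 1..max_gap and the column by 1..max_gap (forward) or recede it
    by 1..max_gap (inverted).
    """

    def successors(k):
        rk, ck, _ = hits[k]
        for m, (rm, cm, _) in enumerate(hits):
            dr = rm - rk
            dc = cm - ck if orientation == "forward" else ck - cm
            if 1 <= dr <= max_gap and 1 <= dc <= max_gap:
                yield m

    def rec(chain):
        yield tuple(chain)
        for m in successors(chain[-1]):
            chain.append(m)
            yield from rec(chain)
            chain.pop()

    for k in range(len(hits)):
        yield from rec([k])


def best_blocks_oracle(cells: dict, max_gap: int, min_hits: int, allow_inversions: bool):
    """Greedy-by-score block extraction over exhaustively enumerated chains.

    Returns a list of (sorted hit-pair tuple, orientation, score), in
    extraction order. Mirrors the contract of ``chain_diagonals``: the
    best-scoring chain is retired first, each hit used at most once, only
    chains of ``min_hits`` or more reported.
    """
    hits = [(i, j, v) for (i, j), v in sorted(cells.items())]
    available = set(range(len(hits)))
    orientations = ["forward"] + (["inverted"] if allow_inversions else [])
    blocks = []
    while True:
        best = None
        for orientation in orientations:
            for chain in enumerate_chains(hits, max_gap, orientation):
                if len(chain) < min_hits or not set(chain) <= available:
                    continue
                score = sum(hits[k][2] for k in chain)
                key = (score, len(chain), orientation == "forward")
                if best is None or key > best[0]:
                    best = (key, chain, orientation)
        if best is None:
            break
        (score, _, _), chain, orientation = best
        blocks.append(
            (tuple((hits[k][0], hits[k][1]) for k in chain), orientation, score)
        )
        available -= set(chain)
    return blocks
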