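"""All-vs-all search, best hits, reciprocal best hits and the family census.

The reciprocal-best-hit (RBH) criterion is the standard operational test
for orthology / family membership used here: two sequences, one from each
set, qualify if each is the other's top-scoring match. E-values follow
blast semantics — the database size ``n`` in the Karlin–Altschul formula
is the total residue count of the *searched* set, so the two search
directions generally give different E-values for the same sequence pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .genome_io import HitTable, ProteinSequence
from .pairwise_align import (
    AlignParams,
    EvalueParams,
    HomologyHit,
    bitscore,
    evalue,
    local_align,
    raw_align_score,
)


@dataclass(frozen=True)
class SearchParams:
    """Significance threshold plus alignment and E-value parameters."""

    evalue_threshold: float = 1e-5
    align: AlignParams = field(default_factory=AlignParams)
    ev: EvalueParams = field(default_factory=EvalueParams)

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValidationError("evalue_threshold must be > 0")


@dataclass(frozen=True)
class RbhPair:
    """A mutual best-hit pair with the E-values from both search directions."""

    id_a: str
    id_b: str
    evalue_ab: float
    evalue_ba: float


def all_vs_all(
    set_a: list[ProteinSequence],
    set_b: list[ProteinSequence],
    p: SearchParams = SearchParams(),
    score_cache: dict | None = None,
) -> HitTable:
    """Search every sequence of ``set_a`` against the database ``set_b``.

    Returns exactly the pairs whose E-value passes the threshold. Scores
    are computed first (fast path); the full traceback is only done for
    passing pairs. ``score_cache`` maps (query_id, subject_id) to a raw
    local score and may be shared across calls to avoid re-aligning the
    same protein pair; scores do not depend on database size.
    """
    if not set_a or not set_b:
        raise ValidationError("both sequence sets must be non-empty")
    n_db = sum(len(s) for s in set_b)
    hits: list[HomologyHit] = []
    for a in set_a:
        for b in set_b:
            key = (a.id, b.id)
            if score_cache is not None and key in score_cache:
                score = score_cache[key]
            else:
                score = raw_align_score(a.residues, b.residues, p.align, "local")
                if score_cache is not None:
                    score_cache[key] = score
                    score_cache[(b.id, a.id)] = score  # SW score is symmetric
            e = evalue(score, len(a), n_db, p.ev)
            if e <= p.evalue_threshold:
                hits.append(local_align(a, b, p.align, p.ev, n_db=n_db))
    return HitTable(hits)


def best_hit(table: HitTable, query_id: str) -> HomologyHit | None:
    """The query's top hit: minimal E-value, then highest bitscore, then
    lexicographically smallest subject id. None for an unknown query."""
    candidates = table.by_query(query_id)
    if not candidates:
        return None
    return min(candidates, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def reciprocal_best_hits(ab: HitTable, ba: HitTable) -> list[RbhPair]:
    """Mutual best-hit pairs between two sets searched in both directions.

    ``ab`` holds hits of set A queried against database B; ``ba`` the
    reverse. A pair (a, b) is reported iff b is a's best hit in ``ab`` and
    a is b's best hit in ``ba``. Output is sorted by ``id_a``.
    """
    pairs: list[RbhPair] = []
    queries_a = sorted({h.query_id for h in ab.hits})
    for qa in queries_a:
        fwd = best_hit(ab, qa)
        if fwd is None:
            continue
        back = best_hit(ba, fwd.subject_id)
        if back is not None and back.subject_id == qa:
            pairs.append(RbhPair(qa, fwd.subject_id, fwd.evalue, back.evalue))
    return pairs


def family_census(
    seed_family: list[ProteinSequence],
    proteome: list[ProteinSequence],
    p: SearchParams = SearchParams(),
) -> list[str]:
    """Census of a gene family in a proteome by the reciprocal criterion.

    A proteome member is counted iff its best hit among the seed-family
    sequences reciprocates: that seed's best hit in the proteome is the
    member itself. Returns the deduplicated, sorted member id list.
    """
    if not seed_family:
        raise ValidationError("seed family must be non-empty")
    cache: dict = {}
    try:
        fwd = all_vs_all(proteome, seed_family, p, score_cache=cache)
        back = all_vs_all(seed_family, proteome, p, score_cache=cache)
    except ValidationError:
        raise
    members = {pair.id_a for pair in reciprocal_best_hits(fwd, back)}
    return sorted(members)
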