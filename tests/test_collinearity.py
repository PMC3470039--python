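"""Window extraction, diagonal chaining (vs brute force) and verdicts."""

import random

import pytest

from paralogtrace import (
    CollinearityParams,
    Event,
    SimulationSpec,
    chain_diagonals,
    classify,
    collinearity_scan,
    extract_window,
)
from paralogtrace.collinearity import HomologyMatrix
from paralogtrace.errors import LookupError_
from paralogtrace.synthetic_data import build_genome

from oracles import best_blocks_oracle


def _matrix(cells, n=20, m=20):
    ids_r = [f"r{i}" for i in range(n)]
    ids_c = [f"c{j}" for j in range(m)]
    return HomologyMatrix(
        row_ids=ids_r,
        col_ids=ids_c,
        row_offsets=list(range(-(n // 2), n - n // 2)),
        col_offsets=list(range(-(m // 2), m - m // 2)),
        cells=dict(cells),
    )


@pytest.fixture(scope="module")
def demo_genome():
    spec = SimulationSpec(
        seed=101, n_chromosomes=2, n_genes=50, protein_length=(90, 140), family_size=2
    )
    return build_genome(spec)


class TestExtractWindow:
    def test_full_window_mid_chromosome(self, demo_genome):
        ann = demo_genome.annotation()
        anchor = ann.chromosomes["chr1"][25].id
        win = extract_window(ann, anchor, CollinearityParams(window_size=20), demo_genome.proteome)
        assert win.realized_size == 21
        assert win.offsets == list(range(-10, 11))
        assert win.members[10][1] == anchor  # anchor at offset 0

    def test_truncated_at_chromosome_end(self, demo_genome):
        ann = demo_genome.annotation()
        anchor = ann.chromosomes["chr1"][2].id
        win = extract_window(ann, anchor, CollinearityParams(window_size=20), demo_genome.proteome)
        assert win.offsets[0] == -2
        assert win.realized_size == 13  # 2 left + anchor + 10 right

    def test_unknown_anchor_raises(self, demo_genome):
        with pytest.raises(LookupError_):
            extract_window(
                demo_genome.annotation(), "nope", CollinearityParams(), demo_genome.proteome
            )


class TestChainDiagonals:
    def test_perfect_forward_diagonal(self):
        m = _matrix({(i, i): 30.0 for i in range(5, 15)})
        (block,) = chain_diagonals(m, CollinearityParams())
        assert block.n_hits == 10 and block.orientation == "forward"

    def test_antidiagonal_found_when_inversions_allowed(self):
        m = _matrix({(i, 19 - i): 30.0 for i in range(5, 15)})
        (block,) = chain_diagonals(m, CollinearityParams())
        assert block.n_hits == 10 and block.orientation == "inverted"
        assert chain_diagonals(m, CollinearityParams(allow_inversions=False)) == []

    def test_gap_tolerance_respected(self):
        # hits 7 apart exceed max_chain_gap=5: two separate short runs
        cells = {(i, i): 10.0 for i in (0, 1, 2)} | {(i, i): 10.0 for i in (9, 10, 11)}
        blocks = chain_diagonals(_matrix(cells), CollinearityParams())
        assert sorted(b.n_hits for b in blocks) == [3, 3]

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_exhaustive_chain_enumeration(self, trial):
        """Greedy block extraction equals brute-force enumeration over all
        valid chains on random sparse matrices up to 8x8."""
        rng = random.Random(3000 + trial)
        n = rng.randint(3, 8)
        n_hits = rng.randint(2, min(12, n * n))
        coords = rng.sample([(i, j) for i in range(n) for j in range(n)], n_hits)
        cells = {(i, j): round(rng.uniform(1.0, 60.0), 3) for i, j in coords}
        p = CollinearityParams(
            window_size=n, max_chain_gap=rng.choice([1, 2, 5]), min_block_hits=2
        )
        blocks = chain_diagonals(_matrix(cells, n, n), p)
        expected = best_blocks_oracle(cells, p.max_chain_gap, p.min_block_hits, True)
        got = sorted((tuple(b.pairs), b.orientation) for b in blocks)
        want = sorted((pairs, ori) for pairs, ori, _ in expected)
        assert got == want


class TestClassify:
    def test_verdict_thresholds(self):
        p = CollinearityParams()
        m10 = _matrix({(i, i): 30.0 for i in range(10)})
        assert classify(chain_diagonals(m10, p), p).verdict == "high"
        m4 = _matrix({(i, i): 30.0 for i in range(4)})
        assert classify(chain_diagonals(m4, p), p).verdict == "weak"
        assert classify([], p).verdict == "none"

    def test_lone_anchor_hit_is_not_collinearity(self):
        m = _matrix({(10, 10): 200.0})
        p = CollinearityParams()
        assert classify(chain_diagonals(m, p), p).verdict == "none"


class TestScan:
    def test_pair_count_and_symmetry(self, demo_genome):
        ann = demo_genome.annotation()
        anchors = [ann.chromosomes["chr1"][10].id, ann.chromosomes["chr1"][30].id,
                   ann.chromosomes["chr2"][25].id]
        p = CollinearityParams(window_size=10)
        calls = collinearity_scan(ann, demo_genome.proteome, anchors, p)
        assert len(calls) == 3  # C(3,2)
        swapped = collinearity_scan(ann, demo_genome.proteome, anchors[::-1], p)
        fwd = {frozenset((c.anchor_a, c.anchor_b)): c.verdict for c in calls}
        rev = {frozenset((c.anchor_a, c.anchor_b)): c.verdict for c in swapped}
        assert fwd == rev

    def test_tandem_duplication_high_shuffled_none(self):
        """Planted tandem segment around two anchors is called high; the pair
        to an anchor on an unrelated shuffled chromosome is called none."""
        spec = SimulationSpec(
            seed=21, n_chromosomes=2, n_genes=40, protein_length=(120, 180),
            family_size=2, family_divergence=0.25,
            events=(
                Event("tandem_duplication", "chr1", 5, 20, divergence=0.1),
                Event("shuffle", "chr2", 0, 40),
            ),
        )
        genome = build_genome(spec)
        fam = genome.truth.family_members
        fam_chr1 = [f for f in fam if f.startswith("chr1")][0]
        # the tandem copy of the chr1 family anchor, if the anchor sat in the span
        pairs = dict(genome.truth.ortholog_pairs)
        anchor_a = fam_chr1 if fam_chr1 in pairs else genome.truth.ortholog_pairs[7][0]
        anchor_b = pairs.get(anchor_a, genome.truth.ortholog_pairs[7][1])
        other = [f for f in fam if f.startswith("chr2")][0]
        p = CollinearityParams(window_size=30)
        calls = collinearity_scan(
            genome.annotation(), genome.proteome, [anchor_a, anchor_b, other], p
        )
        by_pair = {frozenset((c.anchor_a, c.anchor_b)): c.verdict for c in calls}
        assert by_pair[frozenset((anchor_a, anchor_b))] == "high"
        assert by_pair[frozenset((anchor_a, other))] == "none"
        assert by_pair[frozenset((anchor_b, other))] == "none"

    def test_stricter_threshold_never_gains_hits(self, demo_genome):
        spec = SimulationSpec(
            seed=33, n_chromosomes=1, n_genes=30, protein_length=(100, 150),
            family_size=0,
            events=(Event("segmental_duplication", "chr1", 5, 25, divergence=0.2),),
        )
        genome = build_genome(spec)
        a, b = genome.truth.ortholog_pairs[10]
        hits_at = {}
        for thr in (1e-3, 1e-10, 1e-30):
            p = CollinearityParams(window_size=20, evalue_threshold=thr)
            (call,) = collinearity_scan(genome.annotation(), genome.proteome, [a, b], p)
            hits_at[thr] = call.best_block.n_hits if call.best_block else 0
        assert hits_at[1e-3] >= hits_at[1e-10] >= hits_at[1e-30]
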