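"""Determinism, statistical calibration and truth consistency of the generator."""

import numpy as np
import pytest
from scipy import stats

from paralogtrace import (
    Event,
    ProteinSequence,
    SimulationSpec,
    ValidationError,
    build_genome,
    diverge_sequence,
    emit_fixture,
    random_proteome,
    read_fasta,
    read_gff3,
)
from paralogtrace.homology_search import SearchParams, all_vs_all
from paralogtrace.synthetic_data import (
    AMINO_ACIDS,
    BACKGROUND_FREQS,
    _random_residues,
)


class TestRandomProteome:
    def test_deterministic_per_seed(self):
        spec = SimulationSpec(seed=7, n_chromosomes=2, n_genes=10, protein_length=(50, 80))
        a = random_proteome(spec)
        b = random_proteome(spec)
        assert [(s.id, s.residues) for s in a] == [(s.id, s.residues) for s in b]

    def test_lengths_within_bounds(self):
        spec = SimulationSpec(seed=1, n_chromosomes=1, n_genes=30, protein_length=(60, 90))
        assert all(60 <= len(s) <= 90 for s in random_proteome(spec))

    def test_residue_frequencies_match_background(self):
        """Chi-square goodness of fit at 1e5 residues should not reject the
        background table (alpha = 1e-3)."""
        rng = np.random.default_rng(99)
        residues = _random_residues(rng, 100_000)
        counts = np.array([residues.count(a) for a in AMINO_ACIDS])
        freqs = np.array([BACKGROUND_FREQS[a] for a in AMINO_ACIDS])
        freqs = freqs / freqs.sum()
        _, p = stats.chisquare(counts, f_exp=freqs * counts.sum())
        assert p > 1e-3


class TestDivergeSequence:
    def test_zero_divergence_is_identity(self):
        s = ProteinSequence("s", "MKVLIVDEAG")
        assert diverge_sequence(s, 0.0, 1).residues == s.residues

    def test_out_of_range_rejected(self):
        s = ProteinSequence("s", "MKV")
        with pytest.raises(ValidationError):
            diverge_sequence(s, 1.0, 1)

    def test_substitution_count_binomial_mean(self):
        """Observed substitutions across replicates match Binomial(L, d):
        mean within 3 standard errors."""
        rng = np.random.default_rng(5)
        L, d, reps = 200, 0.2, 1000
        s = ProteinSequence("s", _random_residues(rng, L))
        diffs = []
        for _ in range(reps):
            t = diverge_sequence(s, d, rng)
            diffs.append(sum(1 for x, y in zip(s.residues, t.residues) if x != y))
        se = np.sqrt(L * d * (1 - d) / reps)
        assert abs(np.mean(diffs) - L * d) < 3 * se


class TestApplyEvent:
    def test_tandem_copies_adjacent(self):
        spec = SimulationSpec(
            seed=2, n_chromosomes=1, n_genes=10, protein_length=(50, 70), family_size=0,
            events=(Event("tandem_duplication", "chr1", 3, 5, divergence=0.05),),
        )
        genome = build_genome(spec)
        genes = [g.id for g in genome.chromosomes["chr1"]]
        assert len(genes) == 12
        # copies inserted immediately downstream of the duplicated span
        assert genes[5] == genes[3] + ".c1" and genes[6] == genes[4] + ".c2"
        assert genome.truth.ortholog_pairs == [
            (genes[3], genes[5]), (genes[4], genes[6])
        ]

    def test_segmental_without_loss_keeps_all_pairs(self):
        spec = SimulationSpec(
            seed=3, n_chromosomes=1, n_genes=30, protein_length=(50, 70), family_size=0,
            events=(Event("segmental_duplication", "chr1", 5, 25, divergence=0.1),),
        )
        genome = build_genome(spec)
        assert len(genome.truth.ortholog_pairs) == 20
        ((ca, span_a), (cb, span_b)) = genome.truth.planted_blocks[0]
        assert ca == "chr1" and span_a == (5, 24)
        assert len(genome.chromosomes[cb]) == 20

    def test_segmental_loss_is_binomial(self):
        """Across 300 replicate genomes with gene_loss 0.2 on a 20-gene span,
        the mean surviving pair count matches 16 within 3 standard errors."""
        survivors = []
        for seed in range(300):
            spec = SimulationSpec(
                seed=seed, n_chromosomes=1, n_genes=25, protein_length=(5, 10),
                family_size=0,
                events=(Event("segmental_duplication", "chr1", 0, 20,
                              divergence=0.0, gene_loss=0.2),),
            )
            survivors.append(len(build_genome(spec).truth.ortholog_pairs))
        se = np.sqrt(20 * 0.2 * 0.8 / 300)
        assert abs(np.mean(survivors) - 16.0) < 3 * se

    def test_translocation_preserves_content_and_span_order(self):
        spec = SimulationSpec(
            seed=4, n_chromosomes=1, n_genes=12, protein_length=(50, 60), family_size=0,
        )
        base = build_genome(spec)
        ids_before = [g.id for g in base.chromosomes["chr1"]]
        spec2 = SimulationSpec(
            seed=4, n_chromosomes=1, n_genes=12, protein_length=(50, 60), family_size=0,
            events=(Event("translocation", "chr1", 2, 6),),
        )
        moved = build_genome(spec2)
        ids_after = [g.id for g in moved.chromosomes["chr1"]]
        assert sorted(ids_after) == sorted(ids_before)
        span = ids_before[2:6]
        idx = ids_after.index(span[0])
        assert ids_after[idx : idx + 4] == span

    def test_region_overflow_rejected(self):
        spec = SimulationSpec(
            seed=1, n_chromosomes=1, n_genes=5, protein_length=(50, 60), family_size=0,
            events=(Event("tandem_duplication", "chr1", 2, 9),),
        )
        with pytest.raises(ValidationError):
            build_genome(spec)


class TestEmitFixture:
    @pytest.fixture
    def spec(self):
        return SimulationSpec(
            seed=11, n_chromosomes=2, n_genes=15, protein_length=(60, 90), family_size=3,
            events=(Event("segmental_duplication", "chr1", 2, 10, divergence=0.15),),
        )

    def test_roundtrip_equality(self, spec, tmp_path):
        paths = emit_fixture(spec, tmp_path)
        genome = build_genome(spec)
        annotation = genome.annotation()
        back_ann = read_gff3(paths["annotation"])
        assert set(back_ann.index) == set(annotation.index)
        for gid in annotation.index:
            a, b = annotation.gene(gid), back_ann.gene(gid)
            assert (a.chromosome, a.strand, a.start, a.end, a.exons) == (
                b.chromosome, b.strand, b.start, b.end, b.exons
            )
        back_prot = {s.id: s.residues for s in read_fasta(paths["proteome"])}
        assert back_prot == {pid: s.residues for pid, s in genome.proteome.items()}

    def test_same_seed_byte_identical(self, spec, tmp_path):
        p1 = emit_fixture(spec, tmp_path / "a")
        p2 = emit_fixture(spec, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_truth_observation_consistency(self):
        """Planted ortholog pairs at divergence <= 0.3 and length >= 200 all
        align with E <= 1e-5 (checked over 20 seeds)."""
        for seed in range(20):
            spec = SimulationSpec(
                seed=seed, n_chromosomes=1, n_genes=6, protein_length=(200, 260),
                family_size=0,
                events=(Event("segmental_duplication", "chr1", 0, 4, divergence=0.3),),
            )
            genome = build_genome(spec)
            prot = genome.proteome
            for a, b in genome.truth.ortholog_pairs:
                table = all_vs_all([prot[a]], [prot[b]], SearchParams())
                assert len(table) == 1 and table.hits[0].evalue <= 1e-5
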