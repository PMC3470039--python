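"""Synthetic genomes with planted duplication events and machine-readable truth.

The generator emulates the evolutionary situations that shape a small
plant gene family spread over a few chromosomes:

- a *tandem duplication* placing a diverged copy of a segment immediately
  downstream of the original (recent paralogs that are neighboring genes);
- a *segmental / whole-genome duplication* copying a long gene run onto a
  new chromosome, with per-gene loss and sequence divergence (older
  paralogs whose neighborhoods are still collinear);
- *translocation* and *shuffle* events that destroy gene order without
  destroying gene content — the negative controls for collinearity.

Every planted event is recorded in a :class:`SyntheticTruth` object
(ortholog pairs, block coordinates, family members, conserved exon sizes)
so that detection can be scored exactly. Substitutions use uniform
replacement by a different residue, which keeps the identity-divergence
relation analytic: expected percent identity after divergence ``d`` is
``100*(1-d)``. All randomness flows from one integer seed through numpy's
PCG64 generator; equal seeds give byte-identical fixtures.

Gene models carry exon structures drawn from a small template library.
Family members share a 9-exon template with conserved internal exon sizes
(80, 125, 122, 93, 101 nt) and a conserved terminal exon (125 nt);
intergenic spacing is fixed at 1 kb and introns at 100 nt, since gene
ordinals — not physical distance — drive all downstream detection.
Protein sequences are simulated independently of the nucleotide-level
exon layout (no codon model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .genome_io import (
    GeneModel,
    GenomeAnnotation,
    ProteinSequence,
    write_fasta,
    write_gff3,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Robinson–Robinson amino-acid background frequencies (normalized).
BACKGROUND_FREQS = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}
_FREQ_VECTOR = np.array([BACKGROUND_FREQS[a] for a in AMINO_ACIDS])
_FREQ_VECTOR = _FREQ_VECTOR / _FREQ_VECTOR.sum()

INTRON_LENGTH = 100
INTERGENIC_SPACING = 1000

#: 9-exon family template: internal exons 2-6 (1-based) and the terminal
#: exon carry the conserved sizes; the others vary per gene.
FAMILY_TEMPLATE = (150, 80, 125, 122, 93, 101, 160, 140, 125)
FAMILY_CONSERVED_ORDINALS = (1, 2, 3, 4, 5, 8)  # 0-based within the template
FAMILY_VARIABLE_ORDINALS = (0, 6, 7)


@dataclass(frozen=True)
class Event:
    """One planted evolutionary event, applied to an ordinal span of genes."""

    kind: str  # tandem_duplication | segmental_duplication | translocation | shuffle
    chromosome: str
    start: int  # 0-based ordinal, inclusive
    end: int  # 0-based ordinal, exclusive
    divergence: float = 0.1
    gene_loss: float = 0.0

    def __post_init__(self) -> None:
        kinds = ("tandem_duplication", "segmental_duplication", "translocation", "shuffle")
        if self.kind not in kinds:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if not (0 <= self.divergence < 1) or not (0 <= self.gene_loss < 1):
            raise ValidationError("divergence and gene_loss must be in [0, 1)")
        if self.start < 0 or self.end <= self.start:
            raise ValidationError("event span must be non-empty and non-negative")


@dataclass(frozen=True)
class SimulationSpec:
    """Genome shape, planted family, and the ordered event list."""

    seed: int = 0
    n_chromosomes: int = 3
    n_genes: int = 60
    protein_length: tuple[int, int] = (200, 300)
    family_size: int = 7
    family_divergence: float = 0.30
    events: tuple[Event, ...] = ()

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.n_genes) < 1 or self.family_size < 0:
            raise ValidationError("counts must be positive")
        lo, hi = self.protein_length
        if not (1 <= lo <= hi):
            raise ValidationError("protein_length must satisfy 1 <= min <= max")
        if self.family_size > self.n_chromosomes * self.n_genes:
            raise ValidationError("family larger than genome")


@dataclass
class SyntheticTruth:
    """Everything that was planted, for scoring detection against."""

    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_blocks: list[tuple[tuple[str, tuple[int, int]], tuple[str, tuple[int, int]]]] = field(
        default_factory=list
    )
    family_members: list[str] = field(default_factory=list)
    conserved_exon_plants: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class _GeneSeed:
    """Pre-layout gene record: structure and protein, no coordinates yet."""

    id: str
    exon_lengths: tuple[int, ...]
    strand: str
    protein: ProteinSequence


@dataclass
class SyntheticGenome:
    """Mutable genome state: ordered gene seeds per chromosome plus truth."""

    chromosomes: dict[str, list[_GeneSeed]]
    truth: SyntheticTruth
    _copy_counter: int = 0

    @property
    def proteome(self) -> dict[str, ProteinSequence]:
        return {
            seed.protein.id: seed.protein
            for genes in self.chromosomes.values()
            for seed in genes
        }

    def annotation(self) -> GenomeAnnotation:
        """Lay out coordinates (1 kb spacing, 100 nt introns) and freeze."""
        models = []
        for chrom in self.chromosomes:
            cursor = 1
            for seed in self.chromosomes[chrom]:
                exons = []
                pos = cursor
                # templates are in transcription order; minus-strand genes
                # are laid out reversed so the 5' exon sits at the high end
                laid = seed.exon_lengths if seed.strand == "+" else seed.exon_lengths[::-1]
                for length in laid:
                    exons.append((pos, pos + length - 1))
                    pos += length + INTRON_LENGTH
                end = exons[-1][1]
                models.append(
                    GeneModel(
                        id=seed.id,
                        chromosome=chrom,
                        strand=seed.strand,
                        start=cursor,
                        end=end,
                        exons=exons,
                        protein_id=seed.protein.id,
                    )
                )
                cursor = end + INTERGENIC_SPACING + 1
        return GenomeAnnotation(models)


def _random_residues(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=_FREQ_VECTOR)
    return "".join(AMINO_ACIDS[i] for i in idx)


def random_proteome(spec: SimulationSpec) -> list[ProteinSequence]:
    """I.i.d. background-frequency proteins, one per gene slot of the spec."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.protein_length
    out = []
    for c in range(1, spec.n_chromosomes + 1):
        for g in range(spec.n_genes):
            length = int(rng.integers(lo, hi + 1))
            out.append(
                ProteinSequence(f"chr{c}g{g:04d}", _random_residues(rng, length))
            )
    return out


def diverge_sequence(
    seq: ProteinSequence, d: float, seed: int | np.random.Generator, new_id: str | None = None
) -> ProteinSequence:
    """Independently substitute each site with probability ``d``.

    Replacements are uniform over the 19 other canonical residues, so the
    expected fraction of changed sites is exactly ``d``.
    """
    if not (0 <= d < 1):
        raise ValidationError("divergence must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    residues = list(seq.residues)
    hit_mask = rng.random(len(residues)) < d
    for i in np.nonzero(hit_mask)[0]:
        current = residues[i]
        choices = [a for a in AMINO_ACIDS if a != current]
        residues[i] = choices[int(rng.integers(len(choices)))]
    return ProteinSequence(new_id or seq.id, "".join(residues), seq.description)


def _random_exon_template(rng: np.random.Generator) -> tuple[int, ...]:
    n = int(rng.integers(1, 13))
    return tuple(int(rng.integers(50, 401)) for _ in range(n))


def _copy_gene(
    genome: SyntheticGenome, seed: _GeneSeed, d: float, rng: np.random.Generator
) -> _GeneSeed:
    genome._copy_counter += 1
    new_id = f"{seed.id}.c{genome._copy_counter}"
    return _GeneSeed(
        id=new_id,
        exon_lengths=seed.exon_lengths,
        strand=seed.strand,
        protein=diverge_sequence(seed.protein, d, rng, new_id=new_id),
    )


def apply_event(genome: SyntheticGenome, event: Event, rng: np.random.Generator) -> None:
    """Apply one planted event in place, recording its truth."""
    if event.chromosome not in genome.chromosomes:
        raise ValidationError(f"unknown chromosome {event.chromosome!r}")
    genes = genome.chromosomes[event.chromosome]
    if event.end > len(genes):
        raise ValidationError(
            f"event span {event.start}..{event.end} overflows chromosome "
            f"{event.chromosome!r} ({len(genes)} genes)"
        )
    span = genes[event.start : event.end]

    if event.kind == "tandem_duplication":
        copies = [_copy_gene(genome, g, event.divergence, rng) for g in span]
        genome.chromosomes[event.chromosome] = (
            genes[: event.end] + copies + genes[event.end :]
        )
        genome.truth.ortholog_pairs += [(g.id, c.id) for g, c in zip(span, copies)]

    elif event.kind == "segmental_duplication":
        survivors: list[_GeneSeed] = []
        pairs: list[tuple[str, str]] = []
        for g in span:
            if rng.random() < event.gene_loss:
                continue
            c = _copy_gene(genome, g, event.divergence, rng)
            survivors.append(c)
            pairs.append((g.id, c.id))
        new_chrom = f"{event.chromosome}_seg{len(genome.truth.planted_blocks) + 1}"
        genome.chromosomes[new_chrom] = survivors
        genome.truth.ortholog_pairs += pairs
        genome.truth.planted_blocks.append(
            (
                (event.chromosome, (event.start, event.end - 1)),
                (new_chrom, (0, max(len(survivors) - 1, 0))),
            )
        )

    elif event.kind == "translocation":
        rest = genes[: event.start] + genes[event.end :]
        insert_at = int(rng.integers(0, len(rest) + 1))
        genome.chromosomes[event.chromosome] = (
            rest[:insert_at] + span + rest[insert_at:]
        )

    elif event.kind == "shuffle":
        perm = rng.permutation(len(genes))
        genome.chromosomes[event.chromosome] = [genes[i] for i in perm]


def build_genome(spec: SimulationSpec) -> SyntheticGenome:
    """Generate the base genome, plant the family, then apply the events.

    Family members are diverged copies of one founder protein (pairwise
    expected identity about ``100*(1-d)^2`` for family divergence ``d``),
    placed at deterministic, spread-out positions and given the conserved
    9-exon family template with per-member variation of the non-conserved
    exons. All other genes get random proteins and random exon templates.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.protein_length
    genome = SyntheticGenome(chromosomes={}, truth=SyntheticTruth())

    for c in range(1, spec.n_chromosomes + 1):
        chrom = f"chr{c}"
        genes = []
        for g in range(spec.n_genes):
            gene_id = f"{chrom}g{g:04d}"
            length = int(rng.integers(lo, hi + 1))
            genes.append(
                _GeneSeed(
                    id=gene_id,
                    exon_lengths=_random_exon_template(rng),
                    strand="+" if rng.random() < 0.5 else "-",
                    protein=ProteinSequence(gene_id, _random_residues(rng, length)),
                )
            )
        genome.chromosomes[chrom] = genes

    if spec.family_size:
        founder = _random_residues(rng, int(rng.integers(lo, hi + 1)))
        founder_seq = ProteinSequence("founder", founder)
        # Spread members round-robin over chromosomes (random position within
        # each), mirroring a dispersed family; dispersal also keeps anchor
        # neighborhoods disjoint unless an event makes them overlap.
        slots: list[tuple[str, int]] = []
        used: dict[str, set[int]] = {}
        for k in range(spec.family_size):
            chrom = f"chr{k % spec.n_chromosomes + 1}"
            taken = used.setdefault(chrom, set())
            free = [g for g in range(spec.n_genes) if g not in taken]
            g = free[int(rng.integers(len(free)))]
            taken.add(g)
            slots.append((chrom, g))
        for chrom, g in sorted(slots):
            target = genome.chromosomes[chrom][g]
            lengths = list(FAMILY_TEMPLATE)
            for ordinal in FAMILY_VARIABLE_ORDINALS:
                lengths[ordinal] = int(rng.integers(100, 301))
            member = _GeneSeed(
                id=target.id,
                exon_lengths=tuple(lengths),
                strand=target.strand,
                protein=diverge_sequence(
                    founder_seq, spec.family_divergence, rng, new_id=target.id
                ),
            )
            genome.chromosomes[chrom][g] = member
            genome.truth.family_members.append(target.id)
        genome.truth.conserved_exon_plants = [
            (ordinal, FAMILY_TEMPLATE[ordinal]) for ordinal in FAMILY_CONSERVED_ORDINALS
        ]

    for event in spec.events:
        apply_event(genome, event, rng)
    return genome


#: Tree of the emulated seven-member family: three subgroups (one recent
#: pair, one middle pair, one deep pair) with per-branch substitution
#: probabilities. Chosen to reproduce the identity structure typical of a
#: small plant gene family: a very recent duplicate pair (~82% identity),
#: its sibling (~69%), a mid-depth pair (~64%) and a deeply diverged pair
#: (~39%), with cross-subgroup identities in the 20-30% range.
FAMILY_TREE_ROOT_D = {"sub134": 0.40, "sub57": 0.30, "sub26": 0.30}
FAMILY_TREE_TIP_D = {
    "m1": ("sub134", 0.24), "m3": ("sub134", 0.095), "m4": ("sub134", 0.095),
    "m5": ("sub57", 0.20), "m7": ("sub57", 0.20),
    "m2": ("sub26", 0.38), "m6": ("sub26", 0.38),
}


def family_alignment(seed: int = 0, length: int = 5000):
    """Synthetic gap-free family alignment with closed-form identities.

    Seven members are produced by tree-structured divergence from one
    ancestral protein (subgroups ``FAMILY_TREE_*``). Because substitution
    is uniform replacement, every pairwise identity has an exact
    expectation: for two sequences at divergences d1, d2 from their last
    common ancestor, P(site equal) = (1-d1)(1-d2) + d1*d2/19. Returns
    ``(Msa, expected)`` where ``expected`` maps each unordered id pair to
    its expected percent identity.
    """
    from .genome_io import Msa  # local import: Msa lives with the IO types

    rng = np.random.default_rng(seed)
    ancestor = ProteinSequence("ancestor", _random_residues(rng, length))
    sub = {
        name: diverge_sequence(ancestor, d, rng, new_id=name)
        for name, d in FAMILY_TREE_ROOT_D.items()
    }
    seqs = {
        tip: diverge_sequence(sub[parent], d, rng, new_id=tip)
        for tip, (parent, d) in FAMILY_TREE_TIP_D.items()
    }

    def path_d(tip: str) -> float:
        # composition of two uniform-substitution steps root -> sub -> tip
        parent, d = FAMILY_TREE_TIP_D[tip]
        dr = FAMILY_TREE_ROOT_D[parent]
        return dr + d - dr * d * (20 / 19)

    def expected_identity(t1: str, t2: str) -> float:
        if FAMILY_TREE_TIP_D[t1][0] == FAMILY_TREE_TIP_D[t2][0]:
            d1, d2 = FAMILY_TREE_TIP_D[t1][1], FAMILY_TREE_TIP_D[t2][1]
        else:
            d1, d2 = path_d(t1), path_d(t2)
        return 100.0 * ((1 - d1) * (1 - d2) + d1 * d2 / 19)

    order = sorted(FAMILY_TREE_TIP_D)
    msa = Msa(order, [seqs[t].residues for t in order])
    expected = {
        (a, b): expected_identity(a, b)
        for i, a in enumerate(order)
        for b in order[i + 1 :]
    }
    return msa, expected


def emit_fixture(spec: SimulationSpec, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + GFF3 + truth TSVs for a spec; byte-stable per seed.

    Returns the paths written. Files parse back through ``genome_io`` into
    objects equal to the in-memory ones.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = build_genome(spec)
    annotation = genome.annotation()
    proteome = genome.proteome

    paths = {
        "proteome": outdir / "proteome.fasta",
        "annotation": outdir / "annotation.gff3",
        "ortholog_pairs": outdir / "truth_ortholog_pairs.tsv",
        "blocks": outdir / "truth_blocks.tsv",
        "family": outdir / "truth_family.tsv",
        "exon_plants": outdir / "truth_exon_plants.tsv",
    }
    ordered_ids = [g.protein_id for g in annotation.genes()]
    write_fasta([proteome[pid] for pid in ordered_ids], paths["proteome"])
    write_gff3(annotation, paths["annotation"])
    truth = genome.truth
    with open(paths["ortholog_pairs"], "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in truth.ortholog_pairs:
            fh.write(f"{a}\t{b}\n")
    with open(paths["blocks"], "w") as fh:
        fh.write("chrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\n")
        for (ca, (sa, ea)), (cb, (sb, eb)) in truth.planted_blocks:
            fh.write(f"{ca}\t{sa}\t{ea}\t{cb}\t{sb}\t{eb}\n")
    with open(paths["family"], "w") as fh:
        fh.write("gene_id\n")
        for m in truth.family_members:
            fh.write(m + "\n")
    with open(paths["exon_plants"], "w") as fh:
        fh.write("ordinal\tlength\n")
        for ordinal, length in truth.conserved_exon_plants:
            fh.write(f"{ordinal}\t{length}\n")
    return paths
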