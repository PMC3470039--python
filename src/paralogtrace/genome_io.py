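"""Readers and writers for the external formats the pipeline touches.

Formats supported: protein FASTA (sequences and alignments), GFF3 gene
annotations, and the 12-column blast-tabular TSV dialect used to exchange
homology hits. All readers validate strictly: duplicate ids, gap characters
in unaligned sequences, ragged alignment rows and exons outside their gene
span are rejected rather than silently repaired.

Coordinates follow the GFF3 standard (1-based, inclusive) everywhere in
this module; window arithmetic elsewhere in the package uses 0-based gene
ordinals only, which are assigned here per chromosome in start order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, LookupError_, ValidationError

#: The 20 canonical amino acids plus X (unknown). X never counts as an
#: identity match anywhere downstream.
RESIDUE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
GAP = "-"

HIT_COLUMNS = [
    "query",
    "subject",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20 amino-acid letters plus X."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - RESIDUE_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """One gene locus: span, strand and ordered exon coordinates (1-based)."""

    id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.id!r}: unknown strand {self.strand!r}")
        if self.start > self.end:
            raise ValidationError(f"gene {self.id!r}: start > end")
        self.exons = sorted(self.exons)
        prev_end = 0
        for (s, e) in self.exons:
            if s > e:
                raise ValidationError(f"gene {self.id!r}: exon start > end")
            if s < self.start or e > self.end:
                raise ValidationError(
                    f"gene {self.id!r}: exon {s}-{e} outside gene span "
                    f"{self.start}-{self.end}"
                )
            if s <= prev_end:
                raise ValidationError(f"gene {self.id!r}: overlapping exons")
            prev_end = e

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


class GenomeAnnotation:
    """Ordered gene models per chromosome with an id -> (chromosome, ordinal) index.

    Ordinals are 0-based and contiguous per chromosome, in start-coordinate
    order; they are the unit of distance for neighborhood windows.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self.chromosomes: dict[str, list[GeneModel]] = {}
        for g in genes:
            self.chromosomes.setdefault(g.chromosome, []).append(g)
        for chrom in self.chromosomes:
            self.chromosomes[chrom].sort(key=lambda g: (g.start, g.id))
        self.index: dict[str, tuple[str, int]] = {}
        for chrom, models in self.chromosomes.items():
            for i, g in enumerate(models):
                if g.id in self.index:
                    raise ValidationError(f"duplicate gene id {g.id!r}")
                self.index[g.id] = (chrom, i)

    def __len__(self) -> int:
        return len(self.index)

    def gene(self, gene_id: str) -> GeneModel:
        try:
            chrom, i = self.index[gene_id]
        except KeyError:
            raise LookupError_(f"unknown gene id {gene_id!r}") from None
        return self.chromosomes[chrom][i]

    def genes(self) -> Iterable[GeneModel]:
        for chrom in sorted(self.chromosomes):
            yield from self.chromosomes[chrom]


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length rows over residues plus '-'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValidationError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate ids in alignment")
        if not self.rows:
            raise ValidationError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment rows (lengths {sorted(lengths)})")
        if self.n_columns < 1:
            raise ValidationError("alignment has zero columns")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise LookupError_(f"unknown sequence id {seq_id!r}") from None


@dataclass
class HitTable:
    """A set of scored pairwise matches in blast-tabular form."""

    hits: list  # list[pairwise_align.HomologyHit]

    def __len__(self) -> int:
        return len(self.hits)

    def by_query(self, query_id: str) -> list:
        return [h for h in self.hits if h.query_id == query_id]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.hits:
            rows.append(
                {
                    "query": h.query_id,
                    "subject": h.subject_id,
                    "pct_identity": round(100.0 * h.identities / h.aln_length, 2)
                    if h.aln_length
                    else 0.0,
                    "aln_length": h.aln_length,
                    "mismatches": h.aln_length
                    - h.identities
                    - h.gap_columns,
                    "gap_opens": h.gap_opens,
                    "qstart": h.q_span[0],
                    "qend": h.q_span[1],
                    "sstart": h.s_span[0],
                    "send": h.s_span[1],
                    "evalue": h.evalue,
                    "bitscore": round(h.bitscore, 1),
                }
            )
        return pd.DataFrame(rows, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a protein FASTA file into validated :class:`ProteinSequence` records.

    Order is preserved, wrapped records are concatenated and lowercase
    residues are upcased. Duplicate ids and gap characters are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    seen: set[str] = set()
    out: list[ProteinSequence] = []
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if GAP in residues or "." in residues:
            raise ValidationError(f"{path}: gap characters in sequence {rec.id!r}")
        out.append(ProteinSequence(rec.id, residues, rec.description))
    return out


def write_fasta(seqs: Sequence[ProteinSequence], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description) for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Alignments


def read_msa(path: str | Path) -> Msa:
    """Read an aligned FASTA file; all rows must have equal length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    ids = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]
    return Msa(ids, rows)


def write_msa(msa: Msa, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq_id, row in zip(msa.ids, msa.rows):
            fh.write(f">{seq_id}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _best_isoform(exon_sets: dict[str, list[tuple[int, int]]]) -> list[tuple[int, int]]:
    """Pick one isoform: most exons, then longest spliced length, then id."""

    def key(item):
        mrna_id, exons = item
        spliced = sum(e - s + 1 for s, e in exons)
        return (-len(exons), -spliced, mrna_id)

    return sorted(exon_sets.items(), key=key)[0][1]


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Read a GFF3 annotation into a :class:`GenomeAnnotation`.

    Exons may hang off genes directly or through mRNA features
    (gene -> mRNA -> exon). For multi-isoform genes the isoform with the
    most exons is retained (ties: longest spliced length, then
    lexicographically smallest mRNA id). A ``protein_id`` attribute on the
    gene (or its chosen mRNA) links the model to a protein sequence;
    without one the gene id is used.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted low-level errors
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            raise ValidationError(
                f"{path}: gene {gene.id!r} has unknown strand {gene.strand!r}"
            )
        exon_sets: dict[str, list[tuple[int, int]]] = {}
        direct = [
            (f.start, f.end) for f in db.children(gene, featuretype="exon", level=1)
        ]
        if direct:
            exon_sets[gene.id] = direct
        for mrna in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
            exons = [
                (f.start, f.end)
                for f in db.children(mrna, featuretype="exon", level=1)
            ]
            if exons:
                exon_sets[mrna.id] = exons
        exons = _best_isoform(exon_sets) if exon_sets else [(gene.start, gene.end)]
        protein_id = gene.attributes.get("protein_id", [gene.id])[0]
        genes.append(
            GeneModel(
                id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=exons,
                protein_id=protein_id,
            )
        )
    if not genes:
        raise FormatError(f"{path}: no gene features found")
    return GenomeAnnotation(genes)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write an annotation as GFF3 (gene -> mRNA -> exon), deterministically."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chromosomes):
            for g in annotation.chromosomes[chrom]:
                attrs = f"ID={g.id}"
                if g.protein_id:
                    attrs += f";protein_id={g.protein_id}"
                fh.write(
                    f"{chrom}\tparalogtrace\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                mrna_id = f"{g.id}.1"
                fh.write(
                    f"{chrom}\tparalogtrace\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id};Parent={g.id}\n"
                )
                for k, (s, e) in enumerate(g.exons, 1):
                    fh.write(
                        f"{chrom}\tparalogtrace\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={mrna_id}.exon{k};Parent={mrna_id}\n"
                    )


# ---------------------------------------------------------------------------
# Blast-tabular hit tables


def read_hits(path: str | Path) -> HitTable:
    """Read a 12-column blast-tabular TSV into a :class:`HitTable`."""
    from .pairwise_align import HomologyHit  # deferred: avoids import cycle

    try:
        frame = pd.read_csv(
            str(path), sep="\t", header=None, names=HIT_COLUMNS, dtype=str
        )
    except Exception as exc:
        raise FormatError(f"{path}: not readable as TSV ({exc})") from exc
    if frame.shape[1] != 12:
        raise FormatError(f"{path}: expected 12 columns, got {frame.shape[1]}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip() and len(line.rstrip("\n").split("\t")) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns")
    hits = []
    seen: set[tuple] = set()
    for row in frame.itertuples(index=False):
        try:
            aln_length = int(row.aln_length)
            identities = int(round(float(row.pct_identity) / 100.0 * aln_length))
            hit = HomologyHit(
                query_id=row.query,
                subject_id=row.subject,
                raw_score=0,
                bitscore=float(row.bitscore),
                evalue=float(row.evalue),
                identities=identities,
                aln_length=aln_length,
                q_span=(int(row.qstart), int(row.qend)),
                s_span=(int(row.sstart), int(row.send)),
                gap_opens=int(row.gap_opens),
                gap_columns=aln_length - identities - int(row.mismatches),
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed row {tuple(row)} ({exc})") from exc
        key = (hit.query_id, hit.subject_id, hit.q_span, hit.s_span)
        if key in seen:
            raise ValidationError(f"{path}: duplicate hit row {key}")
        seen.add(key)
        hits.append(hit)
    return HitTable(hits)


def write_hits(table: HitTable, path: str | Path) -> None:
    """Write a :class:`HitTable` as 12-column blast-tabular TSV (no header)."""
    frame = table.to_frame()
    buf = io.StringIO()
    frame.to_csv(buf, sep="\t", header=False, index=False, float_format="%.6g")
    Path(path).write_text(buf.getvalue())
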