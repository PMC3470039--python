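"""Exon/intron architecture comparison across a gene set.

Gene families often preserve exon sizes and counts long after sequences
diverge, so shared architecture is independent evidence of common origin.
This module extracts per-gene exon-length profiles (5'->3' in
transcription orientation), finds groups of genes sharing an exon of the
same size at the same position, and classifies genes into the two broad
architectures seen in the family studied here: compact genes with few
exons (1-3, including intronless genes) and multi-exon genes (7-12).

Exon positions are compared anchored from the 5' end, with an additional
pass anchored from the 3' end for the terminal exon: the last exon can be
conserved (it often encodes a terminal transmembrane domain) even when
upstream exon counts differ between genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .genome_io import GeneModel, GenomeAnnotation


@dataclass(frozen=True)
class ExonStructure:
    """Ordered exon lengths of one gene, 5' to 3'."""

    gene_id: str
    exon_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.exon_lengths:
            raise ValidationError(f"gene {self.gene_id!r} has no exons")
        if any(l <= 0 for l in self.exon_lengths):
            raise ValidationError(f"gene {self.gene_id!r} has non-positive exon length")

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)


@dataclass(frozen=True)
class ConservedExonGroup:
    """Genes sharing an exon of (near-)equal length at the same position.

    ``anchoring_end`` records whether the shared ordinal was counted from
    the 5' end ("5prime", ordinal 0-based) or from the 3' end ("3prime",
    terminal exon).
    """

    members: tuple[tuple[str, int], ...]  # (gene_id, 0-based 5'-anchored ordinal)
    length: int
    anchoring_end: str
    tolerance: int


@dataclass(frozen=True)
class StructureClassParams:
    """Exon-count boundaries of the two architecture classes."""

    compact_max: int = 3
    multi_min: int = 7

    def __post_init__(self) -> None:
        if self.compact_max >= self.multi_min:
            raise ValidationError("compact_max must be < multi_min")


def exon_profile(gene: GeneModel) -> ExonStructure:
    """Exon lengths in transcription order (minus-strand genes reversed)."""
    if not gene.exons:
        raise ValidationError(f"gene {gene.id!r} has no exons")
    lengths = [e - s + 1 for s, e in gene.exons]
    if gene.strand == "-":
        lengths.reverse()
    return ExonStructure(gene_id=gene.id, exon_lengths=tuple(lengths))


def count_exons(gene: GeneModel) -> int:
    """Number of exons of the gene's retained isoform."""
    return exon_profile(gene).n_exons


def _clusters(items: list[tuple[str, int, int]], tolerance: int) -> list[list[tuple[str, int, int]]]:
    """Greedy length clustering: sorted lengths, split when the running
    cluster would span more than 2*tolerance."""
    out: list[list[tuple[str, int, int]]] = []
    for item in sorted(items, key=lambda t: (t[2], t[0])):
        if out and item[2] - out[-1][0][2] <= 2 * tolerance:
            out[-1].append(item)
        else:
            out.append([item])
    return out


def conserved_exon_groups(
    structures: Sequence[ExonStructure],
    tolerance: int = 0,
    min_members: int = 4,
) -> list[ConservedExonGroup]:
    """Find exon sizes conserved across genes at the same exon position.

    One pass groups exons by 0-based ordinal from the 5' end; a second
    pass groups terminal exons (3'-anchored), catching last-exon
    conservation between genes of unequal exon counts. Groups reaching
    ``min_members`` are reported, largest first; duplicates between the
    two passes (identical member exon sets) are merged into the 5' pass.
    """
    if len(structures) < 2:
        raise ValidationError("need at least two structures")
    if min_members < 2:
        raise ValidationError("min_members must be >= 2")
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    groups: list[ConservedExonGroup] = []
    seen_member_sets: set[frozenset] = set()

    def emit(items: list[tuple[str, int, int]], anchoring_end: str) -> None:
        for cluster in _clusters(items, tolerance):
            if len(cluster) < min_members:
                continue
            members = tuple(sorted((gid, ordinal) for gid, ordinal, _ in cluster))
            key = frozenset(members)
            if key in seen_member_sets:
                continue
            seen_member_sets.add(key)
            lengths = [l for _, _, l in cluster]
            groups.append(
                ConservedExonGroup(
                    members=members,
                    length=int(round(sum(lengths) / len(lengths))),
                    anchoring_end=anchoring_end,
                    tolerance=tolerance,
                )
            )

    max_ordinal = max(s.n_exons for s in structures)
    for ordinal in range(max_ordinal):
        items = [
            (s.gene_id, ordinal, s.exon_lengths[ordinal])
            for s in structures
            if ordinal < s.n_exons
        ]
        emit(items, "5prime")
    last_items = [(s.gene_id, s.n_exons - 1, s.exon_lengths[-1]) for s in structures]
    emit(last_items, "3prime")
    groups.sort(key=lambda g: (-len(g.members), g.length))
    return groups


def classify_structure(
    structure: ExonStructure, p: StructureClassParams = StructureClassParams()
) -> str:
    """Architecture class from the exon count: compact / multi / other."""
    if structure.n_exons <= p.compact_max:
        return "compact"
    if structure.n_exons >= p.multi_min:
        return "multi"
    return "other"


def structure_table(
    annotation: GenomeAnnotation, p: StructureClassParams = StructureClassParams()
) -> pd.DataFrame:
    """Per-gene structure summary for export (TSV-friendly)."""
    rows = []
    for gene in annotation.genes():
        s = exon_profile(gene)
        rows.append(
            {
                "gene_id": gene.id,
                "n_exons": s.n_exons,
                "exon_lengths": ",".join(map(str, s.exon_lengths)),
                "class": classify_structure(s, p),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_exons", "exon_lengths", "class"])
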