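# Methods

## The question and the model

A small gene family dispersed over a few chromosomes can have several
origins per member pair: a recent tandem duplication (the copy sits next
to the original), an older segmental or whole-genome duplication (the
copies sit in large regions that still share gene content and order), or
independent/ancient divergence (no shared neighborhood signal). The
package operationalizes the classical dot-plot argument: if two anchors
descend from one duplicated segment, the genes surrounding them form
matching runs — a diagonal in the matrix of neighborhood-vs-neighborhood
homology scores. Isolated homology between the anchors themselves (they
are family members, so it is always there) carries no positional
information and must not count.

## Pairwise alignment and significance

Neighborhood comparison needs thousands of protein-vs-protein scores per
anchor pair. Exact affine-gap dynamic programming (Smith–Waterman for
searches, Needleman–Wunsch with penalized end gaps for whole-sequence
identity) replaces heuristic seeded search: the windows are small, so
optimality is affordable and there is no seeding nondeterminism. The DP
engine is Biopython's C `PairwiseAligner`; the package fixes the scoring
model around it:

- BLOSUM62, with the X row/column forced to 0 so unknown residues are
  neutral and never count as identities;
- NCBI gap convention: a gap of length k costs `gap_open + k·gap_extend`
  (defaults 11, 1 — i.e. 12 for the first gapped residue);
- Karlin–Altschul significance `E = K·m·n·e^(−λS)` with the published
  gapped BLOSUM62-11-1 constants λ = 0.267, K = 0.041; the database size
  n is the residue total of the searched set, recomputed per search
  direction exactly as blast does, so the two directions of a reciprocal
  search give different E-values for the same pair.

Correctness of both aligner modes is checked against an independent
brute-force oracle that enumerates every gapped alignment of short
sequences (lengths ≤ 5) and scores each one from the same convention.
When several tracebacks are co-optimal, the aligner's first reported
traceback is used; this is deterministic for fixed inputs. Only the
reported identity/span decomposition can differ between co-optimal
tracebacks, never the score, E-value or any verdict derived from them.

## Collinearity calling

Parameters (defaults in brackets):

- `window_size` [200 genes]: up to half on each side of the anchor, in
  ordinal (gene-rank) order, truncated at chromosome ends. Gene ordinals,
  not physical distance, are the unit throughout.
- `evalue_threshold` [1e-5]: a standard homology-screen cutoff; cells of
  the neighborhood matrix are min(−log₁₀E, 200).
- `max_chain_gap` [5]: the largest ordinal jump on either axis between
  consecutive chained hits; absorbs local gene loss and small insertions.
- `min_block_hits` [3] and `high_block_hits` [10]: a chain must have ≥ 3
  hits to be reported at all (so the lone anchor-anchor hit can never
  constitute collinearity) and ≥ 10 for the high-confidence verdict.
  "High diagonal homology" has no canonical numeric definition; these
  thresholds make it operational and are reported with every call.
- `allow_inversions` [true]: anti-diagonal chains are detected too, since
  inversions are common after duplication.

Chaining is sparse dynamic programming over hits sorted by row ordinal; a
hit extends a chain when both ordinal deltas lie in [1, max_chain_gap]
with a consistent orientation. The DP tracks, for each hit, the best
score per chain-length class capped at `min_block_hits`: this guarantees
the best *eligible* chain is found even when a single high-scoring hit
outscores every chain long enough to count (the capped-length DP exists
precisely for that case, which exhaustive-enumeration testing exposed).
Blocks are extracted greedily by score, each hit belonging to at most one
block, until no eligible chain remains; the verdict comes from the
largest block. Equal-score ties are resolved deterministically (more
hits, then forward orientation, then lowest start coordinate); in
practice ties are measure-zero because cell values are continuous.

## Identity matrices and column filtering

Percent identity from a multiple alignment needs a denominator
convention, and published tables rarely state one. The default,
`pair_columns`, divides identities by the columns where at least one of
the two sequences has a residue: mutual-gap columns (which belong to
*other* sequences' insertions) would otherwise deflate every pairwise
value in a family-wide alignment. `msa_length`, `min_seq_length` and
`aligned_pairs` are selectable for comparison with other tools. Reported
values are rounded half-up to integers; full precision is kept
internally. Site coverage of a column is the fraction of sequences with
a non-gap character (X counts as present — coverage measures data
presence, not certainty); filtering keeps exactly the columns at or
above the threshold and is idempotent.

## Exon-structure comparison

Exon lengths are taken in transcription orientation from whatever exon
features the annotation supplies (the package does not distinguish UTR
from CDS exons; output reflects the input annotation's convention, and
exon counts are annotation-release dependent). For multi-isoform genes
the isoform with the most exons is kept (ties: longest spliced form,
then smallest mRNA id) — one structure per gene, matching how family
architecture figures are drawn. Conserved-size groups are formed per
5′-anchored exon ordinal, with a separate 3′-anchored pass for the
terminal exon because last-exon conservation (often encoding a terminal
transmembrane domain) survives differences in exon count. Default size
tolerance is 0 nt, since conserved plant exon sizes are typically exact;
a positive tolerance clusters greedily with cluster span ≤ 2·tolerance.

## The synthetic study

The generator plants known evolutionary events and hands back the truth,
so every stage is testable without downloads. Its defaults emulate the
shape of the motivating system: a seven-member family spread round-robin
across chromosomes (members of a real small family sit on several
chromosomes; dispersal also keeps anchor windows disjoint unless an
event relates them), proteins of 200–300 residues from Robinson–Robinson
background frequencies, a 9-exon family template carrying conserved exon
sizes of 80/125/122/93/101 nt plus a conserved 125 nt terminal exon,
1 kb intergenic spacing and 100 nt introns. Substitution is uniform
replacement by a different residue, so expected identity after
divergence d is exactly 100·(1−d) and two-branch compositions have the
closed form (1−d₁)(1−d₂) + d₁d₂/19 — this analytic tractability is why a
matrix-weighted substitution model is deliberately not used. The
`family_alignment` helper builds a gap-free seven-member alignment from a
three-subgroup tree whose branch lengths reproduce the identity
structure typical of such a family (a ~82% recent pair, ~70% sibling,
~64% mid pair, ~39% deep pair, 20–30% across subgroups).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: indels and alignment uncertainty (planted
"alignments" are substitution-only), codon-level evolution (proteins are
simulated independently of the nucleotide exon layout), rate variation
across sites and lineages, transposon-rich intergenic structure, and
annotation error. Verdict thresholds tuned here transfer to real
annotations only in the qualitative sense (high vs none).

Problem sizes used by the test suite and the acceptance script are
scaled to the signal being measured: chromosomes of 30–50 genes with
20-gene duplicated segments and windows of 30–40 genes (a planted
segment fully inside a window behaves identically to a 200-gene window
around a real anchor, because hits outside the segment are absent by
construction); proteins of 100–240 residues, long enough that a planted
ortholog at divergence ≤ 0.3 is always significant at 1e-5 while
unrelated same-length pairs essentially never are; identity-recovery
checks use 1000–5000-residue sequences so that binomial noise (σ ≈ 0.6–2
points) sits well inside the stated 2–3-point tolerances.

Negative controls are anchor pairs whose neighborhoods share *no gene
order*: family members on different, shuffled chromosomes. Their windows
share only the anchor-anchor hit, which the min-block rule excludes, so
the expected verdict is none. A chromosome that is duplicated *and then
shuffled* is deliberately not used as the negative: its windows still
share ~20 homologous genes at random positions, and with gap tolerance 5
such scatter yields spurious 3-hit chains (a weak call) in most random
orders — order is destroyed but content is not, which is a different
null hypothesis than "no shared ancestry".

## Degenerate inputs and numerical choices

Empty local alignments (score 0) carry spans (0, 0) and never pass any
threshold. E = 0 (underflow at extreme scores) maps to the dot-plot score
cap (200). Filtering that would leave zero columns raises rather than
returning a degenerate alignment. Duplicate FASTA ids, gaps in unaligned
sequences, ragged alignment rows, exons outside their gene, and unknown
strands are rejected at parse time. All generator randomness flows
through numpy's PCG64 from a single integer seed; fixture emission is
byte-identical per seed.

## Known limitations

Window comparison is all-vs-all per anchor pair, O(w²) alignments —
appropriate for a handful of anchors, not for genome-wide synteny
mapping. The E-value model uses fixed gapped Karlin–Altschul constants
rather than composition-based statistics. The census is a pure
reciprocal-best-hit criterion; it will undercount families with very
recent in-paralogs (two proteome members competing for the same seed).
Identity values from real family alignments depend on the upstream
aligner (the package consumes alignments, it does not build them), so
cross-tool agreement is expected only within a couple of percentage
points.
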