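"""Spliced query-to-genome mapping and genomic target reconstruction.

A user typically pastes a cDNA/CDS fragment. Relative to the genome it may
be spliced (introns removed), so protospacers crossing exon junctions in
the query do not exist in the genome. The mapper aligns the query to the
genome with exact-seed chaining (k = 16, ungapped extension, colinear block
chains) and accepts the alignment only at >= 98% identity; the genomic
sequence between the first and last aligned positions is then reconstructed
with a per-base exon mask so that design happens on real genomic sequence
while translation follows the exonic (query) bases.

This replaces an external spliced aligner: the contract is the identity
threshold and block structure, not a particular algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from Bio.Seq import reverse_complement

MIN_IDENTITY = 0.98
SEED_K = 16


class MappingError(ValueError):
    pass


class AmbiguousMappingError(MappingError):
    """Query maps equally well to more than one locus; reported, not chosen."""

    def __init__(self, loci: list[tuple[str, str, int]]):
        self.loci = loci
        desc = ", ".join(f"{c}:{s}{p}" for c, s, p in loci)
        super().__init__(f"query maps equally well to multiple loci: {desc}")


class UnmappedQueryError(MappingError):
    """Best alignment falls below the identity threshold."""


@dataclass(frozen=True)
class Block:
    """One ungapped aligned block: query and genome intervals, 0-based half-open.

    Genome interval is on the forward strand; for '-' alignments genome
    intervals decrease as query intervals increase.
    """

    q_start: int
    q_end: int
    g_start: int
    g_end: int

    def __post_init__(self) -> None:
        assert self.q_end - self.q_start == self.g_end - self.g_start


@dataclass(frozen=True)
class SplicedAlignment:
    chrom: str
    strand: str
    blocks: tuple[Block, ...]
    identity: float
    matches: int
    query_length: int

    @property
    def is_spliced(self) -> bool:
        return len(self.blocks) > 1

    def genome_span(self) -> tuple[int, int]:
        starts = [b.g_start for b in self.blocks]
        ends = [b.g_end for b in self.blocks]
        return min(starts), max(ends)

    def intron_lengths(self) -> list[int]:
        """Genomic gaps between consecutive blocks, in query order."""
        out = []
        for a, b in zip(self.blocks, self.blocks[1:]):
            if self.strand == "+":
                out.append(b.g_start - a.g_end)
            else:
                out.append(a.g_start - b.g_end)
        return out


@dataclass
class GenomicTarget:
    """Contiguous genomic sequence in coding orientation with an exon mask.

    ``sequence`` reads 5'->3' on the coding (query) strand. ``exon_mask[i]``
    is True when position i is exonic (aligned to the query). ``frame_offset``
    (0/1/2) is the index of the exonic base at which the first complete codon
    starts, counted along exonic bases only. ``coordinate_origin`` is the
    forward-strand genome coordinate of target position 0 ('+') or of the
    last target position ('-').
    """

    sequence: str
    exon_mask: list[bool]
    frame_offset: int = 0
    chrom: str = "query"
    strand: str = "+"
    coordinate_origin: int = 0

    def __len__(self) -> int:
        return len(self.sequence)

    def genome_coordinate(self, pos: int) -> int:
        """Forward-strand genome coordinate of target position ``pos``."""
        if self.strand == "+":
            return self.coordinate_origin + pos
        return self.coordinate_origin + (len(self.sequence) - 1 - pos)

    def exonic_sequence(self) -> str:
        return "".join(b for b, m in zip(self.sequence, self.exon_mask) if m)

    def cds_index(self, pos: int) -> int | None:
        """Index of target position ``pos`` within the exonic sequence, or None."""
        if not self.exon_mask[pos]:
            return None
        return sum(1 for m in self.exon_mask[:pos] if m)


def _seed_hits(query: str, target: str, k: int) -> dict[int, list[int]]:
    """Map diagonal (g - q) -> sorted query seed positions on that diagonal."""
    index: dict[str, list[int]] = {}
    for i in range(len(target) - k + 1):
        index.setdefault(target[i : i + k], []).append(i)
    diags: dict[int, list[int]] = {}
    for q in range(len(query) - k + 1):
        for g in index.get(query[q : q + k], ()):
            diags.setdefault(g - q, []).append(q)
    return diags


def _chain_diagonals(
    diags: dict[int, list[int]], qlen: int, tlen: int, k: int
) -> list[tuple[int, int, int]] | None:
    """Choose a colinear chain of diagonals covering the query.

    Returns [(q_start, q_end, diag), ...] in query order, query-covering
    (the first block is pulled to query position 0, the last to qlen, and
    junction gaps are absorbed by the upstream block), or None when there
    are no seeds.
    """
    if not diags:
        return None
    # one candidate block per diagonal: the seed envelope
    cands = sorted(
        (min(qs), max(qs) + k, d) for d, qs in diags.items()
    )
    # weighted colinear chaining (blocks few at desk scale: O(n^2) DP)
    n = len(cands)
    score = [c[1] - c[0] for c in cands]
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            qi, qe, di = cands[i]
            qj, qje, dj = cands[j]
            # colinear: genome advances past block i's end; query may
            # overlap slightly (trimmed later); genomic gap = intron
            if di < dj and qj >= qi and qj + dj > qe + di:
                cand = score[i] + (qje - max(qj, qe))
                if cand > score[j]:
                    score[j] = cand
                    prev[j] = i
    best = max(range(n), key=lambda j: score[j])
    chain = []
    j = best
    while j != -1:
        chain.append(cands[j])
        j = prev[j]
    chain.reverse()
    # make blocks non-overlapping in query; pull the chain ends to cover
    # the whole query (junction gaps are resolved later by base matching)
    out: list[tuple[int, int, int]] = []
    for idx, (qs, qe, d) in enumerate(chain):
        if idx == 0:
            qs = 0
        if idx == len(chain) - 1:
            qe = qlen
        if out and qs < out[-1][1]:
            qs = out[-1][1]
        # clamp to genome bounds along the diagonal
        qs = max(qs, -d)
        qe = min(qe, tlen - d)
        if qe > qs:
            out.append((qs, qe, d))
    if not out:
        return None
    return out


def _align_one_strand(
    query: str, target: str, k: int, prefer_left: bool = True
) -> tuple[list[Block], int] | None:
    chain = _chain_diagonals(_seed_hits(query, target, k), len(query), len(target), k)
    if chain is None:
        return None
    # resolve seedless junction gaps between consecutive blocks: extend the
    # left block while its diagonal keeps matching, then the right block
    # leftward likewise; leftover mismatching bases stay with the left block
    mut = [list(b) for b in chain]
    for left, right in zip(mut, mut[1:]):
        def _grow_left() -> None:
            while (
                left[1] < right[0]
                and left[1] + left[2] < len(target)
                and query[left[1]] == target[left[1] + left[2]]
            ):
                left[1] += 1

        def _grow_right() -> None:
            while (
                right[0] > left[1]
                and right[0] - 1 + right[2] >= 0
                and query[right[0] - 1] == target[right[0] - 1 + right[2]]
            ):
                right[0] -= 1

        # bases matching both exon diagonals are assigned toward the
        # genomic 5' side so '+' and '-' mappings stay mirror images
        if prefer_left:
            _grow_left(), _grow_right()
            if left[1] < right[0]:
                left[1] = right[0]
            b = left[1]
            while b < right[1] - 1 and query[b] == target[b + left[2]]:
                b += 1
        else:
            _grow_right(), _grow_left()
            if left[1] < right[0]:
                left[1] = right[0]
            b = right[0]
            while b > left[0] + 1 and query[b - 1] == target[b - 1 + right[2]]:
                b -= 1
        left[1] = right[0] = b
    blocks = []
    matches = 0
    for qs, qe, d in mut:
        blocks.append(Block(qs, qe, qs + d, qe + d))
        matches += sum(
            1 for a, b in zip(query[qs:qe], target[qs + d : qe + d]) if a == b
        )
    return blocks, matches


def map_query(
    query: str,
    genome: Mapping[str, str],
    *,
    min_identity: float = MIN_IDENTITY,
    k: int = SEED_K,
) -> SplicedAlignment:
    """Locate ``query`` in ``genome``, allowing splicing, at >= 98% identity.

    ``genome`` maps sequence names to sequences (a dict or a pyfaidx.Fasta).
    Raises :class:`UnmappedQueryError` below the identity threshold and
    :class:`AmbiguousMappingError` when two loci tie at the best identity.
    Identity is matches / query length.
    """
    query = str(query).upper()
    if len(query) < 30:
        raise MappingError(f"query too short to map ({len(query)} < 30 nt)")
    candidates: list[SplicedAlignment] = []
    for chrom in genome.keys():
        fwd = str(genome[chrom]).upper()
        for strand in "+-":
            target = fwd if strand == "+" else reverse_complement(fwd)
            res = _align_one_strand(query, target, k, prefer_left=strand == "+")
            if res is None:
                continue
            blocks, matches = res
            if strand == "-":
                L = len(fwd)
                blocks = [
                    Block(b.q_start, b.q_end, L - b.g_end, L - b.g_start)
                    for b in blocks
                ]
            candidates.append(
                SplicedAlignment(
                    chrom=chrom,
                    strand=strand,
                    blocks=tuple(blocks),
                    identity=matches / len(query),
                    matches=matches,
                    query_length=len(query),
                )
            )
    if not candidates:
        raise UnmappedQueryError("no seed match in genome")
    best = max(c.identity for c in candidates)
    # round-trip tolerance: treat identities equal to the best as ties
    ties = [c for c in candidates if abs(c.identity - best) < 1e-12]
    if best < min_identity:
        raise UnmappedQueryError(
            f"best alignment identity {best:.4f} below threshold {min_identity:.2f}"
        )
    if len(ties) > 1:
        raise AmbiguousMappingError(
            [(c.chrom, c.strand, c.genome_span()[0]) for c in ties]
        )
    return ties[0]


def reconstruct_genomic(
    alignment: SplicedAlignment,
    genome: Mapping[str, str],
    *,
    frame_offset: int = 0,
) -> GenomicTarget:
    """Reconstruct the contiguous genomic target spanned by an alignment.

    Intronic runs between exon blocks are re-inserted and flagged in the
    exon mask; the sequence is returned in the query (coding) orientation.
    ``frame_offset`` selects the codon phase of the first exonic base
    (0 = the reading frame starts at the first query base).
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    g_start, g_end = alignment.genome_span()
    fwd = str(genome[alignment.chrom]).upper()[g_start:g_end]
    if alignment.strand == "+":
        seq = fwd
        exonic_fwd = [False] * len(fwd)
        for b in alignment.blocks:
            for i in range(b.g_start - g_start, b.g_end - g_start):
                exonic_fwd[i] = True
        mask = exonic_fwd
    else:
        seq = reverse_complement(fwd)
        exonic_fwd = [False] * len(fwd)
        for b in alignment.blocks:
            for i in range(b.g_start - g_start, b.g_end - g_start):
                exonic_fwd[i] = True
        mask = exonic_fwd[::-1]
    return GenomicTarget(
        sequence=seq,
        exon_mask=mask,
        frame_offset=frame_offset,
        chrom=alignment.chrom,
        strand=alignment.strand,
        coordinate_origin=g_start,
    )


def target_from_query(query: str, *, frame_offset: int = 0, name: str = "query") -> GenomicTarget:
    """Wrap a raw (unspliced) sequence as an all-exonic target."""
    q = str(query).upper()
    return GenomicTarget(
        sequence=q,
        exon_mask=[True] * len(q),
        frame_offset=frame_offset,
        chrom=name,
        strand="+",
        coordinate_origin=0,
    )


def target_from_annotation(
    genome: Mapping[str, str],
    chrom: str,
    exons: list[tuple[int, int]],
    strand: str = "+",
    *,
    frame_offset: int = 0,
) -> GenomicTarget:
    """Build a target from exon intervals (0-based half-open, forward strand)
    of a gene model, bypassing alignment."""
    exons = sorted(exons)
    g_start, g_end = exons[0][0], exons[-1][1]
    fwd = str(genome[chrom]).upper()[g_start:g_end]
    exonic_fwd = [False] * len(fwd)
    for s, e in exons:
        for i in range(s - g_start, e - g_start):
            exonic_fwd[i] = True
    if strand == "+":
        seq, mask = fwd, exonic_fwd
    else:
        seq, mask = reverse_complement(fwd), exonic_fwd[::-1]
    return GenomicTarget(
        sequence=seq,
        exon_mask=mask,
        frame_offset=frame_offset,
        chrom=chrom,
        strand=strand,
        coordinate_origin=g_start,
    )
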