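"""Genome-wide off-target search for base-editing guides.

Enumerates every PAM-adjacent 20-mer on both genome strands, keeps
near-matches of the spacer within the mismatch limits (at most 4 mismatches
over the spacer and at most 2 within the 12-nt PAM-proximal core), drops
sites without a substrate base in the editing window (a base editor cannot
do harm where it has nothing to edit), and orders the remainder by a
position-weighted threat score: mismatches far from the PAM are better
tolerated by Cas9, so PAM-distal-mismatch sites are the likelier
off-targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Seq import reverse_complement

from .design import iupac_match
from .editors import EditorProfile

THREAT_WEIGHT = 1.2
SPACER_LENGTH = 20


@dataclass(frozen=True)
class SearchConfig:
    """Mismatch limits for candidate off-target sites.

    Both limits apply together: a site passes with <= ``max_core_mismatches``
    in the ``core_length`` nt adjacent to the PAM and <=
    ``max_total_mismatches`` over the whole spacer.
    """

    max_total_mismatches: int = 4
    max_core_mismatches: int = 2
    core_length: int = 12
    pam: str = "NGG"

    def __post_init__(self) -> None:
        if self.max_core_mismatches > self.max_total_mismatches:
            raise ValueError("core mismatch limit exceeds the total limit")
        if not 0 < self.core_length <= SPACER_LENGTH:
            raise ValueError("core_length must be in 1..20")


@dataclass(frozen=True)
class OffTargetHit:
    """A genomic near-match of the spacer with a matching PAM.

    ``start``/``end`` delimit the 20-nt protospacer on the forward strand
    (0-based half-open); ``site_sequence`` is protospacer + PAM 5'->3' on
    the site strand; ``mismatch_positions`` are 1-based protospacer
    positions (1 = PAM-distal end).
    """

    chrom: str
    start: int
    end: int
    strand: str
    site_sequence: str
    mismatch_positions: tuple[int, ...]
    core_mismatches: int
    editable_in_window: bool = False
    threat_score: float = 0.0
    context: str = "unknown"

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


def threat_score(mismatch_positions: Iterable[int], w: float = THREAT_WEIGHT) -> float:
    """Position-weighted threat: sum of w^(21 - p) over mismatch positions.

    PAM-distal mismatches (small p) weigh more — those sites remain good
    Cas9 substrates and are the likelier true off-targets. The perfect
    match scores 0 and is handled separately as the on-target.
    """
    return sum(w ** (21 - p) for p in mismatch_positions)


def _compare(
    spacer: str, site: str, config: SearchConfig
) -> tuple[tuple[int, ...], int] | None:
    """Mismatch profile of ``site`` vs ``spacer``, or None when over limits.

    Early-aborts as soon as either limit is exceeded. Core positions are
    the ``core_length`` bases adjacent to the PAM (3' end of the spacer).
    """
    core_start = SPACER_LENGTH - config.core_length  # 0-based
    mismatches: list[int] = []
    core = 0
    for i in range(SPACER_LENGTH):
        if spacer[i] != site[i]:
            mismatches.append(i + 1)
            if len(mismatches) > config.max_total_mismatches:
                return None
            if i >= core_start:
                core += 1
                if core > config.max_core_mismatches:
                    return None
    return tuple(mismatches), core


def find_offtargets(
    spacer: str,
    genome: Mapping[str, str],
    config: SearchConfig | None = None,
) -> list[OffTargetHit]:
    """All genomic near-matches of ``spacer`` within the mismatch limits.

    Both strands are scanned; the PAM must match its IUPAC pattern exactly
    (PAM bases never count as spacer mismatches). Windows containing N are
    skipped. The perfect on-target match (0 mismatches) is included.
    """
    spacer = str(spacer).upper()
    if len(spacer) != SPACER_LENGTH:
        raise ValueError(f"spacer must be {SPACER_LENGTH} nt, got {len(spacer)}")
    config = config or SearchConfig()
    pam_len = len(config.pam)
    hits: list[OffTargetHit] = []
    for chrom in genome.keys():
        fwd = str(genome[chrom]).upper()
        n = len(fwd)
        for i in range(n - SPACER_LENGTH - pam_len + 1):
            # forward strand site
            pam = fwd[i + SPACER_LENGTH : i + SPACER_LENGTH + pam_len]
            if iupac_match(config.pam, pam):
                site = fwd[i : i + SPACER_LENGTH]
                if "N" not in site:
                    res = _compare(spacer, site, config)
                    if res is not None:
                        mm, core = res
                        hits.append(
                            OffTargetHit(
                                chrom=chrom,
                                start=i,
                                end=i + SPACER_LENGTH,
                                strand="+",
                                site_sequence=site + pam,
                                mismatch_positions=mm,
                                core_mismatches=core,
                                threat_score=threat_score(mm),
                            )
                        )
        for i in range(pam_len, n - SPACER_LENGTH + 1):
            # reverse strand site: PAM 5' of the window on the forward strand
            pam = reverse_complement(fwd[i - pam_len : i])
            if iupac_match(config.pam, pam):
                site = reverse_complement(fwd[i : i + SPACER_LENGTH])
                if "N" not in site:
                    res = _compare(spacer, site, config)
                    if res is not None:
                        mm, core = res
                        hits.append(
                            OffTargetHit(
                                chrom=chrom,
                                start=i,
                                end=i + SPACER_LENGTH,
                                strand="-",
                                site_sequence=site + pam,
                                mismatch_positions=mm,
                                core_mismatches=core,
                                threat_score=threat_score(mm),
                            )
                        )
    return hits


def filter_editable(
    hits: Iterable[OffTargetHit],
    editor: EditorProfile,
    window: tuple[int, int] | None = None,
) -> list[OffTargetHit]:
    """Keep hits with >= 1 substrate base of ``editor`` in the window.

    A site the editor cannot deaminate is not an off-target risk for base
    editing even if Cas9 binds it. ``window`` defaults to the editor's
    observed window. The flag is recorded on the returned hits; the
    operation is idempotent.
    """
    lo, hi = window if window is not None else editor.observed_window
    kept = []
    for h in hits:
        site = h.site_sequence[:SPACER_LENGTH]
        editable = any(
            site[p - 1] == editor.substrate_base
            for p in range(max(lo, 1), min(hi, SPACER_LENGTH) + 1)
        )
        if editable:
            kept.append(
                OffTargetHit(**{**h.__dict__, "editable_in_window": True})
            )
    return kept


def rank_offtargets(hits: Iterable[OffTargetHit]) -> list[OffTargetHit]:
    """Order hits by descending threat, the 0-mismatch on-target first.

    Ties (identical threat scores) break by coordinate: (chrom, start,
    strand).
    """
    return sorted(
        hits,
        key=lambda h: (
            h.n_mismatches != 0,
            -h.threat_score,
            h.chrom,
            h.start,
            h.strand,
        ),
    )


def annotate_context(
    hit: OffTargetHit,
    gene_models: "list | None",
) -> str:
    """Genomic context of a hit: exonic, intronic or intergenic.

    ``gene_models`` is a list of gene records with ``chrom``, ``start``,
    ``end`` and ``exons`` (list of 0-based half-open intervals), as
    produced by :func:`bedesign.io.read_gene_models`. A hit overlapping an
    exon by a single base is exonic; inside a gene span but no exon,
    intronic; otherwise intergenic. Without models the context is unknown.
    """
    if not gene_models:
        return "unknown"
    in_gene = False
    for gene in gene_models:
        if gene.chrom != hit.chrom or hit.end <= gene.start or hit.start >= gene.end:
            continue
        in_gene = True
        for s, e in gene.exons:
            if hit.start < e and hit.end > s:
                return "exonic"
    return "intronic" if in_gene else "intergenic"


def annotate_hits(
    hits: Iterable[OffTargetHit], gene_models: "list | None"
) -> list[OffTargetHit]:
    return [
        OffTargetHit(**{**h.__dict__, "context": annotate_context(h, gene_models)})
        for h in hits
    ]
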