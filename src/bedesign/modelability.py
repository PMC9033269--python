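"""Classify pathogenic SNVs as modelable by base editors in fish.

Human disease variants can be functionally tested in medaka or zebrafish
when (1) the variant is a pathogenic coding SNV, (2) the orthologous fish
position is uniquely alignable and carries the identical base, and (3) a
base editor can install the human alternate allele there: the required
change must be a transition addressable by a CBE (C->T, or G->A via the
opposite strand) or an ABE (A->G / T->C), and an NGG-PAM protospacer must
place the target base at editing-window positions 4-8.

A variant is *stringently* modelable when at least one such guide has no
other substrate base in its window (no bystander edits possible) and
*permissively* modelable when any guide exists at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import reverse_complement

from .design import _single_base_consequence, iupac_match
from .mapping import GenomicTarget

logger = logging.getLogger(__name__)

# SO terms counted as coding consequences: stop_lost, initiator_codon_variant,
# missense_variant, stop_gained
CODING_SO_TERMS = frozenset(
    {"SO:0001578", "SO:0001582", "SO:0001583", "SO:0001587"}
)

STANDARD_WINDOW = (4, 8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ContextTooShortError(ValueError):
    """The fish context cannot host every window placement of a guide."""


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    clinical_significance: str = ""
    consequence_terms: tuple[str, ...] = ()
    variant_id: str = ""

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
            raise ValueError(f"not a SNV: {self.ref}>{self.alt}")


@dataclass(frozen=True)
class OrthologSite:
    """Fish position orthologous to a human variant.

    ``fish_base`` is the aligned base read on the fish strand given by
    ``strand`` ('+': same orientation as the human reference; '-':
    complemented). ``fish_context`` is the fish sequence (>= 41 nt, same
    strand as ``fish_base``) centered on the orthologous position.
    """

    variant_id: str
    fish_chrom: str
    fish_pos: int  # 1-based
    fish_base: str
    unique_alignment: bool
    strand: str = "+"
    fish_context: str = ""

    @property
    def center_index(self) -> int:
        return len(self.fish_context) // 2


@dataclass(frozen=True)
class CandidateGuide:
    protospacer: str
    pam: str
    strand: str  # relative to the fish context orientation
    window_position: int  # 1-based protospacer position of the target base
    bystanders: tuple[int, ...]  # other substrate-base window positions


@dataclass(frozen=True)
class ModelabilityResult:
    variant_id: str
    editor_class: str  # CBE, ABE or none
    candidate_guides: tuple[CandidateGuide, ...] = ()
    stringent: bool = False
    permissive: bool = False

    def __post_init__(self) -> None:
        assert not (self.stringent and not self.permissive)
        if self.editor_class == "none":
            assert not self.permissive


def filter_pathogenic_snvs(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Pathogenic coding SNVs: CLNSIG exactly 'Pathogenic' and at least one
    of the four coding SO consequence terms. Malformed entries are skipped
    with a logged count."""
    kept: list[VariantRecord] = []
    skipped = 0
    for rec in records:
        try:
            if rec.clinical_significance != "Pathogenic":
                continue
            if not CODING_SO_TERMS.intersection(rec.consequence_terms):
                continue
            kept.append(rec)
        except (AttributeError, TypeError):
            skipped += 1
    if skipped:
        logger.warning("skipped %d malformed variant records", skipped)
    return kept


def check_ortholog(
    site: OrthologSite, variant: VariantRecord
) -> tuple[bool, str]:
    """Accept the ortholog mapping or give the rejection reason.

    Requires a unique alignment and the strand-adjusted fish base to be
    identical to the human reference base.
    """
    if not site.unique_alignment:
        return False, "ambiguous"
    fish_ref = site.fish_base.upper()
    human_ref = (
        variant.ref.upper()
        if site.strand == "+"
        else variant.ref.upper().translate(_COMPLEMENT)
    )
    if fish_ref != human_ref:
        return False, "diverged"
    return True, "ok"


def required_edit(variant: VariantRecord, site: OrthologSite) -> tuple[str, str]:
    """ref->alt on the fish context strand."""
    if site.strand == "+":
        return variant.ref.upper(), variant.alt.upper()
    return (
        variant.ref.upper().translate(_COMPLEMENT),
        variant.alt.upper().translate(_COMPLEMENT),
    )


def editor_class_for(ref: str, alt: str) -> str:
    """CBE for C->T / G->A, ABE for A->G / T->C, none for transversions."""
    pair = (ref.upper(), alt.upper())
    if pair in {("C", "T"), ("G", "A")}:
        return "CBE"
    if pair in {("A", "G"), ("T", "C")}:
        return "ABE"
    return "none"


def enumerate_guides(
    context: str,
    center: int,
    substrate: str,
    *,
    window: tuple[int, int] = STANDARD_WINDOW,
    pam: str = "NGG",
    strand_of_context: str = "+",
) -> list[CandidateGuide]:
    """All protospacers in ``context`` placing position ``center`` (which
    must read as ``substrate``) at a window position with a matching PAM."""
    seq = context.upper()
    lo, hi = window
    out: list[CandidateGuide] = []
    if seq[center] != substrate:
        return out
    for w in range(lo, hi + 1):
        s = center - (w - 1)
        if s < 0 or s + 20 + len(pam) > len(seq):
            continue
        pam_seq = seq[s + 20 : s + 20 + len(pam)]
        if not iupac_match(pam, pam_seq):
            continue
        proto = seq[s : s + 20]
        if "N" in proto:
            continue
        bystanders = tuple(
            p for p in range(lo, hi + 1) if p != w and proto[p - 1] == substrate
        )
        out.append(
            CandidateGuide(
                protospacer=proto,
                pam=pam_seq,
                strand=strand_of_context,
                window_position=w,
                bystanders=bystanders,
            )
        )
    return out


def classify_modelability(
    variant: VariantRecord,
    site: OrthologSite,
    *,
    window: tuple[int, int] = STANDARD_WINDOW,
    pam: str = "NGG",
) -> ModelabilityResult:
    """Editor compatibility of a variant at its accepted fish ortholog.

    The required edit is taken on the fish coding strand; a CBE covers
    C->T directly and G->A via the opposite strand (strand symmetry), an
    ABE covers A->G and T->C. Guides are enumerated over both strands of
    the fish context with the target base at window positions
    ``window[0]..window[1]`` and a matching PAM.
    """
    ref, alt = required_edit(variant, site)
    cls = editor_class_for(ref, alt)
    vid = site.variant_id or variant.variant_id
    if cls == "none":
        return ModelabilityResult(variant_id=vid, editor_class="none")
    # minimum context so every window placement can be checked on both
    # strands: 20-mer + PAM around the center at any window offset
    lo, hi = window
    need = max(hi - 1, 20 + len(pam) - lo) * 2 + 1
    if len(site.fish_context) < min(41, need):
        raise ContextTooShortError(
            f"context of {len(site.fish_context)} nt cannot host all "
            f"window placements (need >= {min(41, need)})"
        )
    substrate = "C" if cls == "CBE" else "A"
    guides: list[CandidateGuide] = []
    # orientation where the target base reads as the substrate
    if (ref == "C" and cls == "CBE") or (ref == "A" and cls == "ABE"):
        guides += enumerate_guides(
            site.fish_context, site.center_index, substrate,
            window=window, pam=pam, strand_of_context="+",
        )
    else:  # G->A or T->C: address on the opposite strand
        rc = reverse_complement(site.fish_context)
        guides += enumerate_guides(
            rc, len(site.fish_context) - 1 - site.center_index, substrate,
            window=window, pam=pam, strand_of_context="-",
        )
    permissive = bool(guides)
    stringent = any(not g.bystanders for g in guides)
    return ModelabilityResult(
        variant_id=vid,
        editor_class=cls if permissive else cls,
        candidate_guides=tuple(guides),
        stringent=stringent,
        permissive=permissive,
    )


def annotate_fish_consequence(
    site: OrthologSite,
    variant: VariantRecord,
    fish_target: GenomicTarget,
) -> str:
    """Codon consequence of installing the edit in the fish gene model.

    ``fish_target`` must cover ``site.fish_pos`` on its chromosome; the
    alternate allele is complemented onto the fish coding strand as needed.
    Positions outside the CDS are labelled noncoding (or intronic /
    splice_site inside the modelled gene body).
    """
    if fish_target.chrom != site.fish_chrom:
        raise ValueError("fish gene model is on a different sequence")
    g = site.fish_pos - 1  # forward-strand 0-based
    if fish_target.strand == "+":
        tpos = g - fish_target.coordinate_origin
    else:
        tpos = fish_target.coordinate_origin + len(fish_target.sequence) - 1 - g
    if not 0 <= tpos < len(fish_target.sequence):
        return "noncoding"
    _, alt = required_edit(variant, site)
    # alt is on the context strand; move it onto the target coding strand
    if (site.strand == "+") != (fish_target.strand == "+"):
        alt = alt.translate(_COMPLEMENT)
    cons = _single_base_consequence(
        fish_target,
        tpos,
        alt,
        None,
        exonic_seq=fish_target.exonic_sequence(),
        exonic_pos=[],
    )
    return cons.consequence


def classify_table(
    variants: Sequence[VariantRecord],
    sites: dict[str, OrthologSite],
    *,
    window: tuple[int, int] = STANDARD_WINDOW,
    pam: str = "NGG",
) -> list[tuple[VariantRecord, str, ModelabilityResult | None]]:
    """End-to-end classification of a variant table against ortholog sites.

    Returns one row per pathogenic coding SNV: (record, status, result)
    where status is 'ok', 'no_ortholog', 'ambiguous' or 'diverged'; result
    is None unless the ortholog was accepted.
    """
    rows: list[tuple[VariantRecord, str, ModelabilityResult | None]] = []
    for rec in filter_pathogenic_snvs(variants):
        vid = rec.variant_id or f"{rec.chrom}:{rec.pos}{rec.ref}>{rec.alt}"
        site = sites.get(vid)
        if site is None:
            rows.append((rec, "no_ortholog", None))
            continue
        ok, reason = check_ortholog(site, rec)
        if not ok:
            rows.append((rec, reason, None))
            continue
        rows.append(
            (rec, "ok", classify_modelability(rec, site, window=window, pam=pam))
        )
    return rows
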