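"""Protospacer scanning, codon consequence prediction and guide assembly.

Scans a genomic target (both strands) for 20-nt protospacers with an NGG
PAM that carry at least one substrate base (C for CBEs, A for ABEs) inside
the editing window, predicts the amino-acid consequence of converting each
editable base — and of converting all window substrate bases at once, since
base editors frequently install bystander edits — scores each guide with
the editor's rank score, and emits T7 cloning oligos.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import IUPACData
from Bio.Seq import Seq, reverse_complement

from .editors import (
    EditorProfile,
    ScoreBreakdown,
    base_score,
    guide_score,
)
from .mapping import GenomicTarget

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CONSEQUENCE_CLASSES = (
    "synonymous",
    "missense",
    "nonsense",
    "stop_loss",
    "start_loss",
    "splice_site",
    "intronic",
    "noncoding",
)


def iupac_match(pattern: str, seq: str) -> bool:
    """True when ``seq`` matches the IUPAC ``pattern`` position by position."""
    if len(pattern) != len(seq):
        return False
    for p, s in zip(pattern.upper(), seq.upper()):
        allowed = IUPACData.ambiguous_dna_values.get(p, p)
        if s not in allowed:
            return False
    return True


@dataclass(frozen=True)
class CandidateSite:
    """A protospacer + PAM with at least one editable base in the window.

    ``start`` is the 0-based start of the 20-nt protospacer interval on the
    target forward strand (half-open ``[start, start+20)``) regardless of
    strand; ``protospacer`` and ``pam`` read 5'->3' on the protospacer
    strand. ``editable_positions`` are 1-based protospacer positions
    (1 = PAM-distal 5' end) carrying the editor's substrate base within the
    active window. ``flank5`` is the genomic base 5' of protospacer
    position 1, used for its dinucleotide context (None at a sequence edge).
    """

    protospacer: str
    pam: str
    strand: str
    start: int
    editable_positions: tuple[int, ...]
    flank5: str | None

    def target_index(self, position: int) -> int:
        """Target-forward index of 1-based protospacer ``position``."""
        if self.strand == "+":
            return self.start + position - 1
        return self.start + 20 - position


@dataclass(frozen=True)
class CodonConsequence:
    """Amino-acid consequence of converting one base (or a base set)."""

    protospacer_position: int | None
    genomic_position: int | None
    ref_codon: str | None
    alt_codon: str | None
    ref_aa: str | None
    alt_aa: str | None
    consequence: str
    is_bystander: bool = False
    protein_position: int | None = None

    def hgvs_p(self) -> str:
        """HGVS-like protein notation, e.g. p.Q333X (X = stop)."""
        if self.ref_aa is None or self.protein_position is None:
            return f"p.?({self.consequence})"
        ref = "X" if self.ref_aa == "*" else self.ref_aa
        alt = "X" if self.alt_aa == "*" else self.alt_aa
        if self.consequence == "synonymous":
            return f"p.{ref}{self.protein_position}="
        return f"p.{ref}{self.protein_position}{alt}"


@dataclass(frozen=True)
class OligoPair:
    """Annealed-oligo pair for T7 sgRNA cloning.

    The spacer-derived portion may have its 5' bases swapped to G to
    support T7 transcription initiation.
    """

    forward: str
    reverse: str
    spacer: str
    g_substituted: int


@dataclass
class ScoredGuide:
    site: CandidateSite
    editor: str
    per_base: list[tuple[ScoreBreakdown | None, CodonConsequence]]
    best: ScoreBreakdown | None
    combined_consequence: CodonConsequence | None
    oligos: OligoPair
    combined_protein_change: str = ""


def scan_protospacers(
    target: GenomicTarget,
    editor: EditorProfile,
    *,
    length: int = 20,
    window: tuple[int, int] | None = None,
) -> list[CandidateSite]:
    """All protospacers on both strands with >= 1 substrate base in the window.

    ``window`` defaults to the editor's observed (targetable) window; pass
    e.g. ``(4, 8)`` to restrict to the standard display window. Sites are
    ordered by target-forward start, '+' before '-'.
    """
    seq = target.sequence.upper()
    lo, hi = window if window is not None else editor.observed_window
    pam_len = len(editor.pam)
    sites: list[CandidateSite] = []
    n = len(seq)
    if n < length + pam_len:
        return []
    for i in range(n - length + 1):
        # forward strand: PAM 3' of the protospacer
        if i + length + pam_len <= n and iupac_match(
            editor.pam, seq[i + length : i + length + pam_len]
        ):
            proto = seq[i : i + length]
            if "N" not in proto:
                editable = tuple(
                    p
                    for p in range(max(lo, 1), min(hi, length) + 1)
                    if proto[p - 1] == editor.substrate_base
                )
                if editable:
                    sites.append(
                        CandidateSite(
                            protospacer=proto,
                            pam=seq[i + length : i + length + pam_len],
                            strand="+",
                            start=i,
                            editable_positions=editable,
                            flank5=seq[i - 1] if i > 0 else None,
                        )
                    )
        # reverse strand: protospacer occupies [i, i+length), PAM 5' of it
        # on the forward strand
        if i - pam_len >= 0:
            proto = reverse_complement(seq[i : i + length])
            pam = reverse_complement(seq[i - pam_len : i])
            if iupac_match(editor.pam, pam) and "N" not in proto:
                editable = tuple(
                    p
                    for p in range(max(lo, 1), min(hi, length) + 1)
                    if proto[p - 1] == editor.substrate_base
                )
                if editable:
                    flank = (
                        seq[i + length].translate(_COMPLEMENT)
                        if i + length < n
                        else None
                    )
                    sites.append(
                        CandidateSite(
                            protospacer=proto,
                            pam=pam,
                            strand="-",
                            start=i,
                            editable_positions=editable,
                            flank5=flank,
                        )
                    )
    sites.sort(key=lambda s: (s.start, 0 if s.strand == "+" else 1))
    return sites


def _codon_for(target: GenomicTarget, cds_index: int) -> tuple[int, list[int]] | None:
    """Codon index and exonic-base indices of the codon containing
    ``cds_index``, honouring the target's frame offset; None outside the ORF."""
    off = target.frame_offset
    if cds_index < off:
        return None
    codon_idx = (cds_index - off) // 3
    start = off + 3 * codon_idx
    total_exonic = sum(target.exon_mask)
    if start + 3 > total_exonic:
        return None
    return codon_idx, [start, start + 1, start + 2]


def _exonic_positions(target: GenomicTarget) -> list[int]:
    return [i for i, m in enumerate(target.exon_mask) if m]


def _splice_or_intronic(target: GenomicTarget, pos: int) -> str:
    """Intronic positions within 2 nt of an exon boundary are splice sites
    (the GT donor / AG acceptor dinucleotides)."""
    mask = target.exon_mask
    run_start = pos
    while run_start > 0 and not mask[run_start - 1]:
        run_start -= 1
    run_end = pos
    while run_end < len(mask) - 1 and not mask[run_end + 1]:
        run_end += 1
    if pos - run_start < 2 or run_end - pos < 2:
        return "splice_site"
    return "intronic"


def _classify(ref_aa: str, alt_aa: str, codon_idx: int, ref_codon: str) -> str:
    if alt_aa == ref_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    if ref_aa == "*":
        return "stop_loss"
    if codon_idx == 0 and ref_codon == "ATG":
        return "start_loss"
    return "missense"


def _single_base_consequence(
    target: GenomicTarget,
    tpos: int,
    alt_base: str,
    proto_pos: int | None,
    *,
    exonic_seq: str,
    exonic_pos: list[int],
) -> CodonConsequence:
    gpos = target.genome_coordinate(tpos)
    if not target.exon_mask[tpos]:
        cls = _splice_or_intronic(target, tpos)
        return CodonConsequence(proto_pos, gpos, None, None, None, None, cls)
    c = target.cds_index(tpos)
    assert c is not None
    codon = _codon_for(target, c)
    if codon is None:
        return CodonConsequence(proto_pos, gpos, None, None, None, None, "noncoding")
    codon_idx, members = codon
    ref_codon = "".join(exonic_seq[m] for m in members)
    within = members.index(c)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return CodonConsequence(
        protospacer_position=proto_pos,
        genomic_position=gpos,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=_classify(ref_aa, alt_aa, codon_idx, ref_codon),
        protein_position=codon_idx + 1,
    )


def predict_consequences(
    site: CandidateSite,
    target: GenomicTarget,
    editor: EditorProfile,
    *,
    designated_position: int | None = None,
) -> tuple[list[CodonConsequence], CodonConsequence]:
    """Per-base and combined consequences of editing a candidate site.

    Each editable base is evaluated assuming it alone is fully converted;
    the combined consequence assumes simultaneous conversion of every
    substrate base in the active window (the bystander-inclusive outcome).
    Edits on '-' strand sites are complemented onto the coding strand
    before codon lookup. ``designated_position`` marks the intended target
    base so other editable bases can be flagged as bystanders.
    """
    exonic_seq = target.exonic_sequence()
    exonic_pos = _exonic_positions(target)
    # coding-strand substitution installed by this editor at this site
    if site.strand == "+":
        sub, prod = editor.substrate_base, editor.product_base
    else:
        sub = editor.substrate_base.translate(_COMPLEMENT)
        prod = editor.product_base.translate(_COMPLEMENT)
    per_base: list[CodonConsequence] = []
    for p in site.editable_positions:
        tpos = site.target_index(p)
        cons = _single_base_consequence(
            target, tpos, prod, p, exonic_seq=exonic_seq, exonic_pos=exonic_pos
        )
        if designated_position is not None and p != designated_position:
            cons = CodonConsequence(
                **{**cons.__dict__, "is_bystander": True}
            )
        per_base.append(cons)
    combined = _combined_consequence(site, target, prod, exonic_seq)
    return per_base, combined


def _combined_consequence(
    site: CandidateSite,
    target: GenomicTarget,
    coding_product: str,
    exonic_seq: str,
) -> CodonConsequence:
    """Consequence of converting all editable bases simultaneously."""
    edited = {i: b for i, b in enumerate(exonic_seq)}
    exon_edit_cds: list[int] = []
    intron_classes: list[str] = []
    for p in site.editable_positions:
        tpos = site.target_index(p)
        if target.exon_mask[tpos]:
            c = target.cds_index(tpos)
            assert c is not None
            edited[c] = coding_product
            exon_edit_cds.append(c)
        else:
            intron_classes.append(_splice_or_intronic(target, tpos))
    if not exon_edit_cds:
        cls = "splice_site" if "splice_site" in intron_classes else (
            "intronic" if intron_classes else "noncoding"
        )
        return CodonConsequence(None, None, None, None, None, None, cls)
    classes: list[str] = []
    ref_codons, alt_codons = [], []
    seen: set[int] = set()
    first: CodonConsequence | None = None
    for c in exon_edit_cds:
        codon = _codon_for(target, c)
        if codon is None:
            classes.append("noncoding")
            continue
        codon_idx, members = codon
        if codon_idx in seen:
            continue
        seen.add(codon_idx)
        ref_codon = "".join(exonic_seq[m] for m in members)
        alt_codon = "".join(edited[m] for m in members)
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        cls = _classify(ref_aa, alt_aa, codon_idx, ref_codon)
        classes.append(cls)
        ref_codons.append(ref_codon)
        alt_codons.append(alt_codon)
        cand = CodonConsequence(
            None, None, ref_codon, alt_codon, ref_aa, alt_aa, cls,
            protein_position=codon_idx + 1,
        )
        if first is None or _severity(cls) > _severity(first.consequence):
            first = cand
    # aggregate class: most severe over affected codons
    agg = max(classes, key=_severity) if classes else "noncoding"
    assert first is not None
    return CodonConsequence(
        None,
        None,
        first.ref_codon,
        first.alt_codon,
        first.ref_aa,
        first.alt_aa,
        agg,
        protein_position=first.protein_position,
    )


_SEVERITY = {
    "noncoding": 0,
    "intronic": 1,
    "splice_site": 2,
    "synonymous": 3,
    "missense": 4,
    "start_loss": 5,
    "stop_loss": 6,
    "nonsense": 7,
}


def _severity(cls: str) -> int:
    return _SEVERITY[cls]


def design_oligos(
    protospacer: str,
    *,
    overhang_forward: str = "TAGG",
    overhang_reverse: str = "AAAC",
    mode: str = "replace-two",
) -> OligoPair:
    """Annealed-oligo pair for sgRNA cloning into a T7 vector (DR274-style).

    T7 initiates efficiently on G, so when the protospacer does not start
    with G its 5' end is substituted: in ``replace-two`` mode (default) the
    two most-5' bases both become G; ``replace-one`` substitutes only the
    first. A protospacer already starting with G is used unchanged.
    """
    proto = protospacer.upper()
    if len(proto) != 20:
        raise ValueError(f"protospacer must be 20 nt, got {len(proto)}")
    if proto[0] == "G":
        spacer, n_sub = proto, 0
    elif mode == "replace-two":
        spacer, n_sub = "GG" + proto[2:], 2
    elif mode == "replace-one":
        spacer, n_sub = "G" + proto[1:], 1
    else:
        raise ValueError(f"unknown 5'-G substitution mode: {mode!r}")
    return OligoPair(
        forward=overhang_forward + spacer,
        reverse=overhang_reverse + reverse_complement(spacer),
        spacer=spacer,
        g_substituted=n_sub,
    )


def design_guides(
    target: GenomicTarget,
    editor: EditorProfile,
    *,
    window_override: tuple[int, int] | None = None,
    oligo_overhangs: tuple[str, str] = ("TAGG", "AAAC"),
    oligo_mode: str = "replace-two",
) -> list[ScoredGuide]:
    """Scan, annotate, score and order all guides on a target.

    Guides are returned ranked by descending best score (ties by position).
    With ``window_override`` set the user has changed the editing-window
    limits; the published penalty constants no longer apply, so guides are
    reported unscored in positional order.
    """
    sites = scan_protospacers(target, editor, window=window_override)
    guides: list[ScoredGuide] = []
    for site in sites:
        per_cons, combined = predict_consequences(site, target, editor)
        per_base: list[tuple[ScoreBreakdown | None, CodonConsequence]] = []
        best: ScoreBreakdown | None = None
        if window_override is None:
            scored = []
            for p, cons in zip(site.editable_positions, per_cons):
                preceding = site.protospacer[p - 2] if p >= 2 else site.flank5
                bd = base_score(editor, p, preceding)
                scored.append((p, preceding))
                per_base.append((bd, cons))
            best, _ = guide_score(editor, scored)
        else:
            per_base = [(None, cons) for cons in per_cons]
        oligos = design_oligos(
            site.protospacer,
            overhang_forward=oligo_overhangs[0],
            overhang_reverse=oligo_overhangs[1],
            mode=oligo_mode,
        )
        guides.append(
            ScoredGuide(
                site=site,
                editor=editor.name,
                per_base=per_base,
                best=best,
                combined_consequence=combined,
                oligos=oligos,
            )
        )
    if window_override is None:
        guides.sort(
            key=lambda g: (
                -(g.best.S if g.best else float("-inf")),
                g.site.start,
                0 if g.site.strand == "+" else 1,
            )
        )
    return guides
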