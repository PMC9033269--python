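"""Standard-format input/output: FASTA, GFF3/BED, VCF (minimal), TSV/BED.

Conventions: coordinates are 0-based half-open internally and in BED
output, 1-based inclusive in human-readable TSV reports (stated in every
output header). Sequences are uppercased on ingestion.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

from .modelability import OrthologSite, VariantRecord
from .offtargets import OffTargetHit
from .design import ScoredGuide


class EmptyInputError(ValueError):
    pass


class FastaParseError(ValueError):
    pass


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an uppercased name -> sequence mapping.

    The file is indexed with pyfaidx (creating ``.fai`` beside it when
    writable); malformed input raises :class:`FastaParseError` with the
    offending line when determinable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")
    # cheap validation pass for a clear error with a line number
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise FastaParseError(f"{path}:1: expected '>' header, got {first[:30]!r}")
    try:
        fa = Fasta(str(path), sequence_always_upper=True, rebuild=True)
    except Exception as exc:  # pyfaidx error classes vary
        raise FastaParseError(f"{path}: {exc}") from exc
    out = {name: str(fa[name][:]) for name in fa.keys()}
    if not out:
        raise EmptyInputError(f"{path} contains no records")
    return out


def write_fasta(path: str | os.PathLike, records: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class GeneModel:
    """A minimal gene model: span + exon intervals (0-based half-open)."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA + exon features) or BED12."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".bed", ".bed12"}:
        return _parse_bed12(text)
    return _parse_gff3(text)


def _parse_gff3(text: str) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for ln, line in enumerate(text.splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"GFF3 line {ln}: expected 9 columns, got {len(parts)}")
        chrom, _, ftype, start, end, _, strand, _, attrs = parts
        tags = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        if ftype == "gene":
            gid = tags.get("ID", f"gene{ln}")
            genes[gid] = GeneModel(
                name=tags.get("Name", gid),
                chrom=chrom,
                start=int(start) - 1,
                end=int(end),
                strand=strand,
            )
        elif ftype in {"exon", "CDS"}:
            parent = tags.get("Parent", tags.get("ID", "?"))
            # exon parents may be transcripts: strip one suffix level
            exons.setdefault(parent.split(".")[0], []).append(
                (int(start) - 1, int(end))
            )
    out = []
    for gid, gene in genes.items():
        ex = sorted(set(exons.get(gid, [])))
        gene.exons = ex if ex else [(gene.start, gene.end)]
        out.append(gene)
    return out


def _parse_bed12(text: str) -> list[GeneModel]:
    out = []
    for ln, line in enumerate(text.splitlines(), 1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        p = line.split("\t")
        if len(p) < 12:
            raise ValueError(f"BED12 line {ln}: expected 12 columns, got {len(p)}")
        start = int(p[1])
        sizes = [int(x) for x in p[10].rstrip(",").split(",")]
        offsets = [int(x) for x in p[11].rstrip(",").split(",")]
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        out.append(
            GeneModel(
                name=p[3], chrom=p[0], start=start, end=int(p[2]),
                strand=p[5], exons=exons,
            )
        )
    return out


def read_variants(path: str | os.PathLike) -> list[VariantRecord]:
    """Read SNVs from a minimal VCF (INFO CLNSIG + MC SO terms) or a TSV
    with columns chrom, pos, ref, alt, clnsig, so_terms[, variant_id]."""
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out = []
    for _, row in df.iterrows():
        terms = tuple(
            t for t in str(row.get("so_terms", "")).split(",") if t and t != "nan"
        )
        out.append(
            VariantRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]).upper(),
                alt=str(row["alt"]).upper(),
                clinical_significance=str(row.get("clnsig", "")),
                consequence_terms=terms,
                variant_id=str(row.get("variant_id", "")),
            )
        )
    return out


def _read_vcf(path: Path) -> list[VariantRecord]:
    from pysam import VariantFile

    out = []
    with VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            info = rec.info
            clnsig = info.get("CLNSIG", ("",))
            clnsig = clnsig[0] if isinstance(clnsig, tuple) else str(clnsig)
            mc = info.get("MC", ())
            if isinstance(mc, str):
                mc = (mc,)
            terms = tuple(m.split("|")[0] for m in mc)
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    clinical_significance=str(clnsig),
                    consequence_terms=terms,
                    variant_id=rec.id or f"{rec.chrom}:{rec.pos}{ref}>{alt}",
                )
            )
    return out


def read_ortholog_table(path: str | os.PathLike) -> dict[str, OrthologSite]:
    """Ortholog alignment fixture TSV: variant_id, fish_chrom, fish_pos,
    fish_base, unique_alignment (0/1), strand, fish_context."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out = {}
    for _, row in df.iterrows():
        site = OrthologSite(
            variant_id=str(row["variant_id"]),
            fish_chrom=str(row["fish_chrom"]),
            fish_pos=int(row["fish_pos"]),
            fish_base=str(row["fish_base"]).upper(),
            unique_alignment=str(row["unique_alignment"]) in {"1", "True", "true"},
            strand=str(row.get("strand", "+")),
            fish_context=str(row.get("fish_context", "")).upper(),
        )
        out[site.variant_id] = site
    return out


# --------------------------------------------------------------------------
# report writers

_GUIDE_HEADER = (
    "# guide report; coordinates 1-based inclusive on the target "
    "forward strand; protospacer 5'->3' on the site strand\n"
)


def guides_to_frame(guides: Sequence[ScoredGuide]) -> pd.DataFrame:
    rows = []
    for g in guides:
        per = "; ".join(
            f"{c.protospacer_position}:{c.consequence}:{c.hgvs_p()}"
            for _, c in g.per_base
        )
        rows.append(
            {
                "protospacer": g.site.protospacer,
                "pam": g.site.pam,
                "strand": g.site.strand,
                "start": g.site.start + 1,
                "end": g.site.start + 20,
                "editable_positions": ",".join(map(str, g.site.editable_positions)),
                "best_score": "" if g.best is None else g.best.S,
                "best_position": "" if g.best is None else g.best.position,
                "combined_consequence": (
                    g.combined_consequence.consequence
                    if g.combined_consequence
                    else ""
                ),
                "per_base": per,
                "oligo_fwd": g.oligos.forward,
                "oligo_rev": g.oligos.reverse,
                "g_substituted": g.oligos.g_substituted,
            }
        )
    return pd.DataFrame(rows)


def write_guides_tsv(path: str | os.PathLike, guides: Sequence[ScoredGuide]) -> None:
    with open(path, "w") as fh:
        fh.write(_GUIDE_HEADER)
        guides_to_frame(guides).to_csv(fh, sep="\t", index=False)


def write_guides_bed(
    path: str | os.PathLike, guides: Sequence[ScoredGuide], chrom: str = "target"
) -> None:
    with open(path, "w") as fh:
        for i, g in enumerate(guides):
            score = 0 if g.best is None else max(0, round(g.best.S * 100))
            fh.write(
                f"{chrom}\t{g.site.start}\t{g.site.start + 20}\t"
                f"guide{i + 1}\t{score}\t{g.site.strand}\n"
            )


_OT_HEADER = (
    "# off-target report; start/end 0-based half-open on the forward strand; "
    "mismatch positions 1-based on the protospacer (1 = PAM-distal)\n"
)


def offtargets_to_frame(hits: Sequence[OffTargetHit], spacer: str) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append(
            {
                "spacer": spacer,
                "site": h.site_sequence,
                "chrom": h.chrom,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "mismatch_positions": ",".join(map(str, h.mismatch_positions)),
                "n_mismatches": h.n_mismatches,
                "core_mismatches": h.core_mismatches,
                "editable_in_window": int(h.editable_in_window),
                "threat_score": round(h.threat_score, 4),
                "context": h.context,
            }
        )
    return pd.DataFrame(rows)


def write_offtargets_tsv(
    path: str | os.PathLike, hits: Sequence[OffTargetHit], spacer: str
) -> None:
    with open(path, "w") as fh:
        fh.write(_OT_HEADER)
        offtargets_to_frame(hits, spacer).to_csv(fh, sep="\t", index=False)


def write_offtargets_bed(path: str | os.PathLike, hits: Sequence[OffTargetHit]) -> None:
    with open(path, "w") as fh:
        for i, h in enumerate(hits):
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\tot{i + 1}\t"
                f"{round(h.threat_score * 10)}\t{h.strand}\n"
            )


def modelability_to_frame(rows) -> pd.DataFrame:
    out = []
    for rec, status, res in rows:
        out.append(
            {
                "variant_id": rec.variant_id or f"{rec.chrom}:{rec.pos}{rec.ref}>{rec.alt}",
                "status": status,
                "editor_class": res.editor_class if res else "",
                "stringent": int(res.stringent) if res else "",
                "permissive": int(res.permissive) if res else "",
                "n_guides": len(res.candidate_guides) if res else 0,
                "guides": "; ".join(
                    f"{g.protospacer}[{g.pam}]{g.strand}@{g.window_position}"
                    for g in (res.candidate_guides if res else ())
                ),
            }
        )
    return pd.DataFrame(out)
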