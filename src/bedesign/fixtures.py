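"""Deterministic synthetic fixtures: genomes with planted off-target decoys,
spliced gene models, and variant tables with known modelability truth.

Everything is generated from a seed, verified by construction (planted
decoys are re-checked exhaustively so no accidental near-match of the
spacer exists) and exportable as plain-text FASTA / GFF3 / TSV, so every
test and the acceptance checks run without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .io import GeneModel, write_fasta
from .modelability import OrthologSite, VariantRecord
from .offtargets import SPACER_LENGTH, SearchConfig, find_offtargets

_ALPHABET = np.array(list("ACGT"))

# the 61 sense codons of the standard code
_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in _STOPS
]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def mismatch_profile(total: int, core: int, core_length: int = 12) -> tuple[int, ...]:
    """Deterministic mismatch positions: ``core`` mismatches packed at the
    PAM-proximal end, the rest at the PAM-distal end."""
    if core > total:
        raise ValueError("core mismatches exceed total")
    if core > core_length or total - core > SPACER_LENGTH - core_length:
        raise ValueError("profile does not fit the spacer")
    positions = list(range(SPACER_LENGTH, SPACER_LENGTH - core, -1))
    positions += list(range(1, total - core + 1))
    return tuple(sorted(positions))


@dataclass
class PlantedSite:
    spacer: str
    mismatch_positions: tuple[int, ...]
    strand: str
    start: int = -1  # forward-strand 0-based protospacer start, filled on placement
    site_sequence: str = ""
    pam: str = ""

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


@dataclass
class FixtureGenome:
    seed: int
    genome: dict[str, str]
    planted: list[PlantedSite]
    chrom: str = "fchr1"

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": self.chrom,
                    "start": p.start,
                    "end": p.start + SPACER_LENGTH,
                    "strand": p.strand,
                    "spacer": p.spacer,
                    "site": p.site_sequence,
                    "pam": p.pam,
                    "mismatch_positions": ",".join(map(str, p.mismatch_positions)),
                    "n_mismatches": p.n_mismatches,
                }
                for p in self.planted
            ]
        )

    def write(self, fasta_path, truth_path) -> None:
        write_fasta(fasta_path, self.genome)
        with open(truth_path, "w") as fh:
            fh.write("# planted decoy truth table; start/end 0-based half-open\n")
            self.truth_frame().to_csv(fh, sep="\t", index=False)


def _mutate(rng: np.random.Generator, spacer: str, positions: tuple[int, ...]) -> str:
    site = list(spacer)
    for p in positions:
        orig = site[p - 1]
        site[p - 1] = rng.choice([b for b in "ACGT" if b != orig])
    return "".join(site)


def make_fixture_genome(
    seed: int,
    length: int,
    planted_sites: list[tuple[str, tuple[int, ...], str]],
    *,
    chrom: str = "fchr1",
    max_attempts: int = 25,
    verify_mismatch_limit: int | None = None,
) -> FixtureGenome:
    """A random genome carrying each planted near-match of a spacer exactly
    once and, verified exhaustively, no accidental admissible near-match.

    ``planted_sites`` lists (spacer, mismatch positions, strand); each site
    gets a random NGG PAM and is placed at a spaced, jittered coordinate.
    Construction is verified with an exhaustive search up to
    ``verify_mismatch_limit`` total mismatches (default: the largest
    planted count, at least 4); on accidental matches the genome is
    resampled, failing after ``max_attempts``.
    """
    spacers = sorted({s for s, _, _ in planted_sites})
    max_planted = max((len(p) for _, p, _ in planted_sites), default=0)
    vlimit = verify_mismatch_limit or max(4, max_planted)
    n = len(planted_sites)
    margin = 50
    for attempt in range(max_attempts):
        rng = np.random.default_rng((seed, attempt))
        seq = list(_random_seq(rng, length))
        slot = (length - 2 * margin) // max(n, 1)
        if slot < SPACER_LENGTH + 10:
            raise ValueError("genome too short for the requested sites")
        planted: list[PlantedSite] = []
        for i, (spacer, positions, strand) in enumerate(planted_sites):
            spacer = spacer.upper()
            site = _mutate(rng, spacer, tuple(positions))
            pam = rng.choice(list("ACGT")) + "GG"
            pos = margin + i * slot + int(rng.integers(0, slot - SPACER_LENGTH - 10))
            if strand == "+":
                block = site + pam
                seq[pos : pos + len(block)] = block
                start = pos
            else:
                block = reverse_complement(site + pam)
                seq[pos : pos + len(block)] = block
                start = pos + 3  # protospacer begins after the (revcomp) PAM
            planted.append(
                PlantedSite(
                    spacer=spacer,
                    mismatch_positions=tuple(sorted(positions)),
                    strand=strand,
                    start=start,
                    site_sequence=site,
                    pam=pam,
                )
            )
        genome = {chrom: "".join(seq)}
        if _verify_planted(genome, chrom, spacers, planted, vlimit):
            return FixtureGenome(seed=seed, genome=genome, planted=planted, chrom=chrom)
    raise RuntimeError(
        f"could not place {n} decoys without accidental near-matches "
        f"after {max_attempts} attempts"
    )


def _verify_planted(
    genome: dict[str, str],
    chrom: str,
    spacers: list[str],
    planted: list[PlantedSite],
    vlimit: int,
) -> bool:
    cfg = SearchConfig(
        max_total_mismatches=vlimit, max_core_mismatches=vlimit, core_length=12
    )
    for spacer in spacers:
        expected = {
            (chrom, p.start, p.strand) for p in planted if p.spacer == spacer
        }
        found = {
            (h.chrom, h.start, h.strand) for h in find_offtargets(spacer, genome, cfg)
        }
        if found != expected:
            return False
    return True


# --------------------------------------------------------------------------
# spliced gene fixture


@dataclass
class GeneFixture:
    genome: dict[str, str]
    chrom: str
    gene: GeneModel
    query: str  # exon concatenation (the spliced transcript CDS)
    cds: str
    gff3: str
    frame_offset: int = 0

    @property
    def exons(self) -> list[tuple[int, int]]:
        return self.gene.exons


def make_fixture_gene(
    seed: int,
    *,
    exon_lengths: tuple[int, ...] = (120, 141),
    intron_length: int = 200,
    flank: int = 300,
    chrom: str = "chr1",
    name: str = "geneA",
) -> GeneFixture:
    """A gene with a stop-free CDS split over exons by GT..AG introns.

    The CDS starts with ATG, continues with sense codons only, and is cut
    into ``exon_lengths`` pieces separated by ``intron_length``-nt introns;
    ``flank`` nt of random sequence pad each side. Identical seeds give
    identical bytes.
    """
    rng = np.random.default_rng(seed)
    cds_len = sum(exon_lengths)
    if cds_len % 3:
        raise ValueError("exon lengths must sum to a codon multiple")
    codons = ["ATG"] + list(rng.choice(SENSE_CODONS, size=cds_len // 3 - 1))
    cds = "".join(codons)
    pieces = []
    exons: list[tuple[int, int]] = []
    pos = flank
    offset = 0
    left = _random_seq(rng, flank)
    pieces.append(left)
    for i, el in enumerate(exon_lengths):
        exon_seq = cds[offset : offset + el]
        pieces.append(exon_seq)
        exons.append((pos, pos + el))
        pos += el
        offset += el
        if i < len(exon_lengths) - 1:
            intron = "GT" + _random_seq(rng, intron_length - 4) + "AG"
            pieces.append(intron)
            pos += intron_length
    pieces.append(_random_seq(rng, flank))
    seq = "".join(pieces)
    gene = GeneModel(
        name=name, chrom=chrom, start=exons[0][0], end=exons[-1][1],
        strand="+", exons=exons,
    )
    gff3_lines = [
        "##gff-version 3",
        f"{chrom}\tfixture\tgene\t{gene.start + 1}\t{gene.end}\t.\t+\t.\tID={name};Name={name}",
    ]
    phase = 0
    for i, (s, e) in enumerate(exons):
        gff3_lines.append(
            f"{chrom}\tfixture\texon\t{s + 1}\t{e}\t.\t+\t{phase}\tParent={name}"
        )
        phase = (3 - ((e - s) - phase) % 3) % 3
    return GeneFixture(
        genome={chrom: seq},
        chrom=chrom,
        gene=gene,
        query=cds,
        cds=cds,
        gff3="\n".join(gff3_lines) + "\n",
    )


# --------------------------------------------------------------------------
# modelability variant table with construction truth

MODELABILITY_CATEGORIES = (
    "CBE_stringent",
    "CBE_permissive",
    "CBE_stringent_minus",
    "ABE_stringent",
    "ABE_permissive",
    "transversion",
    "diverged",
    "ambiguous",
    "not_pathogenic",
    "noncoding_SO",
)

_CTX_LEN = 47  # odd; center index 23
_TARGET_WINDOW_POS = 6  # window position at which the target base is placed


def _build_context(substrate: str, *, bystander: bool) -> str:
    """A context with exactly one admissible NGG guide placing the center
    base (the substrate) at window position 6.

    The background alternates two non-substrate, non-G bases so no other
    NGG PAM and no stray substrate base can create additional guides or
    bystanders; ``bystander`` plants one extra substrate base at window
    position 7 of the unique guide.
    """
    if substrate == "C":
        bg = "AT"  # no C, no G outside the planted PAM
    else:
        bg = "CT"  # no A, no G outside the planted PAM
    ctx = [bg[i % 2] for i in range(_CTX_LEN)]
    center = _CTX_LEN // 2
    ctx[center] = substrate
    s = center - (_TARGET_WINDOW_POS - 1)  # protospacer start
    ctx[s + 21] = "G"  # PAM NGG at s+20..s+22
    ctx[s + 22] = "G"
    if bystander:
        ctx[s + 6] = substrate  # window position 7
    return "".join(ctx)


def make_variant_table(
    seed: int, n: int = 200
) -> tuple[list[VariantRecord], dict[str, OrthologSite], pd.DataFrame]:
    """``n`` synthetic variants cycling through known-truth categories.

    Covers stringently and permissively CBE/ABE-modelable transitions
    (including G->A handled via the opposite strand), transversions,
    diverged and ambiguous orthologs, non-pathogenic entries and
    noncoding-consequence entries. Returns the variant records, the
    ortholog sites keyed by variant id, and the construction-truth table.
    """
    rng = np.random.default_rng(seed)
    variants: list[VariantRecord] = []
    sites: dict[str, OrthologSite] = {}
    truth_rows = []
    for i in range(n):
        cat = MODELABILITY_CATEGORIES[i % len(MODELABILITY_CATEGORIES)]
        vid = f"var{i + 1:04d}"
        pos = 1000 + i * 100
        fish_pos = 5000 + i * 100
        clnsig = "Pathogenic"
        terms = ("SO:0001583",)
        strand = "+"
        unique = True
        expected_status = "ok"
        if cat == "CBE_stringent":
            ref, alt = "C", "T"
            ctx = _build_context("C", bystander=False)
            fish_base = "C"
            exp = ("CBE", True, True)
        elif cat == "CBE_permissive":
            ref, alt = "C", "T"
            ctx = _build_context("C", bystander=True)
            fish_base = "C"
            exp = ("CBE", False, True)
        elif cat == "CBE_stringent_minus":
            # human G->A; the fish context is the plus strand, so the CBE
            # must address the complementary C on the minus strand
            ref, alt = "G", "A"
            ctx = reverse_complement(_build_context("C", bystander=False))
            fish_base = "G"
            exp = ("CBE", True, True)
        elif cat == "ABE_stringent":
            ref, alt = "A", "G"
            ctx = _build_context("A", bystander=False)
            fish_base = "A"
            exp = ("ABE", True, True)
        elif cat == "ABE_permissive":
            ref, alt = "A", "G"
            ctx = _build_context("A", bystander=True)
            fish_base = "A"
            exp = ("ABE", False, True)
        elif cat == "transversion":
            ref, alt = "C", "G"
            ctx = _build_context("C", bystander=False)
            fish_base = "C"
            exp = ("none", False, False)
        elif cat == "diverged":
            ref, alt = "C", "T"
            ctx = _build_context("A", bystander=False)
            fish_base = "A"  # differs from the human ref
            exp = ("", False, False)
            expected_status = "diverged"
        elif cat == "ambiguous":
            ref, alt = "C", "T"
            ctx = _build_context("C", bystander=False)
            fish_base = "C"
            unique = False
            exp = ("", False, False)
            expected_status = "ambiguous"
        elif cat == "not_pathogenic":
            ref, alt = "C", "T"
            ctx = _build_context("C", bystander=False)
            fish_base = "C"
            clnsig = "Likely_pathogenic"
            exp = ("", False, False)
            expected_status = "filtered"
        else:  # noncoding_SO
            ref, alt = "C", "T"
            ctx = _build_context("C", bystander=False)
            fish_base = "C"
            terms = ("SO:0001627",)  # intron_variant
            exp = ("", False, False)
            expected_status = "filtered"
        variants.append(
            VariantRecord(
                chrom=f"chr{int(rng.integers(1, 23))}",
                pos=pos,
                ref=ref,
                alt=alt,
                clinical_significance=clnsig,
                consequence_terms=terms,
                variant_id=vid,
            )
        )
        sites[vid] = OrthologSite(
            variant_id=vid,
            fish_chrom="fchr1",
            fish_pos=fish_pos,
            fish_base=fish_base,
            unique_alignment=unique,
            strand=strand,
            fish_context=ctx,
        )
        truth_rows.append(
            {
                "variant_id": vid,
                "category": cat,
                "expected_status": expected_status,
                "expected_class": exp[0],
                "expected_stringent": exp[1],
                "expected_permissive": exp[2],
            }
        )
    return variants, sites, pd.DataFrame(truth_rows)


def write_variant_table(path, variants: list[VariantRecord]) -> None:
    rows = [
        {
            "variant_id": v.variant_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "clnsig": v.clinical_significance,
            "so_terms": ",".join(v.consequence_terms),
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ortholog_table(path, sites: dict[str, OrthologSite]) -> None:
    rows = [
        {
            "variant_id": s.variant_id,
            "fish_chrom": s.fish_chrom,
            "fish_pos": s.fish_pos,
            "fish_base": s.fish_base,
            "unique_alignment": int(s.unique_alignment),
            "strand": s.strand,
            "fish_context": s.fish_context,
        }
        for s in sites.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
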