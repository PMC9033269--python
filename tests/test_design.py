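"""Protospacer scanning, codon consequences, oligos and guide assembly."""

import numpy as np
import pytest
from Bio.Seq import Seq, reverse_complement

from bedesign.design import (
    design_guides,
    design_oligos,
    predict_consequences,
    scan_protospacers,
)
from bedesign.fixtures import SENSE_CODONS
from bedesign.mapping import GenomicTarget, target_from_query

from conftest import KCNH6A_R512, OCA2_Q333


def _brute_force_sites(seq, substrate, window):
    """Independent protospacer enumeration by direct slicing."""
    lo, hi = window
    found = set()
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for i in range(len(s) - 22):
            if s[i + 21 : i + 23] == "GG":
                proto = s[i : i + 20]
                if any(proto[p - 1] == substrate for p in range(lo, hi + 1)):
                    start = i if strand == "+" else len(s) - i - 20
                    found.add((start, strand, proto))
    return found


class TestScan:
    def test_oca2_site_found_for_any_cbe(self, profiles):
        seq = "TTTT" + OCA2_Q333[0] + OCA2_Q333[1] + "TTTT"
        tg = target_from_query(seq)
        for name in ("BE4-Gam", "ancBE4max", "evoBE4max"):
            sites = [
                s
                for s in scan_protospacers(tg, profiles[name], window=(4, 8))
                if s.strand == "+" and s.protospacer == OCA2_Q333[0]
            ]
            assert len(sites) == 1
            assert sites[0].editable_positions == (5, 6, 7)
            assert sites[0].pam == "AGG"
            assert sites[0].flank5 == "T"

    def test_no_pam_no_sites(self, profiles):
        tg = target_from_query("A" * 60)
        assert scan_protospacers(tg, profiles["ABE8e"]) == []

    def test_sites_ordered_by_start_then_strand(self, profiles):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        sites = scan_protospacers(target_from_query(seq), profiles["evoBE4max"])
        keys = [(s.start, 0 if s.strand == "+" else 1) for s in sites]
        assert keys == sorted(keys)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_and_mirrors_under_revcomp(self, profiles, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        prof = profiles["evoBE4max"]
        got = {
            (s.start, s.strand, s.protospacer)
            for s in scan_protospacers(target_from_query(seq), prof)
        }
        assert got == _brute_force_sites(seq, "C", prof.observed_window)
        # scanning the reverse complement flips strands, mirrors coordinates
        rc = {
            (len(seq) - s.start - 20, {"+": "-", "-": "+"}[s.strand], s.protospacer)
            for s in scan_protospacers(
                target_from_query(reverse_complement(seq)), prof
            )
        }
        assert rc == got


class TestConsequences:
    def test_oca2_cbe_stop_at_c7(self, profiles):
        tg = target_from_query(OCA2_Q333[0] + OCA2_Q333[1])
        site = [
            s
            for s in scan_protospacers(tg, profiles["evoBE4max"], window=(4, 8))
            if s.strand == "+" and s.start == 0
        ][0]
        per, combined = predict_consequences(site, tg, profiles["evoBE4max"])
        by_pos = {c.protospacer_position: c for c in per}
        assert by_pos[7].consequence == "nonsense"
        assert (by_pos[7].ref_codon, by_pos[7].alt_codon) == ("CAG", "TAG")
        assert by_pos[6].consequence == "synonymous"
        assert by_pos[5].consequence == "missense"  # Thr -> Ile
        assert combined.consequence == "nonsense"

    def test_oca2_abe_missense_pair(self, profiles):
        tg = target_from_query(OCA2_Q333[0] + OCA2_Q333[1])
        site = [
            s
            for s in scan_protospacers(tg, profiles["ABE8e"], window=(4, 8))
            if s.strand == "+" and s.start == 0
        ][0]
        per, combined = predict_consequences(site, tg, profiles["ABE8e"])
        by_pos = {c.protospacer_position: c for c in per}
        assert by_pos[4].hgvs_p() == "p.T2A"  # ACC -> GCC
        assert by_pos[8].hgvs_p() == "p.Q3R"  # CAG -> CGG
        assert combined.consequence == "missense"

    def test_kcnh6a_single_window_adenine(self, profiles):
        tg = target_from_query(KCNH6A_R512[0] + KCNH6A_R512[1])
        sites = [
            s
            for s in scan_protospacers(tg, profiles["ABE8e"], window=(4, 8))
            if s.strand == "+" and s.start == 0
        ]
        assert sites[0].editable_positions == (8,)

    def test_minus_strand_consistent_with_coding_substitution(self, profiles):
        # editing a '-' site must equal complementing the edit onto the
        # coding strand: plant a CCN PAM so a CBE site lies on '-'
        rng = np.random.default_rng(3)
        for _ in range(20):
            cds = "ATG" + "".join(rng.choice(SENSE_CODONS, size=20))
            tg = target_from_query(cds)
            prof = profiles["evoBE4max"]
            for site in scan_protospacers(tg, prof):
                if site.strand != "-":
                    continue
                per, _ = predict_consequences(site, tg, prof)
                for cons in per:
                    p = cons.protospacer_position
                    tpos = site.target_index(p)
                    assert cds[tpos] == "G"  # coding strand shows G for a '-' C
                    edited = cds[:tpos] + "A" + cds[tpos + 1 :]
                    ref_aa = str(Seq(cds[: len(cds) // 3 * 3]).translate())
                    alt_aa = str(Seq(edited[: len(edited) // 3 * 3]).translate())
                    if cons.consequence == "synonymous":
                        assert ref_aa == alt_aa
                    elif cons.consequence == "nonsense":
                        assert "*" in alt_aa and alt_aa != ref_aa

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_codon_table_oracle(self, profiles, seed):
        """Per-base calls vs direct whole-protein translation on random CDS."""
        rng = np.random.default_rng(seed)
        prof = profiles["ancBE4max"]
        for _ in range(200):
            cds = "ATG" + "".join(rng.choice(SENSE_CODONS, size=15))
            tg = target_from_query(cds)
            for site in scan_protospacers(tg, prof):
                per, _ = predict_consequences(site, tg, prof)
                for cons in per:
                    tpos = site.target_index(cons.protospacer_position)
                    alt = "T" if site.strand == "+" else "A"
                    edited = cds[:tpos] + alt + cds[tpos + 1 :]
                    ref_p = str(Seq(cds).translate())
                    alt_p = str(Seq(edited).translate())
                    if ref_p == alt_p:
                        expect = "synonymous"
                    else:
                        diff = next(
                            (a, b) for a, b in zip(ref_p, alt_p) if a != b
                        )
                        if diff[1] == "*":
                            expect = "nonsense"
                        elif cons.protein_position == 1 and cds[:3] == "ATG":
                            expect = "start_loss"
                        else:
                            expect = "missense"
                    assert cons.consequence == expect, (cds, site, cons)

    def test_intronic_and_splice_site_classes(self, profiles, gene_fixture):
        from bedesign.mapping import map_query, reconstruct_genomic

        aln = map_query(gene_fixture.query, gene_fixture.genome)
        tg = reconstruct_genomic(aln, gene_fixture.genome)
        prof = profiles["evoBE4max"]
        intron_found = 0
        for site in scan_protospacers(tg, prof):
            per, _ = predict_consequences(site, tg, prof)
            for cons in per:
                tpos = site.target_index(cons.protospacer_position)
                if not tg.exon_mask[tpos]:
                    intron_found += 1
                    assert cons.consequence in {"intronic", "splice_site"}
        assert intron_found > 0  # a 200-nt intron must yield some intronic calls

    def test_combined_equals_per_base_for_single_substrate(self, profiles):
        # exactly one editable base -> combined outcome is that base's outcome
        tg = target_from_query(KCNH6A_R512[0] + KCNH6A_R512[1])
        site = [
            s
            for s in scan_protospacers(tg, profiles["ABE8e"], window=(4, 8))
            if s.strand == "+" and s.start == 0
        ][0]
        per, combined = predict_consequences(site, tg, profiles["ABE8e"])
        assert len(per) == 1
        assert combined.consequence == per[0].consequence


class TestOligos:
    def test_leading_g_unchanged(self):
        pair = design_oligos("GGAGCGCCAAAAACGTCTTG")
        assert pair.g_substituted == 0
        assert pair.forward == "TAGG" + "GGAGCGCCAAAAACGTCTTG"

    def test_non_g_start_replaces_two(self):
        pair = design_oligos("AGAGCGCCAAAAACGTCTTG")
        assert pair.spacer == "GGAGCGCCAAAAACGTCTTG"
        assert pair.g_substituted == 2

    def test_replace_one_mode(self):
        pair = design_oligos("AGAGCGCCAAAAACGTCTTG", mode="replace-one")
        assert pair.spacer == "GGAGCGCCAAAAACGTCTTG"[:1] + "GAGCGCCAAAAACGTCTTG"
        assert pair.g_substituted == 1

    def test_reverse_is_revcomp_of_spacer(self):
        pair = design_oligos("AGAGCGCCAAAAACGTCTTG")
        assert pair.reverse == "AAAC" + reverse_complement(pair.spacer)
        assert reverse_complement(pair.reverse[4:]) == pair.spacer

    def test_custom_overhangs(self):
        pair = design_oligos(
            "GTACAGCGACTGGTTAGTCA", overhang_forward="ACCG", overhang_reverse="AAAC"
        )
        assert pair.forward.startswith("ACCG")

    def test_length_validated(self):
        with pytest.raises(ValueError, match="20 nt"):
            design_oligos("ACGT")


class TestDesignGuides:
    def test_peak_tc_context_outranks_edge_gc(self, profiles):
        # two planted CBE sites: a TC-context peak-window C should rank
        # above a GC-context edge-of-window C
        good = "AAATTCAAAATTTATTTAAA"  # C at position 6 (peak), preceded by T
        poor = "AATTTTTTTGCTTTTTTTTT"  # C at position 11 (outside peak), after G
        seq = good + "TGG" + "ATAT" * 3 + poor + "AGG"
        tg = target_from_query(seq)
        guides = design_guides(tg, profiles["evoBE4max"])
        protos = [g.site.protospacer for g in guides]
        assert protos.index(good) < protos.index(poor)
        assert guides[0].best.S >= guides[-1].best.S

    def test_single_site_singleton(self, profiles):
        tg = target_from_query(KCNH6A_R512[0] + KCNH6A_R512[1])
        guides = [
            g
            for g in design_guides(tg, profiles["ABE8e"])
            if g.site.strand == "+" and g.site.start == 0
        ]
        assert len(guides) == 1

    def test_ranking_is_permutation_of_scan(self, profiles):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=800))
        tg = target_from_query(seq)
        prof = profiles["ancBE4max"]
        guides = design_guides(tg, prof)
        scanned = scan_protospacers(tg, prof)
        assert sorted((g.site.start, g.site.strand) for g in guides) == sorted(
            (s.start, s.strand) for s in scanned
        )
        scores = [g.best.S for g in guides]
        assert scores == sorted(scores, reverse=True)

    def test_window_override_disables_ranking(self, profiles):
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        tg = target_from_query(seq)
        guides = design_guides(tg, profiles["evoBE4max"], window_override=(2, 10))
        assert all(g.best is None for g in guides)
        starts = [(g.site.start, g.site.strand) for g in guides]
        assert starts == sorted(starts, key=lambda t: (t[0], t[1] == "-"))

    def test_scores_match_editor_module(self, profiles):
        from bedesign.editors import base_score

        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        tg = target_from_query(seq)
        prof = profiles["evoBE4max"]
        for g in design_guides(tg, prof):
            for bd, _ in g.per_base:
                p = bd.position
                preceding = (
                    g.site.protospacer[p - 2] if p >= 2 else g.site.flank5
                )
                assert bd.S == pytest.approx(base_score(prof, p, preceding).S)
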