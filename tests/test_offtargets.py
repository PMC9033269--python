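"""Off-target search: mismatch limits, ranking, context annotation."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from bedesign.fixtures import make_fixture_genome, mismatch_profile
from bedesign.io import GeneModel
from bedesign.offtargets import (
    OffTargetHit,
    SearchConfig,
    annotate_context,
    filter_editable,
    find_offtargets,
    rank_offtargets,
    threat_score,
)

from conftest import OCA2_Q333

SPACER = OCA2_Q333[0]


def _oracle_scan(spacer, genome, max_total, max_core, core_len=12, pam_len=3):
    """Independent exhaustive scan: slice every PAM window, count mismatches
    by direct base comparison (no early abort, no shared code path)."""
    hits = set()
    for chrom, fwd in genome.items():
        fwd = fwd.upper()
        n = len(fwd)
        for strand in "+-":
            for i in range(n):
                if strand == "+":
                    if i + 20 + pam_len > n:
                        continue
                    site, pam = fwd[i : i + 20], fwd[i + 20 : i + 20 + pam_len]
                else:
                    if i - pam_len < 0 or i + 20 > n:
                        continue
                    site = reverse_complement(fwd[i : i + 20])
                    pam = reverse_complement(fwd[i - pam_len : i])
                if not (pam[1:] == "GG" and pam[0] in "ACGT") or "N" in site:
                    continue
                mm = [p for p in range(1, 21) if site[p - 1] != spacer[p - 1]]
                core = sum(1 for p in mm if p > 20 - core_len)
                if len(mm) <= max_total and core <= max_core:
                    hits.add((chrom, i, strand))
    return hits


@pytest.fixture(scope="module")
def decoy_genome():
    """30-kb genome with decoys spanning the admissibility boundary."""
    planted = [
        (SPACER, mismatch_profile(t, c), s)
        for (t, c, s) in [
            (0, 0, "+"), (1, 0, "-"), (2, 1, "+"), (3, 2, "-"), (4, 2, "+"),
            (5, 2, "-"),  # over the total limit
            (3, 3, "+"),  # over the core limit
            (4, 4, "-"),  # over the core limit
        ]
    ]
    return make_fixture_genome(19, 30_000, planted)


class TestFind:
    def test_on_target_always_reported(self, decoy_genome):
        hits = find_offtargets(SPACER, decoy_genome.genome)
        assert any(h.n_mismatches == 0 for h in hits)

    def test_limits_respected(self, decoy_genome):
        hits = find_offtargets(SPACER, decoy_genome.genome)
        assert all(h.n_mismatches <= 4 and h.core_mismatches <= 2 for h in hits)

    def test_boundary_decoys(self, decoy_genome):
        hits = {(h.start, h.strand): h for h in find_offtargets(SPACER, decoy_genome.genome)}
        for p in decoy_genome.planted:
            key = (p.start, p.strand)
            core = sum(1 for q in p.mismatch_positions if q > 8)
            admissible = p.n_mismatches <= 4 and core <= 2
            assert (key in hits) == admissible, p
            if admissible:
                assert hits[key].mismatch_positions == p.mismatch_positions

    def test_counting_property(self, decoy_genome):
        # admissible planted decoys are recovered exactly, nothing else
        hits = find_offtargets(SPACER, decoy_genome.genome)
        admissible = [
            p
            for p in decoy_genome.planted
            if p.n_mismatches <= 4
            and sum(1 for q in p.mismatch_positions if q > 8) <= 2
        ]
        assert len(hits) == len(admissible)

    @pytest.mark.parametrize("max_total,max_core", [(4, 2), (2, 2), (6, 6)])
    def test_equals_oracle(self, decoy_genome, max_total, max_core):
        cfg = SearchConfig(
            max_total_mismatches=max_total, max_core_mismatches=max_core
        )
        got = {
            (h.chrom, h.start, h.strand)
            for h in find_offtargets(SPACER, decoy_genome.genome, cfg)
        }
        assert got == _oracle_scan(SPACER, decoy_genome.genome, max_total, max_core)

    def test_strand_symmetry(self):
        fx = make_fixture_genome(23, 8_000, [(SPACER, (1, 20), "+"), (SPACER, (5,), "-")])
        genome = fx.genome
        mirror = {c: reverse_complement(s) for c, s in genome.items()}
        fwd_hits = find_offtargets(SPACER, genome)
        rc_hits = find_offtargets(SPACER, mirror)
        L = len(genome["fchr1"])
        mirrored = {
            (L - h.end, {"+": "-", "-": "+"}[h.strand], h.site_sequence)
            for h in rc_hits
        }
        assert {(h.start, h.strand, h.site_sequence) for h in fwd_hits} == mirrored

    def test_n_windows_skipped(self):
        genome = {"c": "T" * 30 + SPACER[:10] + "N" + SPACER[11:] + "AGG" + "T" * 30}
        assert find_offtargets(SPACER, genome) == []

    def test_bad_spacer_length(self):
        with pytest.raises(ValueError, match="20 nt"):
            find_offtargets("ACGT", {"c": "A" * 100})

    def test_core_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            SearchConfig(max_total_mismatches=2, max_core_mismatches=3)


class TestFilterEditable:
    def _hit(self, site):
        return OffTargetHit(
            chrom="c", start=0, end=20, strand="+", site_sequence=site + "AGG",
            mismatch_positions=(), core_mismatches=0,
        )

    def test_no_substrate_in_window_removed(self, profiles):
        site = "TTTTTTTTTTTTTTTTTTTT"
        assert filter_editable([self._hit(site)], profiles["evoBE4max"], (4, 8)) == []

    def test_single_substrate_retained(self, profiles):
        site = "TTTCTTTTTTTTTTTTTTTT"  # C at position 4
        kept = filter_editable([self._hit(site)], profiles["evoBE4max"], (4, 8))
        assert len(kept) == 1 and kept[0].editable_in_window

    def test_idempotent(self, profiles):
        hits = [self._hit("TTTCTTTTTTTTTTTTTTTT"), self._hit("T" * 20)]
        once = filter_editable(hits, profiles["evoBE4max"], (4, 8))
        twice = filter_editable(once, profiles["evoBE4max"], (4, 8))
        assert once == twice


class TestRank:
    def _mm_hit(self, positions, start=0):
        return OffTargetHit(
            chrom="c", start=start, end=start + 20, strand="+",
            site_sequence="N" * 23, mismatch_positions=tuple(positions),
            core_mismatches=0, threat_score=threat_score(positions),
        )

    def test_pam_distal_mismatch_more_threatening(self):
        distal = self._mm_hit([1], start=100)
        proximal = self._mm_hit([19], start=0)
        ranked = rank_offtargets([proximal, distal])
        assert ranked[0].mismatch_positions == (1,)

    def test_on_target_listed_first(self):
        on = self._mm_hit([], start=500)
        off = self._mm_hit([1, 2], start=0)
        assert rank_offtargets([off, on])[0].n_mismatches == 0

    def test_tie_broken_by_coordinates(self):
        a = self._mm_hit([5], start=300)
        b = self._mm_hit([5], start=10)
        assert rank_offtargets([a, b])[0].start == 10

    def test_moving_mismatch_toward_pam_never_increases_threat(self):
        rng = np.random.default_rng(29)
        for _ in range(500):
            k = int(rng.integers(1, 5))
            pos = sorted(rng.choice(np.arange(1, 21), size=k, replace=False))
            base = threat_score(pos)
            movable = [i for i, p in enumerate(pos) if p + 1 <= 20 and p + 1 not in pos]
            for i in movable:
                moved = list(pos)
                moved[i] += 1
                assert threat_score(moved) < base


class TestContext:
    GENES = [
        GeneModel(name="g1", chrom="c", start=100, end=400, strand="+",
                  exons=[(100, 200), (300, 400)]),
    ]

    def _hit(self, start):
        return OffTargetHit(
            chrom="c", start=start, end=start + 20, strand="+",
            site_sequence="N" * 23, mismatch_positions=(), core_mismatches=0,
        )

    def test_exonic(self):
        assert annotate_context(self._hit(150), self.GENES) == "exonic"

    def test_intronic(self):
        assert annotate_context(self._hit(250), self.GENES) == "intronic"

    def test_intergenic(self):
        assert annotate_context(self._hit(600), self.GENES) == "intergenic"

    def test_boundary_overlap_is_exonic(self):
        # one base of exon overlap suffices
        assert annotate_context(self._hit(190), self.GENES) == "exonic"
        assert annotate_context(self._hit(199), self.GENES) == "exonic"

    def test_without_models_unknown(self):
        assert annotate_context(self._hit(150), None) == "unknown"
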