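"""Allen-style target scoring, cutoffs, and degradome validation."""

from __future__ import annotations

import numpy as np
import pytest

from mossrna.seq import random_dna, revcomp
from mossrna.targeting import (DegradomeProfile, best_alignment,
                               find_target_sites, score_alignment,
                               validate_with_degradome)
from oracles import WC, oracle_best_score


class TestScoreAlignment:
    def test_perfect_complement_scores_zero(self, rng):
        sr = random_dna(rng, 21)
        for mode in ("miRNA", "siRNA"):
            aln = score_alignment(sr, revcomp(sr), mode)
            assert aln.score == 0.0
            assert set(aln.per_position_state) == {"match"}
            assert aln.symbols == ":" * 21

    def test_single_wobble_at_position_5(self):
        # G:U wobble at small-RNA position 5: doubled in miRNA mode
        # (positions 2-13), undoubled in siRNA mode (exempt 2-7)
        sr = "A" * 21
        sr = sr[:4] + "G" + sr[5:]          # position 5 is G
        target = revcomp("A" * 21)          # all T -> G:T wobble at 5
        assert score_alignment(sr, target, "miRNA").score == 1.0
        assert score_alignment(sr, target, "siRNA").score == 0.5

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(120):
            sr = random_dna(rng, 21)
            window = random_dna(rng, 30)
            if rng.random() < 0.5:  # plant a degenerate site
                site = list(revcomp(sr))
                for _k in range(int(rng.integers(0, 4))):
                    p = int(rng.integers(0, len(site)))
                    site[p] = "ACGT"[int(rng.integers(0, 4))]
                window = ("".join(site) + random_dna(rng, 9))[:30]
            for mode in ("miRNA", "siRNA"):
                aln = best_alignment(sr, window, mode)
                assert aln.score == pytest.approx(
                    oracle_best_score(sr, window, mode))

    def test_sirna_score_never_exceeds_mirna_score(self, rng):
        for _ in range(50):
            sr, window = random_dna(rng, 21), random_dna(rng, 30)
            assert best_alignment(sr, window, "siRNA").score <= \
                best_alignment(sr, window, "miRNA").score

    def test_symmetry_under_joint_reverse_complement(self, rng):
        # reverse-complementing both strands swaps the roles of the two
        # sequences in the duplex; an ungapped perfect-length alignment
        # keeps its unweighted pair pattern (weights follow the new query)
        sr = random_dna(rng, 21)
        window = random_dna(rng, 21)
        fwd = score_alignment(sr, window, "miRNA")
        rev = score_alignment(revcomp(window), revcomp(sr), "miRNA")
        fwd_un = [s for s in fwd.per_position_state if s != "gap"]
        rev_un = [s for s in rev.per_position_state if s != "gap"]
        if fwd.gap_position is None and rev.gap_position is None:
            assert fwd_un == rev_un


class TestFindTargetSites:
    def test_exact_complement_found_at_any_cutoff(self, rng):
        sr = random_dna(rng, 21)
        tx = {"t1": random_dna(rng, 200) + revcomp(sr) + random_dna(rng, 200)}
        for cutoff in (0.0, 4.0, 8.0):
            sites = find_target_sites(sr, tx, "miRNA", cutoff=cutoff)
            assert sites and sites[0].score == 0.0
            assert sites[0].target_interval == (201, 221)

    def test_cutoff_8_admits_sites_cutoff_4_rejects(self, rng):
        sr = random_dna(rng, 21)
        site = list(revcomp(sr))
        # three mismatches inside the doubled region -> score > 4
        for srna_pos in (3, 5, 7):
            t_idx = 21 - srna_pos
            bad = {WC[sr[srna_pos - 1]], sr[srna_pos - 1]}
            site[t_idx] = next(b for b in "ACGT" if b not in bad
                               and (sr[srna_pos - 1], b) not in
                               (("G", "T"), ("T", "G")))
        tx = {"t1": random_dna(rng, 50) + "".join(site) + random_dna(rng, 50)}
        s4 = find_target_sites(sr, tx, "miRNA", cutoff=4.0)
        s8 = find_target_sites(sr, tx, "miRNA", cutoff=8.0)
        assert not [a for a in s4 if a.score == 6.0]
        assert [a for a in s8 if a.score == 6.0]

    def test_cutoff_monotonicity(self, rng):
        sr = random_dna(rng, 21)
        tx = {f"t{i}": random_dna(rng, 300) for i in range(10)}
        keys4 = {(a.transcript_id, a.target_interval, a.gap_position)
                 for a in find_target_sites(sr, tx, "miRNA", cutoff=4.0)}
        keys8 = {(a.transcript_id, a.target_interval, a.gap_position)
                 for a in find_target_sites(sr, tx, "miRNA", cutoff=8.0)}
        assert keys4 <= keys8

    def test_scrambled_transcripts_yield_no_strong_sites(self, rng):
        sr = random_dna(rng, 21)
        tx = {f"t{i}": random_dna(rng, 500) for i in range(20)}
        sites = find_target_sites(sr, tx, "miRNA", cutoff=4.0)
        for a in sites:  # every reported site re-verified by the oracle
            window = tx[a.transcript_id][
                a.target_interval[0] - 1:a.target_interval[1]]
            assert oracle_best_score(sr, window, "miRNA") <= a.score


class TestDegradomeValidation:
    def _alignment(self, rng, tx_len=200, site_start=100):
        sr = random_dna(rng, 21)
        tx = random_dna(rng, site_start) + revcomp(sr) \
            + random_dna(rng, tx_len - site_start - 21)
        aln = find_target_sites(sr, {"t1": tx}, "miRNA", cutoff=0.0)[0]
        return aln

    def test_cleavage_position_is_opposite_position_10(self, rng):
        aln = self._alignment(rng)
        # site ends at 121; position 10 from the small-RNA 5' end pairs
        # the target base at end - 9
        assert aln.target_interval == (101, 121)
        assert aln.cleavage_position() == 112

    def test_planted_peak_validates(self, rng):
        aln = self._alignment(rng)
        profile = DegradomeProfile("t1", {aln.cleavage_position(): 20})
        call, = validate_with_degradome([aln], {"t1": profile})
        assert call.validated and call.peak_category == "dominant-on-transcript"
        assert call.site_count == 20

    def test_no_reads_anywhere_not_validated(self, rng):
        aln = self._alignment(rng)
        call, = validate_with_degradome([aln], {"t1": DegradomeProfile("t1", {})})
        assert not call.validated and call.site_count == 0

    def test_uniform_background_not_validated(self, rng):
        aln = self._alignment(rng)
        profile = DegradomeProfile("t1", {p: 1 for p in range(1, 201)})
        call, = validate_with_degradome([aln], {"t1": profile})
        assert not call.validated  # 1 read < the 5-read minimum

    def test_subpeak_not_validated(self, rng):
        aln = self._alignment(rng)
        counts = {aln.cleavage_position(): 6, aln.target_interval[0] + 2: 40}
        call, = validate_with_degradome(
            [aln], {"t1": DegradomeProfile("t1", counts)})
        assert call.peak_category == "sub-peak" and not call.validated

    def test_missing_profile_flagged(self, rng):
        aln = self._alignment(rng)
        call, = validate_with_degradome([aln], {})
        assert call.peak_category == "no-profile" and not call.validated
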