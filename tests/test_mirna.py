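"""miRNA discovery: duplex geometry, the four criteria, and recovery."""

from __future__ import annotations

import pytest

from mossrna.alignment import GenomicLocus, place_reads
from mossrna.mirna import (anneal_duplex, candidate_windows, discover_mirnas,
                           match_known)
from mossrna.preprocess import CleanRead
from mossrna.seq import random_dna, revcomp


def make_precursor(rng, mature_len=21, loop=15):
    """Mature + loop + star hairpin with exact 2-nt 3' overhangs."""
    mature = random_dna(rng, mature_len)
    star = revcomp(mature[:-2]) + random_dna(rng, 2)
    return mature, star, mature + random_dna(rng, loop) + star


class TestAnnealDuplex:
    def test_constructed_duplex_has_two_nt_overhangs(self, rng):
        for _ in range(20):
            mature, star, _ = make_precursor(rng)
            d = anneal_duplex(mature, star)
            assert (d.overhang_3p_mature, d.overhang_3p_star) == (2, 2)
            assert d.n_pairs == 19

    def test_blunt_duplex_has_zero_overhangs(self, rng):
        mature = random_dna(rng, 21)
        d = anneal_duplex(mature, revcomp(mature))
        assert (d.overhang_3p_mature, d.overhang_3p_star) == (0, 0)
        assert d.paired_fraction == 1.0

    def test_unrelated_sequences_pair_poorly(self, rng):
        # random 21-mers rarely anneal with >60% pairing in any register
        weak = sum(anneal_duplex(random_dna(rng, 21), random_dna(rng, 21))
                   .paired_fraction < 0.8 for _ in range(30))
        assert weak >= 25


class TestMatchKnown:
    def test_exact_and_terminal_slop_matches(self, rng):
        known = {"miR-a": random_dna(rng, 21)}
        exact = CleanRead(known["miR-a"], {"L1": 5})
        trimmed = CleanRead(known["miR-a"][2:], {"L1": 1})
        matched, pool = match_known([exact, trimmed], known)
        assert len(matched["miR-a"]) == 2 and not pool

    def test_internal_mismatch_stays_in_pool(self, rng):
        seq = random_dna(rng, 21)
        mutated = seq[:10] + ("A" if seq[10] != "A" else "C") + seq[11:]
        matched, pool = match_known([CleanRead(mutated, {"L1": 1})],
                                    {"miR-a": seq})
        assert not matched["miR-a"] and len(pool) == 1

    def test_conservation(self, rng):
        known = {"miR-a": random_dna(rng, 21)}
        reads = [CleanRead(random_dna(rng, 21), {"L1": 1}) for _ in range(20)]
        reads.append(CleanRead(known["miR-a"], {"L1": 1}))
        matched, pool = match_known(reads, known)
        assert sum(len(v) for v in matched.values()) + len(pool) == len(reads)


class TestCandidateWindows:
    def test_extension_and_step_arithmetic(self):
        locus = GenomicLocus("chr1", 1000, 1021)
        wins = list(candidate_windows([locus], {"chr1": "A" * 2000}))
        assert wins[0] == ("chr1", 700, 950)
        assert all(e - s == 250 for _, s, e in wins)
        assert wins[-1] == ("chr1", 1050, 1300)
        assert len(wins) == 15
        assert all(e <= 1321 for _, s, e in wins)

    def test_clamped_at_chromosome_start(self):
        locus = GenomicLocus("chr1", 10, 31)
        wins = list(candidate_windows([locus], {"chr1": "A" * 2000}))
        assert wins[0][1] == 0

    def test_short_chromosome_single_window(self):
        locus = GenomicLocus("chr1", 50, 71)
        wins = list(candidate_windows([locus], {"chr1": "A" * 120}))
        assert wins == [("chr1", 0, 120)]


def build_locus(rng, mature_depth=15, star_depth=2, genome_len=3000,
                star_shift=0, strand="+"):
    mature, star, pre = make_precursor(rng)
    pos = 1400
    genome = random_dna(rng, genome_len)
    planted = pre if strand == "+" else revcomp(pre)
    genome = genome[:pos] + planted + genome[pos + len(pre):]
    reads = []
    if mature_depth:
        reads.append(CleanRead(mature, {"L1": mature_depth}))
    if star_depth:
        if star_shift:
            if strand == "+":
                s0 = pos + 21 + 15 + star_shift
                star_read = genome[s0:s0 + 21]
            else:
                s0 = pos + len(pre) - 21 - 15 - 21 - star_shift
                star_read = revcomp(genome[s0:s0 + 21])
        else:
            star_read = star
        reads.append(CleanRead(star_read, {"L1": star_depth}))
    return {"chr1": genome}, reads, (mature, star)


class TestDiscovery:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_planted_precursor_recovered(self, rng, strand):
        genome, reads, (mature, star) = build_locus(rng, strand=strand)
        anns, _ = discover_mirnas(place_reads(reads, genome), genome)
        assert len(anns) == 1
        ann = anns[0]
        assert ann.mature_sequence == mature and ann.star_sequence == star
        assert (ann.mature_count, ann.star_count) == (15, 2)
        assert ann.strand == strand
        # geometry re-check, independent of the fold
        d = anneal_duplex(ann.mature_sequence, ann.star_sequence)
        assert abs(d.overhang_3p_mature - 2) <= 1
        assert abs(d.overhang_3p_star - 2) <= 1

    def test_exactly_ten_mature_reads_rejected(self, rng):
        # "more than 10 reads" is strict
        genome, reads, _ = build_locus(rng, mature_depth=10)
        anns, _ = discover_mirnas(place_reads(reads, genome), genome)
        assert not anns
        genome, reads, _ = build_locus(rng, mature_depth=11)
        anns, _ = discover_mirnas(place_reads(reads, genome), genome)
        assert len(anns) == 1

    def test_no_star_read_rejected(self, rng):
        genome, reads, _ = build_locus(rng, star_depth=0)
        anns, rej = discover_mirnas(place_reads(reads, genome), genome)
        assert not anns
        assert any(r.reason == "no_star_read" for r in rej)

    def test_broken_overhang_rejected(self, rng):
        genome, reads, _ = build_locus(rng, star_shift=4)
        anns, _ = discover_mirnas(place_reads(reads, genome), genome)
        assert not anns

    def test_monotone_in_mature_depth(self, rng):
        for depth in (11, 20, 200, 2000):
            genome, reads, _ = build_locus(rng, mature_depth=depth)
            anns, _ = discover_mirnas(place_reads(reads, genome), genome)
            assert len(anns) == 1 and anns[0].mature_count == depth

    def test_background_singletons_never_called(self, rng):
        genome = {"chr1": random_dna(rng, 50_000)}
        reads = []
        for _ in range(300):
            ln = int(rng.integers(17, 31))
            s = int(rng.integers(0, 50_000 - ln))
            seq = genome["chr1"][s:s + ln]
            reads.append(CleanRead(seq, {"L1": 1}))
        merged: dict[str, CleanRead] = {}
        for r in reads:
            if r.sequence in merged:
                merged[r.sequence].counts["L1"] += 1
            else:
                merged[r.sequence] = r
        anns, _ = discover_mirnas(place_reads(list(merged.values()), genome),
                                  genome)
        assert not anns
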