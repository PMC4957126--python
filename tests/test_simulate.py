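"""Synthetic-data generator contracts: determinism, geometry, conservation."""

from __future__ import annotations

import pytest

from mossrna.mirna import anneal_duplex
from mossrna.simulate import (LocusOverride, SimulationConfig, locus_depth,
                              simulate_degradome, simulate_genome,
                              simulate_reads)


class TestSimulateGenome:
    def test_empty_plant_case(self):
        cfg = SimulationConfig(genome_length=20_000, n_mirna_loci=0,
                               n_known_mirna=0, n_tas_loci=0, n_hpRNA_loci=0,
                               n_target_events=0, seed=3)
        genome, truth = simulate_genome(cfg)
        assert len(genome["chr1"]) == 20_000
        assert not truth.mirna_loci and not truth.tas_loci
        assert not truth.hpRNA_loci and not truth.target_events

    def test_planted_duplex_geometry(self, small_dataset):
        config, genome, truth, _ = small_dataset
        for mt in truth.mirna_loci:
            d = anneal_duplex(mt.mature_seq, mt.star_seq)
            assert (d.overhang_3p_mature, d.overhang_3p_star) == (2, 2)

    def test_same_seed_identical_output(self, small_config):
        g1, _ = simulate_genome(small_config)
        g2, _ = simulate_genome(small_config)
        assert g1 == g2
        r1 = simulate_reads(g1, simulate_genome(small_config)[1], small_config)
        r2 = simulate_reads(g2, simulate_genome(small_config)[1], small_config)
        assert r1 == r2

    def test_loci_do_not_overlap(self, small_dataset):
        _, _, truth, _ = small_dataset
        ivs = sorted([m.precursor for m in truth.mirna_loci]
                     + [t.interval for t in truth.tas_loci]
                     + [h.interval for h in truth.hpRNA_loci])
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2

    def test_infeasible_packing_fails(self):
        cfg = SimulationConfig(genome_length=3_000, n_mirna_loci=10, seed=1)
        with pytest.raises(ValueError):
            simulate_genome(cfg)

    def test_tas_phase_geometry(self, small_dataset):
        # cleavage opposite trigger position 10: 9 nt upstream of the
        # site's last base; phased read starts sit on that register
        _, genome, truth, _ = small_dataset
        for tt in truth.tas_loci:
            assert tt.cleavage_genomic == tt.trigger_site[1] - 1 - 9
            assert tt.cleavage_genomic % 21 == tt.phase_offset


class TestSimulateReads:
    def test_read_conservation(self, small_dataset):
        config, genome, truth, reads = small_dataset
        for cond in config.conditions:
            expected = config.background_read_count
            for mt in truth.mirna_loci:
                d = round(locus_depth(config, mt.locus_id)
                          * config.fold_changes.get(mt.locus_id, {})
                          .get(cond, 1.0))
                expected += d + max(2, d // config.star_depth_divisor)
            for tt in truth.tas_loci:
                expected += round(locus_depth(config, tt.locus_id)
                                  * config.fold_changes.get(tt.locus_id, {})
                                  .get(cond, 1.0))
            for ht in truth.hpRNA_loci:
                expected += locus_depth(config, ht.locus_id)
            assert len(reads[cond]) == expected

    def test_zero_depth_zero_background_empty(self):
        cfg = SimulationConfig(genome_length=20_000, n_mirna_loci=0,
                               n_known_mirna=0, n_tas_loci=0, n_hpRNA_loci=0,
                               n_target_events=0, background_read_count=0,
                               seed=3)
        genome, truth = simulate_genome(cfg)
        reads = simulate_reads(genome, truth, cfg)
        assert all(not v for v in reads.values())

    def test_fold_change_scales_counts(self):
        cfg = SimulationConfig(
            genome_length=40_000, n_mirna_loci=2, n_known_mirna=0,
            n_tas_loci=0, n_hpRNA_loci=0, n_target_events=0,
            background_read_count=0,
            fold_changes={"mir_1": {"B": 2.0}}, conditions=("A", "B"), seed=5)
        genome, truth = simulate_genome(cfg)
        reads = simulate_reads(genome, truth, cfg)

        def mature_count(cond, locus):
            return sum(1 for rid, _, _ in reads[cond]
                       if rid.split(":")[1] == locus)

        assert mature_count("B", "mir_1") == 2 * mature_count("A", "mir_1")
        assert mature_count("B", "mir_0") == mature_count("A", "mir_0")

    def test_star_override_changes_emitted_star(self, small_dataset):
        config, genome, truth, _ = small_dataset
        mt = truth.mirna_loci[-1]
        reads = simulate_reads(genome, truth, config,
                               overrides={mt.locus_id:
                                          LocusOverride(star_depth=0)})
        star_ids = [rid for cond in config.conditions
                    for rid, _, _ in reads[cond]
                    if rid.split(":")[1] == mt.locus_id + "*"]
        assert not star_ids


class TestSimulateDegradome:
    def test_single_event_single_peak(self, small_dataset):
        config, genome, truth, _ = small_dataset
        quiet = SimulationConfig(**{**config.__dict__,
                                    "degradome_background_per_nt": 0.0})
        tx = truth.transcript_sequences(genome)
        profiles = simulate_degradome(truth, tx, quiet)
        for ev in truth.target_events:
            counts = profiles[ev.transcript_id].counts
            assert counts[ev.cleavage_position] == quiet.degradome_event_depth
        for tid, prof in profiles.items():
            if not any(ev.transcript_id == tid for ev in truth.target_events):
                assert not prof.counts

    def test_cleavage_outside_transcript_fails(self, small_dataset):
        config, genome, truth, _ = small_dataset
        tx = truth.transcript_sequences(genome)
        ev = truth.target_events[0]
        short = dict(tx)
        short[ev.transcript_id] = short[ev.transcript_id][:5]
        with pytest.raises(ValueError):
            simulate_degradome(truth, short, config)

    def test_background_below_peak_rule(self, small_dataset):
        # uniform background alone never reaches the 5-read peak criterion
        config, genome, truth, _ = small_dataset
        bg_only = SimulationConfig(**{**config.__dict__,
                                      "degradome_event_depth": 0})
        tx = truth.transcript_sequences(genome)
        profiles = simulate_degradome(truth, tx, bg_only)
        assert max((p.max_count() for p in profiles.values()), default=0) < 5
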