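"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from mossrna.preprocess import CleanRead, RawRead, filter_qualified
from mossrna.simulate import SimulationConfig, simulate_genome, simulate_reads

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact dataset: 4 miRNA precursors, 2 TAS loci, 1 hpRNA."""
    return SimulationConfig(
        genome_length=80_000, n_mirna_loci=4, n_known_mirna=1,
        n_tas_loci=2, n_hpRNA_loci=1, hpRNA_stem_lengths=(180,),
        hpRNA_depth=600, background_read_count=300,
        n_target_events=2, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    genome, truth = simulate_genome(small_config)
    reads = simulate_reads(genome, truth, small_config)
    return small_config, genome, truth, reads


def fastq_records_to_raw(records, library: str):
    """Convert simulate_reads tuples into RawRead objects."""
    return [RawRead(rid, seq, [40] * len(seq), library)
            for rid, seq, qual in records]


def qualified_reads(config, reads) -> list[CleanRead]:
    """Preprocess simulated per-condition records into collapsed reads."""
    stream = (r for cond in config.conditions
              for r in fastq_records_to_raw(reads[cond], cond))
    clean, _ = filter_qualified(stream, config.adapter_sequence)
    return clean


@pytest.fixture(scope="session")
def small_clean(small_dataset):
    config, genome, truth, reads = small_dataset
    return qualified_reads(config, reads)
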