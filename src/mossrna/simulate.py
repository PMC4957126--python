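"""Synthetic genomes, small-RNA libraries and degradome profiles with
planted, fully known ground truth.

The generator emulates the structures the discovery modules look for:

* miRNA precursors — a mature/star duplex embedded in a hairpin so that the
  two strands anneal with exactly 2-nt 3' overhangs on both ends, with the
  mature on the 5p or 3p arm;
* TAS-like loci — a trigger small-RNA binding site followed by 21-nt reads
  on the phase register set by the trigger's canonical cleavage position;
* long hpRNA loci — extensively annealed foldback stems (default 180 and
  370 bp) sampled with a configurable 3':5' arm bias and a 20-22-nt-heavy
  read-size distribution;
* degradome 5'-end pileups at canonical cleavage sites of planted target
  events, over a uniform low background;
* per-condition abundance shifts of chosen magnitude for differential
  expression, plus genome-wide singleton background reads that exercise the
  read-support filters as true negatives.

Read depths across miRNA loci decay geometrically, a stand-in for the
heavy-tailed abundance of real libraries.  Everything is driven by a single
seed; a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seq import random_dna, revcomp

CHROM = "chr1"


@dataclass
class SimulationConfig:
    genome_length: int = 200_000
    n_mirna_loci: int = 8
    n_known_mirna: int = 2          # planted matures also listed as "known"
    n_tas_loci: int = 3
    n_hpRNA_loci: int = 2
    hpRNA_stem_lengths: tuple[int, ...] = (180, 370)
    mature_length: int = 21
    loop_length: int = 15
    hpRNA_loop_length: int = 40
    # read depths (per locus, first condition)
    mirna_base_depth: int = 150
    mirna_depth_decay: float = 0.8
    mirna_min_depth: int = 15
    star_depth_divisor: int = 8     # star depth = max(2, mature // divisor)
    tas_depth: int = 60
    tas_n_phases: int = 8
    hpRNA_depth: int = 1000
    hpRNA_arm_ratio: float = 5.0    # 3'-arm : 5'-arm sampling odds
    hpRNA_length_probs: dict[int, float] = field(
        default_factory=lambda: {20: 0.075, 21: 0.78, 22: 0.075, 24: 0.07})
    background_read_count: int = 1000
    # targets / degradome
    n_target_events: int = 4
    target_gene_length: int = 500
    degradome_event_depth: int = 20
    degradome_background_per_nt: float = 0.2
    # sequencing
    adapter_sequence: str = "TGGAATTCTCGGGTGCCAAGG"
    read_length: int = 40
    error_rate: float = 0.0
    count_noise: str = "none"       # {"none", "poisson"}
    # conditions
    conditions: tuple[str, ...] = ("WT_ABA", "WT_rehydration")
    fold_changes: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "mir_1": {"WT_rehydration": 2.0},
        "mir_2": {"WT_rehydration": 3.2},
        "mir_3": {"WT_rehydration": 0.125},
    })
    seed: int = 0

    def validate(self) -> None:
        if self.count_noise not in ("none", "poisson"):
            raise ValueError("count_noise must be 'none' or 'poisson'")
        if abs(sum(self.hpRNA_length_probs.values()) - 1.0) > 1e-9:
            raise ValueError("hpRNA_length_probs must sum to 1")
        if len(self.adapter_sequence) < 7:
            raise ValueError("adapter must be at least 7 nt")


@dataclass
class MirnaTruth:
    locus_id: str
    chrom: str
    strand: str
    precursor: tuple[int, int]
    mature: tuple[int, int]
    star: tuple[int, int]
    mature_seq: str
    star_seq: str
    arm: str                 # {5p, 3p}
    known: bool


@dataclass
class TasTruth:
    locus_id: str
    chrom: str
    interval: tuple[int, int]
    trigger_id: str
    trigger_site: tuple[int, int]        # genomic, 0-based half-open
    phase_offset: int                    # genomic cleavage position mod 21
    cleavage_genomic: int
    transcript_id: str
    transcript_interval: tuple[int, int]


@dataclass
class HpRnaTruth:
    locus_id: str
    chrom: str
    interval: tuple[int, int]
    arm5: tuple[int, int]
    arm3: tuple[int, int]


@dataclass
class TargetEventTruth:
    small_rna_id: str
    small_rna_seq: str
    transcript_id: str
    binding_interval: tuple[int, int]    # 1-based inclusive on transcript
    cleavage_position: int               # 1-based on transcript


@dataclass
class GroundTruth:
    mirna_loci: list[MirnaTruth] = field(default_factory=list)
    tas_loci: list[TasTruth] = field(default_factory=list)
    hpRNA_loci: list[HpRnaTruth] = field(default_factory=list)
    target_events: list[TargetEventTruth] = field(default_factory=list)
    transcripts: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    known_matures: dict[str, str] = field(default_factory=dict)
    expression_truth: dict[str, dict[str, float]] = field(default_factory=dict)

    def transcript_sequences(self, genome: dict[str, str]) -> dict[str, str]:
        return {tid: genome[c][s:e]
                for tid, (c, s, e) in sorted(self.transcripts.items())}


def _make_star(mature: str, rng: np.random.Generator) -> str:
    """Star strand annealing to the mature with 2-nt 3' overhangs on both
    ends: star = revcomp(mature[:-2]) + 2 free tail bases."""
    tail = random_dna(rng, 2)
    return revcomp(mature[:-2]) + tail


def _place_intervals(rng: np.random.Generator, genome_length: int,
                     footprints: list[int], margin: int = 800) -> list[int]:
    """Non-overlapping start offsets with at least ``margin`` nt separation.

    Deterministically feasible: the loci are laid out in order with the
    mandatory margins, and the remaining slack is split at random between
    the gaps.
    """
    n = len(footprints)
    if n == 0:
        return []
    need = sum(footprints) + margin * (n + 1)
    slack = genome_length - need
    if slack < 0:
        raise ValueError(
            f"cannot pack {n} loci ({need} nt with margins) "
            f"into a {genome_length}-nt genome")
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    starts = []
    pos = margin
    for i, fp in enumerate(footprints):
        extra = int(cuts[i]) - (int(cuts[i - 1]) if i else 0)
        pos += max(0, extra)
        starts.append(pos)
        pos += fp + margin
    return starts


def simulate_genome(config: SimulationConfig) -> tuple[dict[str, str], GroundTruth]:
    """Build a random genome with planted loci and the matching truth."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    truth = GroundTruth()
    L = config.mature_length
    loop = config.loop_length
    pre_len = 2 * L + loop

    # design sequences first, then paint them onto the random genome
    mirnas = []
    for i in range(config.n_mirna_loci):
        mature = random_dna(rng, L)
        star = _make_star(mature, rng)
        arm = "5p" if i % 2 == 0 else "3p"
        strand = "+" if i % 4 < 2 else "-"
        if arm == "5p":
            pre = mature + random_dna(rng, loop) + star
        else:
            pre = star + random_dna(rng, loop) + mature
        mirnas.append((f"mir_{i}", mature, star, arm, strand, pre))

    triggers = {f"trigger_{i}": random_dna(rng, L)
                for i in range(config.n_tas_loci)}
    tas_designs = []
    for i in range(config.n_tas_loci):
        tid = f"trigger_{i}"
        site = revcomp(triggers[tid])  # perfect binding site on the + strand
        tas_len = len(site) + 21 * config.tas_n_phases + 100
        tas_designs.append((f"tas_{i}", tid, site, tas_len))

    hp_designs = []
    for i in range(config.n_hpRNA_loci):
        stem = config.hpRNA_stem_lengths[i % len(config.hpRNA_stem_lengths)]
        arm5 = random_dna(rng, stem)
        # a highly annealed but imperfect stem: one substitution every
        # ~10 nt keeps >=90% pairing yet makes every >=20-nt read map to
        # a single arm (a perfect inverted repeat would double-map them)
        arm3 = list(revcomp(arm5))
        for pos in range(5, stem, 10):
            arm3[pos] = "ACGT"[(("ACGT".index(arm3[pos])) +
                                int(rng.integers(1, 4))) % 4]
        hp_seq = (arm5 + random_dna(rng, config.hpRNA_loop_length)
                  + "".join(arm3))
        hp_designs.append((f"hp_{i}", stem, hp_seq))

    gene_designs = []
    n_events = min(config.n_target_events, config.n_mirna_loci)
    for i in range(n_events):
        name, mature, *_ = mirnas[i]
        gene = random_dna(rng, config.target_gene_length)
        offset = int(rng.integers(100, config.target_gene_length - 100 - L))
        gene = gene[:offset] + revcomp(mature) + gene[offset + L:]
        gene_designs.append((f"gene_{i}", name, mature, offset, gene))

    footprints = ([pre_len] * len(mirnas)
                  + [d[3] for d in tas_designs]
                  + [len(d[2]) for d in hp_designs]
                  + [len(d[4]) for d in gene_designs])
    starts = _place_intervals(rng, config.genome_length, footprints)
    genome = list(random_dna(rng, config.genome_length))

    def paint(pos: int, seq: str) -> None:
        genome[pos:pos + len(seq)] = list(seq)

    cursor = 0
    for (name, mature, star, arm, strand, pre) in mirnas:
        s = starts[cursor]; cursor += 1
        planted = pre if strand == "+" else revcomp(pre)
        paint(s, planted)
        if arm == "5p":
            m_rel, s_rel = (0, L), (L + loop, 2 * L + loop)
        else:
            s_rel, m_rel = (0, L), (L + loop, 2 * L + loop)
        if strand == "+":
            g = lambda iv: (s + iv[0], s + iv[1])
        else:
            g = lambda iv: (s + pre_len - iv[1], s + pre_len - iv[0])
        truth.mirna_loci.append(MirnaTruth(
            name, CHROM, strand, (s, s + pre_len), g(m_rel), g(s_rel),
            mature, star, arm, known=cursor <= config.n_known_mirna))
        if cursor <= config.n_known_mirna:
            truth.known_matures[name] = mature

    for (name, trig_id, site, tas_len) in tas_designs:
        s = starts[cursor]; cursor += 1
        site_start = s + 40
        paint(site_start, site)
        # canonical cleavage opposite trigger positions 10/11: the 5' end of
        # the 3' fragment sits 9 nt upstream of the site's last base
        cleave = site_start + len(site) - 1 - 9
        truth.known_matures[trig_id] = triggers[trig_id]
        tx_id = f"TAS_{name}"
        tx_iv = (s, s + tas_len)
        truth.transcripts[tx_id] = (CHROM, *tx_iv)
        truth.tas_loci.append(TasTruth(
            name, CHROM, (s, s + tas_len), trig_id,
            (site_start, site_start + len(site)), cleave % 21, cleave,
            tx_id, tx_iv))

    for (name, stem, hp_seq) in hp_designs:
        s = starts[cursor]; cursor += 1
        paint(s, hp_seq)
        truth.hpRNA_loci.append(HpRnaTruth(
            name, CHROM, (s, s + len(hp_seq)),
            (s, s + stem),
            (s + stem + config.hpRNA_loop_length, s + len(hp_seq))))

    for (gid, srna_id, mature, offset, gene) in gene_designs:
        s = starts[cursor]; cursor += 1
        paint(s, gene)
        truth.transcripts[gid] = (CHROM, s, s + len(gene))
        binding = (offset + 1, offset + L)          # 1-based inclusive
        cleavage = binding[1] - 9
        truth.target_events.append(TargetEventTruth(
            srna_id, mature, gid, binding, cleavage))

    genome_str = "".join(genome)
    # painting must not have been clobbered by later loci
    for mt in truth.mirna_loci:
        m0, m1 = mt.mature
        observed = genome_str[m0:m1]
        expected = mt.mature_seq if mt.strand == "+" else revcomp(mt.mature_seq)
        assert observed == expected, "planted locus was overwritten"
    _fill_expression_truth(truth, config)
    return {CHROM: genome_str}, truth


def locus_depth(config: SimulationConfig, locus_id: str) -> int:
    """Base (first-condition) expected read depth for a planted locus."""
    kind, idx = locus_id.split("_")
    i = int(idx)
    if kind == "mir":
        return max(config.mirna_min_depth,
                   round(config.mirna_base_depth * config.mirna_depth_decay ** i))
    if kind == "tas":
        return config.tas_depth
    if kind == "hp":
        return config.hpRNA_depth
    raise KeyError(locus_id)


def _condition_depth(config: SimulationConfig, locus_id: str, cond: str) -> float:
    mult = config.fold_changes.get(locus_id, {}).get(cond, 1.0)
    return locus_depth(config, locus_id) * mult


def _fill_expression_truth(truth: GroundTruth, config: SimulationConfig) -> None:
    ids = ([m.locus_id for m in truth.mirna_loci]
           + [t.locus_id for t in truth.tas_loci]
           + [h.locus_id for h in truth.hpRNA_loci])
    totals = {}
    for cond in config.conditions:
        star = sum(max(2, round(_condition_depth(config, m.locus_id, cond))
                       // config.star_depth_divisor)
                   for m in truth.mirna_loci)
        totals[cond] = (sum(_condition_depth(config, lid, cond) for lid in ids)
                        + star + config.background_read_count)
    for lid in ids:
        truth.expression_truth[lid] = {
            cond: _condition_depth(config, lid, cond) * 1e6 / totals[cond]
            for cond in config.conditions}


@dataclass
class LocusOverride:
    """Per-locus read-emission tweaks used by ablation experiments."""

    mature_depth: int | None = None
    star_depth: int | None = None
    star_shift: int = 0      # shift the emitted star read along the genome


def _emit(rng: np.random.Generator, n: int, config: SimulationConfig) -> int:
    if config.count_noise == "poisson":
        return int(rng.poisson(n))
    return int(round(n))


def simulate_reads(genome: dict[str, str], truth: GroundTruth,
                   config: SimulationConfig,
                   overrides: dict[str, LocusOverride] | None = None,
                   ) -> dict[str, list[tuple[str, str, str]]]:
    """Per-condition FASTQ records (id, sequence, quality string).

    Each read is the locus-derived insert plus the 3' adapter, truncated to
    the machine read length; background reads are uniform genomic 17-30-mers
    emitted once each.  Per-condition locus depths are the configured base
    depths scaled by the locus's fold change for that condition.
    """
    config.validate()
    overrides = overrides or {}
    rng = np.random.default_rng([config.seed, 1])
    seq = genome[CHROM]
    out: dict[str, list[tuple[str, str, str]]] = {c: [] for c in config.conditions}

    def add(cond: str, name: str, insert: str) -> None:
        if config.error_rate > 0:
            bases = list(insert)
            for i in range(len(bases)):
                if rng.random() < config.error_rate:
                    bases[i] = "ACGT"[int(rng.integers(0, 4))]
            insert = "".join(bases)
        read = (insert + config.adapter_sequence)[:config.read_length]
        qual = "I" * len(read)
        out[cond].append((f"{cond}:{name}:{len(out[cond])}", read, qual))

    for cond in config.conditions:
        for mt in truth.mirna_loci:
            ov = overrides.get(mt.locus_id, LocusOverride())
            depth = _emit(rng, round(_condition_depth(config, mt.locus_id, cond)), config)
            if ov.mature_depth is not None:
                depth = ov.mature_depth
            star_depth = max(2, depth // config.star_depth_divisor)
            if ov.star_depth is not None:
                star_depth = ov.star_depth
            for k in range(depth):
                add(cond, mt.locus_id, mt.mature_seq)
            star_insert = mt.star_seq
            if ov.star_shift:
                s0, s1 = mt.star
                if mt.strand == "+":
                    star_insert = seq[s0 + ov.star_shift:s1 + ov.star_shift]
                else:
                    star_insert = revcomp(seq[s0 - ov.star_shift:s1 - ov.star_shift])
            for k in range(star_depth):
                add(cond, mt.locus_id + "*", star_insert)
        for tt in truth.tas_loci:
            depth = _emit(rng, round(_condition_depth(config, tt.locus_id, cond)), config)
            for k in range(depth):
                phase = k % config.tas_n_phases
                start = tt.cleavage_genomic + 21 * phase
                add(cond, tt.locus_id, seq[start:start + 21])
        for ht in truth.hpRNA_loci:
            depth = _emit(rng, round(_condition_depth(config, ht.locus_id, cond)), config)
            lengths = sorted(config.hpRNA_length_probs)
            probs = [config.hpRNA_length_probs[l] for l in lengths]
            p3 = config.hpRNA_arm_ratio / (config.hpRNA_arm_ratio + 1.0)
            for k in range(depth):
                arm = ht.arm3 if rng.random() < p3 else ht.arm5
                ln = int(rng.choice(lengths, p=probs))
                start = int(rng.integers(arm[0], arm[1] - ln))
                add(cond, ht.locus_id, seq[start:start + ln])
        for k in range(config.background_read_count):
            ln = int(rng.integers(17, 31))
            start = int(rng.integers(0, len(seq) - ln))
            insert = seq[start:start + ln]
            if rng.random() < 0.5:
                insert = revcomp(insert)
            add(cond, "bg", insert)
    return out


def simulate_degradome(truth: GroundTruth, transcripts: dict[str, str],
                       config: SimulationConfig) -> dict[str, "object"]:
    """Per-transcript 5'-end count profiles: a pileup of configurable depth
    at each planted cleavage position over a uniform background."""
    from .targeting import DegradomeProfile
    rng = np.random.default_rng([config.seed, 2])
    profiles = {tid: DegradomeProfile(tid, {}) for tid in sorted(transcripts)}
    for ev in truth.target_events:
        tx = transcripts[ev.transcript_id]
        if not 1 <= ev.cleavage_position <= len(tx):
            raise ValueError(
                f"cleavage position {ev.cleavage_position} outside "
                f"transcript {ev.transcript_id}")
        counts = profiles[ev.transcript_id].counts
        counts[ev.cleavage_position] = (counts.get(ev.cleavage_position, 0)
                                        + config.degradome_event_depth)
    for tid in sorted(transcripts):
        n_bg = int(round(config.degradome_background_per_nt * len(transcripts[tid])))
        if n_bg:
            positions = rng.integers(1, len(transcripts[tid]) + 1, size=n_bg)
            counts = profiles[tid].counts
            for pos in positions:
                counts[int(pos)] = counts.get(int(pos), 0) + 1
    return profiles


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_dataset(outdir, config: SimulationConfig) -> dict[str, str]:
    """Simulate and write the full dataset; returns a path manifest."""
    from . import gff
    from .targeting import write_degradome_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = simulate_genome(config)
    reads = simulate_reads(genome, truth, config)
    transcripts = truth.transcript_sequences(genome)
    profiles = simulate_degradome(truth, transcripts, config)

    paths = {}
    paths["genome"] = str(outdir / "genome.fa")
    _write_fasta(paths["genome"], genome)
    paths["transcripts"] = str(outdir / "transcripts.fa")
    _write_fasta(paths["transcripts"], transcripts)
    paths["known_mirnas"] = str(outdir / "known_mirnas.fa")
    _write_fasta(paths["known_mirnas"], truth.known_matures)
    for cond, records in reads.items():
        p = str(outdir / f"reads_{cond}.fastq")
        paths[f"reads:{cond}"] = p
        with open(p, "w") as fh:
            for rid, rseq, qual in records:
                fh.write(f"@{rid}\n{rseq}\n+\n{qual}\n")
    paths["degradome"] = str(outdir / "degradome.tsv")
    write_degradome_tsv(profiles, paths["degradome"])
    paths["truth_gff"] = str(outdir / "truth.gff3")
    gff.write_truth_gff(truth, paths["truth_gff"])
    paths["truth_targets"] = str(outdir / "truth_targets.tsv")
    with open(paths["truth_targets"], "w") as fh:
        fh.write("small_rna_id\ttranscript_id\tbinding_start\tbinding_end\t"
                 "cleavage_position\n")
        for ev in truth.target_events:
            fh.write(f"{ev.small_rna_id}\t{ev.transcript_id}\t"
                     f"{ev.binding_interval[0]}\t{ev.binding_interval[1]}\t"
                     f"{ev.cleavage_position}\n")
    paths["expression_truth"] = str(outdir / "expression_truth.tsv")
    with open(paths["expression_truth"], "w") as fh:
        fh.write("locus_id\tcondition\texpected_rpm\n")
        for lid in sorted(truth.expression_truth):
            for cond, rpm in truth.expression_truth[lid].items():
                fh.write(f"{lid}\t{cond}\t{rpm:.4f}\n")
    return paths


def _write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            s = sequences[name]
            for i in range(0, len(s), 70):
                fh.write(s[i:i + 70] + "\n")
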