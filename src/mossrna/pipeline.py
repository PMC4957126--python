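"""End-to-end orchestration: preprocess -> align -> miRNA -> siRNA ->
targeting (+degradome) -> expression, with read accounting and a checksum
manifest for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import gff
from .alignment import cluster_placements, place_reads
from .expression import build_table, call_de, de_calls_frame
from .mirna import discover_mirnas, match_known
from .preprocess import (filter_qualified, read_fastq, write_collapsed_fasta,
                         write_count_table)
from .sirna import call_sirna_loci, classify_tas, summarize_hpRNA
from .targeting import (find_target_sites, read_degradome_tsv,
                        validate_with_degradome, write_cleavage_tsv,
                        write_sites_tsv)

log = logging.getLogger("mossrna")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a pipeline run.

    Threshold defaults are the method's canonical values: adapter matches
    of more than 6 nt, minimum insert 17 nt, 300-nt locus extension, 250-nt
    folding windows, 50-nt siRNA clustering, 10-read support, 70% 21-nt
    enrichment, target cutoffs 4 (standalone) / 8 (with degradome), and the
    2-fold differential-expression rule.
    """

    # inputs
    genome: str = ""
    transcripts: str = ""
    known_mirnas: str = ""
    libraries: dict[str, str] = field(default_factory=dict)  # condition -> fastq
    degradome: str = ""
    # preprocess
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter_min_match: int = 6
    min_length: int = 17
    min_mean_quality: float | None = 20.0
    # miRNA discovery
    locus_extension: int = 300
    window_size: int = 250
    window_step: int = 25
    mirna_min_reads: int = 10       # strict: mature support must exceed this
    overhang_tolerance: int = 1
    fold_backend: str = "auto"
    known_locus_flank: int = 60     # known-mature hit -> precursor-scale removal
    # siRNA discovery
    sirna_cluster_window: int = 50
    sirna_min_reads: int = 10
    sirna_min_fraction_21: float = 0.70
    search_cdna: bool = True
    # targeting
    target_cutoff: float = 4.0
    degradome_cutoff: float = 8.0
    degradome_min_reads: int = 5
    cleavage_slop: int = 1
    max_sirna_queries_per_cluster: int = 3
    # expression
    de_fold_threshold: float = 2.0
    de_pseudocount: float = 1.0
    comparison_pairs: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "comparison_pairs" in data:
            data["comparison_pairs"] = [tuple(p) for p in data["comparison_pairs"]]
        return cls(**data)


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline; returns the output manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label, path in [("genome", config.genome)] + \
            [(f"library {c}", p) for c, p in config.libraries.items()]:
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"missing input: {label} ({path!r})")

    genome = _read_fasta(config.genome)
    transcripts = _read_fasta(config.transcripts) if config.transcripts else {}
    known = _read_fasta(config.known_mirnas) if config.known_mirnas else {}

    # ---- preprocess ------------------------------------------------------
    log.info("preprocessing %d libraries", len(config.libraries))
    raw_stream = (read for cond in sorted(config.libraries)
                  for read in read_fastq(config.libraries[cond], library=cond))
    clean, tally = filter_qualified(
        raw_stream, config.adapter, min_length=config.min_length,
        min_mean_quality=config.min_mean_quality,
        min_match=config.adapter_min_match)
    write_collapsed_fasta(clean, outdir / "collapsed.fa")
    write_count_table(clean, outdir / "collapsed_counts.tsv")
    with open(outdir / "discard_summary.tsv", "w") as fh:
        fh.write("reason\tcount\n")
        for reason, count in tally.items():
            fh.write(f"{reason}\t{count}\n")

    # ---- alignment -------------------------------------------------------
    placements = place_reads(clean, genome)
    placed_seqs = {p.clean_read.sequence for p in placements}
    mapped_reads = [r for r in clean if r.sequence in placed_seqs]
    unplaced = [r for r in clean if r.sequence not in placed_seqs]
    library_totals = {}
    for read in mapped_reads:
        for lib, cnt in read.counts.items():
            library_totals[lib] = library_totals.get(lib, 0) + cnt
    log.info("placed %d/%d distinct reads", len(mapped_reads), len(clean))

    # ---- miRNA discovery -------------------------------------------------
    known_hits, pool = match_known(mapped_reads, known)
    pool_seqs = {r.sequence for r in pool}
    pool_placements = [p for p in placements if p.clean_read.sequence in pool_seqs]
    # placements inside a known-miRNA locus neighbourhood (star reads,
    # isomiRs) belong to the known annotation and must not seed novel
    # discovery
    known_neighbourhoods = []
    for mid, readset in known_hits.items():
        seqs = {r.sequence for r in readset}
        for p in placements:
            if p.clean_read.sequence in seqs:
                known_neighbourhoods.append(
                    (p.chrom, p.start - config.known_locus_flank,
                     p.end + config.known_locus_flank))
    discovery_placements = [
        p for p in pool_placements
        if not any(c == p.chrom and p.start < e and p.end > s
                   for c, s, e in known_neighbourhoods)]
    annotations, rejections = discover_mirnas(
        discovery_placements, genome, backend=config.fold_backend,
        min_mature_reads=config.mirna_min_reads,
        extension=config.locus_extension, window=config.window_size,
        step=config.window_step)
    for k, ann in enumerate(annotations, start=1):
        ann.name = f"novel-miR{k}"
    gff.write_mirna_gff(annotations, outdir / "mirna.gff3")
    log.info("%d novel miRNA annotations (%d windows rejected)",
             len(annotations), len(rejections))

    # ---- siRNA discovery -------------------------------------------------
    # a known mature read marks its whole precursor neighbourhood as a
    # miRNA locus so that star/isomiR reads are removed with it
    mirna_intervals = [(a.chrom, a.precursor[0], a.precursor[1])
                       for a in annotations]
    for mid, readset in known_hits.items():
        seqs = {r.sequence for r in readset}
        for p in placements:
            if p.clean_read.sequence in seqs:
                mirna_intervals.append((p.chrom,
                                        p.start - config.known_locus_flank,
                                        p.end + config.known_locus_flank))

    def in_mirna_locus(p) -> bool:
        return any(c == p.chrom and p.start < e and p.end > s
                   for c, s, e in mirna_intervals)

    mirna_read_seqs = {p.clean_read.sequence for p in pool_placements
                       if in_mirna_locus(p)}
    for readset in known_hits.values():
        mirna_read_seqs |= {r.sequence for r in readset}
    sirna_pool = [r for r in mapped_reads if r.sequence not in mirna_read_seqs]
    sirna_placements = [p for p in placements
                        if p.clean_read.sequence in {r.sequence for r in sirna_pool}]
    clusters = cluster_placements(sirna_placements, config.sirna_cluster_window,
                                  stranded=False)
    accepted, rejected = call_sirna_loci(
        clusters, min_reads=config.sirna_min_reads,
        min_fraction_21=config.sirna_min_fraction_21)
    if config.search_cdna and transcripts:
        accepted = _add_cdna_clusters(accepted, sirna_pool, transcripts, config)
    triggers = dict(known)
    triggers.update({ann.name: ann.mature_sequence for ann in annotations})
    for cl in accepted:
        ref = genome if cl.locus.chrom in genome else transcripts
        classify_tas(cl, ref, triggers, cutoff=config.target_cutoff,
                     backend=config.fold_backend)
    gff.write_sirna_gff(accepted, outdir / "sirna.gff3")
    hp_rows = []
    for cl in accepted:
        if cl.classification == "hpRNA":
            ref = genome if cl.locus.chrom in genome else transcripts
            s = summarize_hpRNA(cl, ref, backend=config.fold_backend)
            hp_rows.append((cl.locus.chrom, cl.locus.start + 1, cl.locus.end,
                            s.arm5_count, s.arm3_count, s.loop_count,
                            "" if s.arm_ratio is None else f"{s.arm_ratio:.2f}",
                            f"{s.size_class_fraction_20_22:.3f}"))
    with open(outdir / "hpRNA_summary.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tarm5_reads\tarm3_reads\tloop_reads\t"
                 "arm_ratio\tfraction_20_22\n")
        for row in hp_rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    log.info("%d siRNA clusters accepted (%d rejected)",
             len(accepted), len(rejected))

    # ---- targeting -------------------------------------------------------
    queries: dict[str, str] = {}
    for ann in annotations:
        queries[ann.name] = ann.mature_sequence
    for mid, readset in known_hits.items():
        if readset and mid in known:
            queries[mid] = known[mid]
    for k, cl in enumerate(accepted):
        top = sorted(cl.locus.placements,
                     key=lambda p: (-p.count, p.clean_read.sequence))
        for j, p in enumerate(top[:config.max_sirna_queries_per_cluster]):
            queries[f"sirna{k + 1}.{j + 1}"] = p.clean_read.sequence
    profiles = (read_degradome_tsv(config.degradome)
                if config.degradome else {})
    mode_cutoff = config.degradome_cutoff if profiles else config.target_cutoff
    sites = []
    for qid in sorted(queries):
        mode = "miRNA" if not qid.startswith("sirna") else "siRNA"
        sites.extend(find_target_sites(queries[qid], transcripts, mode,
                                       cutoff=mode_cutoff, small_rna_id=qid))
    write_sites_tsv(sites, outdir / "target_sites.tsv")
    calls = validate_with_degradome(sites, profiles,
                                    min_reads=config.degradome_min_reads,
                                    slop=config.cleavage_slop) if profiles else []
    write_cleavage_tsv(calls, outdir / "cleavage_calls.tsv")

    # ---- expression ------------------------------------------------------
    counts: dict[str, dict[str, int]] = {}
    for ann in annotations:
        counts[f"{ann.name}.mature"] = _sum_counts(
            r for r in pool if r.sequence == ann.mature_sequence)
        counts[f"{ann.name}.star"] = _sum_counts(
            r for r in pool if r.sequence == ann.star_sequence)
    for mid, readset in known_hits.items():
        if readset:
            counts[mid] = _sum_counts(readset)
    for k, cl in enumerate(accepted):
        per_lib: dict[str, int] = {}
        for p in cl.locus.placements:
            for lib, c in p.clean_read.counts.items():
                per_lib[lib] = per_lib.get(lib, 0) + c
        counts[f"sirna{k + 1}"] = per_lib
    table = build_table(counts, library_totals) if library_totals else None
    de_calls = []
    if table is not None and not table.empty:
        pairs = config.comparison_pairs or _default_pairs(library_totals)
        de_calls = call_de(table, pairs, pseudocount=config.de_pseudocount,
                           fold_threshold=config.de_fold_threshold)
        table.to_csv(outdir / "expression_rpm.tsv", sep="\t")
        de_calls_frame(de_calls).to_csv(outdir / "de_calls.tsv", sep="\t",
                                        index=False)

    # ---- accounting + manifest ------------------------------------------
    raw_total = sum(tally.values())
    qualified = tally["kept"]
    mirna_assigned = sum(r.total_count for r in mapped_reads
                         if r.sequence in mirna_read_seqs)
    sirna_pool_total = sum(r.total_count for r in sirna_pool)
    unplaced_total = sum(r.total_count for r in unplaced)
    accounting = {
        "raw_reads": raw_total,
        "qualified": qualified,
        "discarded": raw_total - qualified,
        "mirna_assigned": mirna_assigned,
        "sirna_pool": sirna_pool_total,
        "unplaced": unplaced_total,
    }
    assert qualified == mirna_assigned + sirna_pool_total + unplaced_total
    manifest = {"accounting": accounting, "outputs": {}, "seed": config.seed,
                "n_mirna": len(annotations), "n_sirna_clusters": len(accepted),
                "n_target_sites": len(sites),
                "n_validated_cleavages": sum(c.validated for c in calls),
                "n_de_calls": len(de_calls)}
    for path in sorted(outdir.glob("*")):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest["outputs"][path.name] = {
            "sha256": _sha256(path),
            "rows": sum(1 for _ in open(path)) if path.suffix != ".json" else None,
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _sum_counts(reads) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in reads:
        for lib, c in r.counts.items():
            out[lib] = out.get(lib, 0) + c
    return out


def _default_pairs(library_totals) -> list[tuple[str, str]]:
    libs = sorted(library_totals)
    return [(b, a) for a, b in zip(libs, libs[1:])]


def _add_cdna_clusters(accepted, sirna_pool, transcripts, config):
    """Search cDNA for 21-nt-enriched clusters missed on the genome.

    Clusters whose reads are already members of an accepted genomic cluster
    are duplicates of the genomic call and are dropped (genome coordinates
    win); only cDNA-exclusive clusters are appended.
    """
    seen = {p.clean_read.sequence for cl in accepted for p in cl.locus.placements}
    tx_placements = place_reads(sirna_pool, transcripts)
    clusters = cluster_placements(tx_placements, config.sirna_cluster_window,
                                  stranded=False)
    extra, _ = call_sirna_loci(clusters, min_reads=config.sirna_min_reads,
                               min_fraction_21=config.sirna_min_fraction_21)
    for cl in extra:
        if not any(p.clean_read.sequence in seen for p in cl.locus.placements):
            accepted.append(cl)
    return accepted
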