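"""Exact (zero-mismatch) read placement and locus clustering.

Qualified reads are placed on the reference with no mismatches on both
strands; every occurrence is reported and each placement carries the total
number of genome-wide hits of its sequence.  Placements are then clustered
into loci by single linkage: two placements join one locus when their
intervals overlap or the gap between them is at most the clustering window.

Coordinates are 0-based half-open internally; file output (GFF3) is 1-based
closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .preprocess import CleanRead
from .seq import revcomp


@dataclass(frozen=True)
class Placement:
    """One zero-mismatch occurrence of a clean read on the reference."""

    clean_read: CleanRead
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    n_genomic_hits: int = 1

    @property
    def count(self) -> int:
        return self.clean_read.total_count

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """0-based coordinate of the 5' end of the read on the reference."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GenomicLocus:
    """A strand-aware half-open interval with the placements it contains."""

    chrom: str
    start: int
    end: int
    placements: list[Placement] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(p.count for p in self.placements)

    @property
    def n_distinct_reads(self) -> int:
        return len({p.clean_read.sequence for p in self.placements})

    @property
    def length_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for p in self.placements:
            hist[p.length] = hist.get(p.length, 0) + p.count
        return hist

    @property
    def strands(self) -> set[str]:
        return {p.strand for p in self.placements}


def _occurrences(haystack: str, needle: str) -> list[int]:
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def place_reads(reads: list[CleanRead], genome: dict[str, str]) -> list[Placement]:
    """Report every exact occurrence of each read on both strands.

    ``genome`` maps chromosome id to uppercase sequence.  Reads containing
    non-ACGT characters are rejected.  Output order is deterministic:
    by chromosome, start, strand, then read sequence.
    """
    placements: list[Placement] = []
    chrom_ids = sorted(genome)
    for read in reads:
        if any(b not in "ACGT" for b in read.sequence):
            raise ValueError(f"read contains non-ACGT base: {read.sequence!r}")
        hits: list[tuple[str, int, str]] = []
        rc = revcomp(read.sequence)
        for chrom in chrom_ids:
            seq = genome[chrom]
            for start in _occurrences(seq, read.sequence):
                hits.append((chrom, start, "+"))
            for start in _occurrences(seq, rc):
                hits.append((chrom, start, "-"))
        for chrom, start, strand in hits:
            placements.append(Placement(read, chrom, start,
                                        start + len(read.sequence), strand,
                                        n_genomic_hits=len(hits)))
    placements.sort(key=lambda p: (p.chrom, p.start, p.strand, p.clean_read.sequence))
    return placements


def cluster_placements(placements: list[Placement], window: int,
                       *, stranded: bool = False) -> list[GenomicLocus]:
    """Single-linkage clustering of placements into loci.

    Two placements on the same chromosome (and strand, if ``stranded``) join
    one locus when the gap between their intervals is at most ``window`` nt;
    overlapping intervals always join.  Locus bounds are the min start / max
    end of the members.
    """
    groups: dict[tuple, list[Placement]] = {}
    for p in placements:
        key = (p.chrom, p.strand) if stranded else (p.chrom,)
        groups.setdefault(key, []).append(p)
    loci: list[GenomicLocus] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda p: (p.start, p.end))
        current: list[Placement] = []
        cur_end = None
        for p in members:
            if current and p.start - cur_end > window:
                loci.append(GenomicLocus(current[0].chrom, current[0].start,
                                         cur_end, current))
                current = []
                cur_end = None
            current.append(p)
            cur_end = p.end if cur_end is None else max(cur_end, p.end)
        if current:
            loci.append(GenomicLocus(current[0].chrom, current[0].start,
                                     cur_end, current))
    loci.sort(key=lambda l: (l.chrom, l.start, l.end))
    return loci


def load_sam_placements(path, reads_by_seq: dict[str, CleanRead]) -> list[Placement]:
    """Ingest external aligner output (SAM text) as placements.

    Primary and secondary records are accepted; records with NM > 0 or any
    non-match CIGAR operation are rejected to enforce the zero-mismatch
    contract.  ``reads_by_seq`` links alignment sequences back to collapsed
    reads (reverse complement is consulted for minus-strand records).
    """
    import pysam

    placements = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if any(op != 0 for op, _ in (rec.cigartuples or [])):
                raise ValueError(f"non-match CIGAR in record {rec.query_name}")
            if rec.has_tag("NM") and rec.get_tag("NM") != 0:
                raise ValueError(f"NM != 0 in record {rec.query_name}")
            seq = rec.query_sequence.upper()
            strand = "-" if rec.is_reverse else "+"
            if strand == "-":
                seq = revcomp(seq)
            read = reads_by_seq.get(seq)
            if read is None:
                continue
            placements.append(Placement(read, rec.reference_name,
                                        rec.reference_start, rec.reference_end,
                                        strand))
    # recompute hit multiplicity per sequence
    by_seq: dict[str, int] = {}
    for p in placements:
        by_seq[p.clean_read.sequence] = by_seq.get(p.clean_read.sequence, 0) + 1
    placements = [Placement(p.clean_read, p.chrom, p.start, p.end, p.strand,
                            n_genomic_hits=by_seq[p.clean_read.sequence])
                  for p in placements]
    placements.sort(key=lambda p: (p.chrom, p.start, p.strand, p.clean_read.sequence))
    return placements
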