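"""Known-miRNA matching and novel miRNA precursor discovery.

Novel precursors are found by the classic plant small-RNA procedure: reads
matching known mature miRNAs are set aside, the remaining placements are
merged into loci wherever reads overlap, each locus is extended 300 nt on
both ends, 250-nt windows are slid across the extension, every window is
folded, and a candidate is accepted only when all four criteria hold:

1. the candidate mature accumulates more than 10 reads;
2. the window folds into a hairpin placing mature and star on opposite arms
   (>= 60% of mature bases paired, none within the mature itself, and the
   mature/star duplex dominating the window's read output);
3. at least one sequenced read corresponds to the star sequence; and
4. re-annealing mature and star yields ~2-nt 3' overhangs on both ends
   (tolerance 2 +/- 1 nt).

Overlapping accepted windows describing the same mature collapse to a
single annotation (the best-paired duplex wins).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .alignment import GenomicLocus, Placement, cluster_placements
from .fold import FoldResult, fold
from .preprocess import CleanRead
from .seq import is_wc_pair, is_wobble_pair, revcomp

LOCUS_EXTENSION = 300
WINDOW_SIZE = 250
WINDOW_STEP = 25
MIN_MATURE_READS = 10       # strict: mature_count must exceed this
MIN_PAIRED_FRACTION = 0.6
#: re-annealed mature/star duplex: at most ~5 of 21 positions unpaired,
#: the standard plant miRNA duplex criterion
DUPLEX_MIN_PAIRED_FRACTION = 0.75
OVERHANG_TOLERANCE = 1      # accepted overhangs: 2 +/- 1 nt
ISOMIR_SLOP = 2             # reads within +/-2 nt of the representative
MIN_DUPLEX_FRACTION = 0.5   # mature+star reads must dominate the window


@dataclass
class DuplexGeometry:
    """Geometry of a mature/star duplex obtained by re-annealing the two
    sequences (independent of the genomic fold)."""

    overhang_3p_mature: int
    overhang_3p_star: int
    paired_fraction: float
    n_pairs: int


@dataclass
class MirnaAnnotation:
    chrom: str
    strand: str
    precursor: tuple[int, int]        # genomic, 0-based half-open
    mature: tuple[int, int]
    star: tuple[int, int]
    mature_sequence: str
    star_sequence: str
    mature_count: int
    star_count: int
    duplex: DuplexGeometry
    fold: FoldResult
    status: str = "novel"             # {known, novel}
    name: str = ""


@dataclass
class Rejection:
    chrom: str
    window: tuple[int, int]
    reason: str


def write_precursor_fasta(annotations: list[MirnaAnnotation], genome: dict[str, str],
                          path) -> None:
    """Precursor sequences with their dot-bracket structure in the header."""
    with open(path, "w") as fh:
        for k, ann in enumerate(annotations, start=1):
            name = ann.name or f"novel-miR{k}"
            s, e = ann.precursor
            seq = genome[ann.chrom][s:e]
            if ann.strand == "-":
                seq = revcomp(seq)
            fh.write(f">{name} {ann.chrom}:{s + 1}-{e}({ann.strand}) "
                     f"{ann.fold.structure}\n{seq}\n")


def write_mature_star_counts(annotations: list[MirnaAnnotation],
                             reads_by_seq: dict[str, "CleanRead"], path) -> None:
    """Per-library mature and star counts for each annotation."""
    libraries = sorted({lib for r in reads_by_seq.values() for lib in r.counts})
    with open(path, "w") as fh:
        fh.write("id\tpart\tsequence\t" + "\t".join(libraries) + "\n")
        for k, ann in enumerate(annotations, start=1):
            name = ann.name or f"novel-miR{k}"
            for part, seq in (("mature", ann.mature_sequence),
                              ("star", ann.star_sequence)):
                counts = reads_by_seq.get(seq)
                row = "\t".join(str(counts.counts.get(lib, 0) if counts else 0)
                                for lib in libraries)
                fh.write(f"{name}\t{part}\t{seq}\t{row}\n")


def anneal_duplex(mature: str, star: str) -> DuplexGeometry:
    """Anneal two small-RNA strands as a free duplex.

    Tries every antiparallel register (mature position i pairing star
    position j with i + j constant), counts Watson-Crick plus wobble pairs,
    and keeps the register with the most pairs (ties: overhangs closest to
    the canonical 2 nt).  3' overhangs are the unpaired terminal lengths
    implied by the register, not by which bases happen to pair.
    """
    lm, ls = len(mature), len(star)
    best = None
    for d in range(lm + ls - 1):
        pairs = 0
        for i in range(max(0, d - ls + 1), min(lm, d + 1)):
            a, b = mature[i], star[d - i]
            if is_wc_pair(a, b) or is_wobble_pair(a, b):
                pairs += 1
        over_m = lm - 1 - d   # mature 3' bases past the star 5' end
        over_s = ls - 1 - d   # star 3' bases past the mature 5' end
        badness = abs(over_m - 2) + abs(over_s - 2)
        key = (-pairs, badness, d)
        if best is None or key < best[0]:
            best = (key, pairs, over_m, over_s)
    _, pairs, over_m, over_s = best
    return DuplexGeometry(over_m, over_s, pairs / max(lm, 1), pairs)


def match_known(reads: list[CleanRead], known_matures: dict[str, str],
                slop: int = 2) -> tuple[dict[str, list[CleanRead]], list[CleanRead]]:
    """Split reads into known-miRNA expression and the novel-discovery pool.

    A read matches a known mature when the two sequences are identical up to
    trimming/extension of at most ``slop`` nt at each terminus (zero
    mismatches in the shared body).  Returns (matches per known id, pool).
    """
    matched: dict[str, list[CleanRead]] = {mid: [] for mid in known_matures}
    pool: list[CleanRead] = []
    for read in reads:
        hit = None
        for mid in sorted(known_matures):
            if _termini_match(read.sequence, known_matures[mid], slop):
                hit = mid
                break
        if hit is None:
            pool.append(read)
        else:
            matched[hit].append(read)
    return matched, pool


def _termini_match(a: str, b: str, slop: int) -> bool:
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if len(long_) - len(short) > 2 * slop:
        return False
    for off in range(len(long_) - len(short) + 1):
        if off <= slop and (len(long_) - len(short) - off) <= slop \
                and long_[off:off + len(short)] == short:
            return True
    return False


def candidate_windows(loci: list[GenomicLocus], genome: dict[str, str],
                      *, extension: int = LOCUS_EXTENSION,
                      window: int = WINDOW_SIZE,
                      step: int = WINDOW_STEP) -> Iterator[tuple[str, int, int]]:
    """Extend each locus and emit sliding windows over the extension.

    Each locus is widened by ``extension`` nt on both ends (clamped to the
    chromosome), then ``window``-nt segments are emitted from the 5' end
    with the given step while they fit; an extension shorter than one window
    yields a single full-region segment.
    """
    for locus in loci:
        chrom_len = len(genome[locus.chrom])
        lo = max(0, locus.start - extension)
        hi = min(chrom_len, locus.end + extension)
        if hi - lo <= window:
            yield (locus.chrom, lo, hi)
            continue
        start = lo
        while start + window <= hi:
            yield (locus.chrom, start, start + window)
            start += step


def fold_window(window_seq: str, backend: str = "auto") -> FoldResult:
    """Fold one candidate window (DNA in, transcribed internally)."""
    return fold(window_seq, backend=backend)


def _window_relative(p: Placement, win: tuple[str, int, int], strand: str) -> tuple[int, int]:
    _, ws, we = win
    if strand == "+":
        return p.start - ws, p.end - ws
    return we - p.end, we - p.start


def _derive_star(pair_table, m_s: int, m_e: int) -> tuple[tuple[int, int] | None, str]:
    """Locate the star interval implied by the fold of the window.

    The partners of the mature's paired bases must all fall outside the
    mature (no self-pairing) and on one side; the duplex register D = i +
    partner(i) (its median over paired mature bases) places the star so that
    each strand's 3' end overhangs by 2 nt.
    """
    partners = [(i, pair_table[i]) for i in range(m_s, m_e)
                if pair_table[i] is not None]
    m_len = m_e - m_s
    if len(partners) / m_len < MIN_PAIRED_FRACTION:
        return None, "not_hairpin"
    if any(m_s <= j < m_e for _, j in partners):
        return None, "self_pairing"
    regs = sorted(i + j for i, j in partners)
    d = regs[len(regs) // 2]
    star = (d - m_e + 3, d - m_s + 3)
    if star[0] < 0:
        return None, "star_outside_window"
    return star, ""


def _intervals_close(a: tuple[int, int], b: tuple[int, int], slop: int) -> bool:
    return abs(a[0] - b[0]) <= slop and abs(a[1] - b[1]) <= slop


def call_mirna(window: tuple[str, int, int], window_seq: str, strand: str,
               placements: list[Placement], fold_result: FoldResult, *,
               min_mature_reads: int = MIN_MATURE_READS,
               min_duplex_fraction: float = MIN_DUPLEX_FRACTION,
               overhang_tolerance: int = OVERHANG_TOLERANCE,
               ) -> MirnaAnnotation | Rejection:
    """Apply the four acceptance criteria to one folded window.

    ``placements`` must be same-strand placements lying fully inside the
    window; ``window_seq`` is the strand-oriented window sequence matching
    ``fold_result``.
    """
    chrom, ws, we = window
    rel = [(p, *_window_relative(p, window, strand)) for p in placements]
    rel = [(p, s, e) for p, s, e in rel if s >= 0 and e <= we - ws]
    if not rel:
        return Rejection(chrom, (ws, we), "no_reads")
    # candidate mature: most abundant distinct read in the window
    rel.sort(key=lambda t: (-t[0].count, t[1], t[0].clean_read.sequence))
    mature_p, m_s, m_e = rel[0]
    mature_iv = (m_s, m_e)
    mature_count = sum(p.count for p, s, e in rel
                       if _intervals_close((s, e), mature_iv, ISOMIR_SLOP))
    if mature_count <= min_mature_reads:
        return Rejection(chrom, (ws, we), "insufficient_reads")
    star_iv, why = _derive_star(fold_result.pair_table, m_s, m_e)
    if star_iv is None:
        return Rejection(chrom, (ws, we), why)
    if star_iv[1] > we - ws or not (star_iv[1] <= m_s or star_iv[0] >= m_e):
        return Rejection(chrom, (ws, we), "star_overlaps_mature")
    star_count = sum(p.count for p, s, e in rel
                     if _intervals_close((s, e), star_iv, ISOMIR_SLOP))
    if star_count < 1:
        return Rejection(chrom, (ws, we), "no_star_read")
    mature_seq = window_seq[m_s:m_e]
    star_seq = window_seq[star_iv[0]:star_iv[1]]
    duplex = anneal_duplex(mature_seq, star_seq)
    if abs(duplex.overhang_3p_mature - 2) > overhang_tolerance \
            or abs(duplex.overhang_3p_star - 2) > overhang_tolerance:
        return Rejection(chrom, (ws, we), "bad_overhang")
    if duplex.paired_fraction < DUPLEX_MIN_PAIRED_FRACTION:
        return Rejection(chrom, (ws, we), "weak_duplex")
    total = sum(p.count for p, _, _ in rel)
    if (mature_count + star_count) / total < min_duplex_fraction:
        return Rejection(chrom, (ws, we), "duplex_not_dominant")

    def to_genome(iv: tuple[int, int]) -> tuple[int, int]:
        if strand == "+":
            return (ws + iv[0], ws + iv[1])
        return (we - iv[1], we - iv[0])

    g_mature = to_genome(mature_iv)
    g_star = to_genome(star_iv)
    precursor = (min(g_mature[0], g_star[0]), max(g_mature[1], g_star[1]))
    return MirnaAnnotation(chrom, strand, precursor, g_mature, g_star,
                           mature_seq, star_seq, mature_count, star_count,
                           duplex, fold_result)


def discover_mirnas(placements: list[Placement], genome: dict[str, str], *,
                    backend: str = "auto",
                    min_mature_reads: int = MIN_MATURE_READS,
                    extension: int = LOCUS_EXTENSION,
                    window: int = WINDOW_SIZE, step: int = WINDOW_STEP,
                    ) -> tuple[list[MirnaAnnotation], list[Rejection]]:
    """Full novel-miRNA discovery over a set of genome placements.

    Placements are merged into strand-specific loci wherever reads overlap;
    only loci whose read support can possibly satisfy the mature-count
    criterion seed candidate windows.  Accepted calls from overlapping
    windows are deduplicated on the genomic mature interval, keeping the
    best-paired duplex.
    """
    loci = cluster_placements(placements, 0, stranded=True)
    by_strand: dict[str, list[Placement]] = {"+": [], "-": []}
    for p in placements:
        by_strand[p.strand].append(p)
    accepted: dict[tuple, MirnaAnnotation] = {}
    rejections: list[Rejection] = []
    for locus in loci:
        if locus.total_count <= min_mature_reads:
            continue
        strand = next(iter(locus.strands))
        candidates = [p for p in by_strand[strand] if p.chrom == locus.chrom]
        for win in candidate_windows([locus], genome, extension=extension,
                                     window=window, step=step):
            _, ws, we = win
            inside = [p for p in candidates if p.start >= ws and p.end <= we]
            if sum(p.count for p in inside) <= min_mature_reads:
                continue
            seq = genome[locus.chrom][ws:we]
            if strand == "-":
                seq = revcomp(seq)
            result = call_mirna(win, seq, strand, inside, fold_window(seq, backend),
                                min_mature_reads=min_mature_reads)
            if isinstance(result, Rejection):
                rejections.append(result)
                continue
            key = (result.chrom, result.strand, result.mature)
            prev = accepted.get(key)
            if prev is None or result.duplex.n_pairs > prev.duplex.n_pairs:
                accepted[key] = result
    # collapse annotations whose matures overlap (same locus seen from
    # neighbouring windows with slightly shifted representatives)
    final: list[MirnaAnnotation] = []
    for key in sorted(accepted, key=lambda k: (k[0], k[2], k[1])):
        ann = accepted[key]
        merged = False
        for prev in final:
            if prev.chrom == ann.chrom and prev.strand == ann.strand \
                    and _intervals_close(prev.mature, ann.mature, ISOMIR_SLOP):
                if ann.duplex.n_pairs > prev.duplex.n_pairs:
                    final[final.index(prev)] = ann
                merged = True
                break
        if not merged:
            final.append(ann)
    final.sort(key=lambda a: (a.chrom, a.precursor, a.strand))
    return final, rejections
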