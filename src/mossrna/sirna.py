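"""siRNA-producing locus calling and classification.

Read clusters (50-nt single-linkage, after removal of miRNA-assigned reads)
are kept as siRNA candidates when they carry at least 10 mapped reads and
strictly more than 70% of those reads are exactly 21 nt long — the signature
of DCL4-phased products, as opposed to random degradation or heterochromatic
24-nt siRNAs.  Kept clusters are classified:

* ``TAS-like`` — a small-RNA (miRNA) binding site scored at the standard
  target cutoff lies within the cluster's flanking context; ta-siRNA
  production requires such a trigger cleavage site.
* ``hpRNA`` — the locus context folds back into one long, highly annealed
  stem (>= 80 paired nt) with reads on both arms.
* ``other`` — neither.

A diagnostic phasing statistic (fraction of 21-nt read 5' ends on the
dominant mod-21 register) is reported but never used for filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import GenomicLocus, Placement
from .fold import FoldResult, fold
from .targeting import DEFAULT_CUTOFF, TargetAlignment, find_target_sites

MIN_CLUSTER_READS = 10
MIN_21NT_FRACTION = 0.70        # strict: must exceed
SIRNA_CLUSTER_WINDOW = 50
TRIGGER_FLANK = 300
HPRNA_CONTEXT = 500
MIN_HPRNA_STEM_PAIRS = 80


@dataclass
class SirnaCluster:
    locus: GenomicLocus
    total_count: int
    fraction_21nt: float
    n_distinct_reads: int
    classification: str = "unclassified"   # {TAS-like, hpRNA, other}
    trigger_sites: list[TargetAlignment] = field(default_factory=list)
    phase_register_fraction: float = 0.0


@dataclass
class HpRnaSummary:
    cluster: SirnaCluster
    arm5_count: int
    arm3_count: int
    loop_count: int
    arm_ratio: float | None       # arm3/arm5 in reads; None when undefined
    size_class_fraction_20_22: float


def _fraction_21nt(locus: GenomicLocus) -> float:
    hist = locus.length_histogram
    total = sum(hist.values())
    return hist.get(21, 0) / total if total else 0.0


def _phase_register_fraction(locus: GenomicLocus) -> float:
    """Fraction of 21-nt read 5' ends on the dominant mod-21 register."""
    registers: dict[int, int] = {}
    total = 0
    for p in locus.placements:
        if p.length != 21:
            continue
        registers[p.five_prime % 21] = registers.get(p.five_prime % 21, 0) + p.count
        total += p.count
    if not total:
        return 0.0
    return max(registers.values()) / total


def call_sirna_loci(loci: list[GenomicLocus], *,
                    min_reads: int = MIN_CLUSTER_READS,
                    min_fraction_21: float = MIN_21NT_FRACTION,
                    ) -> tuple[list[SirnaCluster], list[tuple[GenomicLocus, str]]]:
    """Apply the read-support and 21-nt enrichment filters to clusters.

    Returns (accepted clusters, rejected (locus, reason) pairs).  Both
    filters are strict boundaries: clusters with fewer than ``min_reads``
    mapped reads, or a 21-nt fraction not exceeding ``min_fraction_21``, are
    removed.
    """
    accepted, rejected = [], []
    for locus in loci:
        total = locus.total_count
        if total < min_reads:
            rejected.append((locus, "insufficient_reads"))
            continue
        frac = _fraction_21nt(locus)
        if not frac > min_fraction_21:
            rejected.append((locus, "not_21nt_enriched"))
            continue
        accepted.append(SirnaCluster(
            locus, total, frac, locus.n_distinct_reads,
            phase_register_fraction=_phase_register_fraction(locus)))
    return accepted, rejected


STEM_REGISTER_TOLERANCE = 30    # bulge slack when grouping pairs into a stem


def _hairpin_arms(fold_result: FoldResult) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """5'/3' arm intervals of the dominant stem, or None if it is too short.

    Pairs belonging to one (possibly bulged) stem share a pairing register
    i + partner(i); the modal register isolates the long foldback from
    incidental pairing in the flanks.
    """
    pt = fold_result.pair_table
    pairs = [(i, j) for i, j in enumerate(pt) if j is not None and j > i]
    if len(pairs) < MIN_HPRNA_STEM_PAIRS:
        return None
    registers = sorted(i + j for i, j in pairs)
    # densest register window = the dominant stem
    best_lo = best_n = 0
    for lo in range(len(registers)):
        hi = lo
        while hi < len(registers) and \
                registers[hi] - registers[lo] <= 2 * STEM_REGISTER_TOLERANCE:
            hi += 1
        if hi - lo > best_n:
            best_lo, best_n = lo, hi - lo
    if best_n < MIN_HPRNA_STEM_PAIRS:
        return None
    d_lo = registers[best_lo]
    d_hi = d_lo + 2 * STEM_REGISTER_TOLERANCE
    stem = [(i, j) for i, j in pairs if d_lo <= i + j <= d_hi]
    five = [i for i, _ in stem]
    three = [j for _, j in stem]
    return (min(five), max(five) + 1), (min(three), max(three) + 1)


def classify_tas(cluster: SirnaCluster, genome: dict[str, str],
                 trigger_small_rnas: dict[str, str], *,
                 cutoff: float = DEFAULT_CUTOFF,
                 flank: int = TRIGGER_FLANK,
                 backend: str = "auto") -> SirnaCluster:
    """Classify one accepted cluster as TAS-like, hpRNA, or other.

    ``trigger_small_rnas`` maps small-RNA ids to mature sequences (known and
    newly annotated miRNAs); a binding site at the miRNA cutoff inside the
    cluster +/- ``flank`` makes the cluster TAS-like.  Both polarities of
    the context are searched, since the trigger cleaves the precursor
    transcript, which may run on either strand.
    """
    locus = cluster.locus
    seq = genome[locus.chrom]
    lo = max(0, locus.start - flank)
    hi = min(len(seq), locus.end + flank)
    context = seq[lo:hi]
    from .seq import revcomp
    sites: list[TargetAlignment] = []
    for rid in sorted(trigger_small_rnas):
        srna = trigger_small_rnas[rid]
        for ctx_id, ctx in (("fwd", context), ("rev", revcomp(context))):
            sites.extend(find_target_sites(
                srna, {f"{locus.chrom}:{lo}-{hi}:{ctx_id}": ctx}, "miRNA",
                cutoff=cutoff, small_rna_id=rid))
    if sites:
        cluster.classification = "TAS-like"
        cluster.trigger_sites = sorted(
            sites, key=lambda a: (a.score, a.small_rna_id))[:5]
        return cluster
    if hpRNA_context_fold(cluster, genome, backend=backend) is not None:
        cluster.classification = "hpRNA"
    else:
        cluster.classification = "other"
    return cluster


def _context_stem(cluster: SirnaCluster, genome: dict[str, str], *,
                  context: int = HPRNA_CONTEXT, backend: str = "auto"):
    """Fold the locus context; return (context start, fold, arm intervals)
    when the fold carries a long dominant stem, else None."""
    locus = cluster.locus
    seq = genome[locus.chrom]
    lo = max(0, locus.start - context)
    hi = min(len(seq), locus.end + context)
    fr = fold(seq[lo:hi], backend=backend)
    arms = _hairpin_arms(fr)
    if arms is None:
        return None
    return lo, fr, arms


def hpRNA_context_fold(cluster: SirnaCluster, genome: dict[str, str], *,
                       context: int = HPRNA_CONTEXT,
                       backend: str = "auto") -> tuple[int, FoldResult] | None:
    """Long-stem criterion for classification: the context folds with >= 80
    paired stem nucleotides AND the cluster has reads on both arms."""
    ctx = _context_stem(cluster, genome, context=context, backend=backend)
    if ctx is None:
        return None
    lo, fr, ((a5s, a5e), (a3s, a3e)) = ctx
    on5 = any(a5s <= p.start - lo < a5e for p in cluster.locus.placements)
    on3 = any(a3s <= p.start - lo < a3e for p in cluster.locus.placements)
    if not (on5 and on3):
        return None
    return lo, fr


def summarize_hpRNA(cluster: SirnaCluster, genome: dict[str, str], *,
                    context: int = HPRNA_CONTEXT,
                    backend: str = "auto") -> HpRnaSummary:
    """Partition a hairpin locus's reads into 5'-arm / loop / 3'-arm.

    Reads are assigned by the midpoint of their placement relative to the
    folded context.  ``arm_ratio`` is 3'-arm over 5'-arm read counts (None
    when the 5' arm has no reads, e.g. all reads in the loop); the
    20-22-nt size-class fraction is computed over all reads in the cluster.
    """
    ctx = _context_stem(cluster, genome, context=context, backend=backend)
    if ctx is None:
        raise ValueError("locus context does not fold into a long stem")
    lo, fr, ((a5s, a5e), (a3s, a3e)) = ctx
    arm5 = arm3 = loop = 0
    size_20_22 = total = 0
    for p in cluster.locus.placements:
        mid = (p.start + p.end) // 2 - lo
        if mid < a5e:
            arm5 += p.count
        elif mid >= a3s:
            arm3 += p.count
        else:
            loop += p.count
        total += p.count
        if 20 <= p.length <= 22:
            size_20_22 += p.count
    ratio = arm3 / arm5 if arm5 else None
    return HpRnaSummary(cluster, arm5, arm3, loop, ratio,
                        size_20_22 / total if total else 0.0)
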