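"""Independent brute-force oracles and planting helpers shared by the
unit and acceptance suites.  Every oracle is written from the operation's
definition, not from the implementation it checks."""

from __future__ import annotations

from functools import lru_cache

from mossrna.alignment import Placement, GenomicLocus
from mossrna.preprocess import CleanRead
from mossrna.seq import random_dna, revcomp

WC = {"A": "T", "C": "G", "G": "C", "T": "A"}
RNA_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
             ("G", "U"), ("U", "G")}


def oracle_trim(read: str, adapter: str):
    """Exhaustive longest-substring adapter search: every (read offset,
    adapter offset) pair extended maximally; longest wins, leftmost read
    offset on ties; matches of 6 nt or less are not adapter evidence."""
    best_len, best_pos = 0, 0
    for i in range(len(read)):
        for j in range(len(adapter)):
            k = 0
            while (i + k < len(read) and j + k < len(adapter)
                   and read[i + k] == adapter[j + k]):
                k += 1
            if k > best_len:
                best_len, best_pos = k, i
    if best_len > 6:
        return read[:best_pos], True, best_len
    return read, False, best_len


def oracle_max_pairs(rna: str, min_loop: int = 3) -> int:
    """Maximum base pairing by an independent recursion (last base unpaired
    or paired with an admissible partner)."""

    @lru_cache(maxsize=None)
    def opt(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        best = opt(i, j - 1)
        for k in range(i, j - min_loop):
            if (rna[k], rna[j]) in RNA_PAIRS:
                cand = 1 + opt(i, k - 1) + opt(k + 1, j - 1)
                if cand > best:
                    best = cand
        return best

    result = opt(0, len(rna) - 1) if rna else 0
    opt.cache_clear()
    return result


def oracle_pair_penalty(sr_base: str, t_base: str) -> float:
    if WC[sr_base] == t_base:
        return 0.0
    if (sr_base, t_base) in (("G", "T"), ("T", "G")):
        return 0.5
    return 1.0


def oracle_weight(pos: int, mode: str) -> float:
    doubled = range(2, 14) if mode == "miRNA" else range(8, 14)
    return 2.0 if pos in doubled else 1.0


def oracle_best_score(small_rna: str, target: str, mode: str) -> float:
    """Enumerate every ungapped and single-internal-gap placement of the
    small RNA on the target and return the minimum score."""
    L = len(small_rna)
    best = float("inf")
    for s in range(len(target) - L + 1):
        site = target[s:s + L]
        score = sum(oracle_pair_penalty(small_rna[i - 1], site[L - i])
                    * oracle_weight(i, mode) for i in range(1, L + 1))
        best = min(best, score)
    for s in range(len(target) - (L - 1) + 1):
        site = target[s:s + L - 1]
        for g in range(2, L):
            score = oracle_weight(g, mode)
            t_idx = len(site) - 1
            for i in range(1, L + 1):
                if i == g:
                    continue
                score += oracle_pair_penalty(small_rna[i - 1], site[t_idx]) \
                    * oracle_weight(i, mode)
                t_idx -= 1
            best = min(best, score)
    return best


def oracle_partition(intervals, window):
    """O(n^2) transitive closure of the 'gap <= window' relation."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            if max(s1, s2) - min(e1, e2) <= window:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(intervals[i])
    return sorted(sorted(g) for g in groups.values())


def brute_force_placements(read: str, genome: str):
    hits = []
    rc = revcomp(read)
    for i in range(len(genome) - len(read) + 1):
        if genome[i:i + len(read)] == read:
            hits.append((i, "+"))
        if genome[i:i + len(read)] == rc:
            hits.append((i, "-"))
    return hits


# ---------------------------------------------------------------------------
# planting helpers
# ---------------------------------------------------------------------------

def plant_tas(rng, genome_len=8000, site_pos=3000, n_phases=6, per_phase=3):
    """A trigger binding site plus phased 21-nt reads downstream of the
    canonical cleavage position."""
    trigger = random_dna(rng, 21)
    genome = random_dna(rng, genome_len)
    site = revcomp(trigger)
    genome = genome[:site_pos] + site + genome[site_pos + 21:]
    cleave = site_pos + 21 - 1 - 9
    reads = []
    for k in range(n_phases):
        s = cleave + 21 * k
        reads.append(Placement(CleanRead(genome[s:s + 21], {"L1": per_phase}),
                               "chr1", s, s + 21, "+"))
    return {"chr1": genome}, trigger, reads, (site_pos, site_pos + 21)


def plant_hpRNA(rng, stem=180, loop=40, genome_len=10_000, pos=4000):
    """A long foldback: arm, loop, imperfect reverse-complement arm (one
    substitution per ~10 nt keeps reads arm-unique)."""
    arm5 = random_dna(rng, stem)
    arm3 = list(revcomp(arm5))
    for p in range(5, stem, 10):
        arm3[p] = "ACGT"[("ACGT".index(arm3[p]) + 1) % 4]
    hp = arm5 + random_dna(rng, loop) + "".join(arm3)
    genome = random_dna(rng, genome_len)
    genome = genome[:pos] + hp + genome[pos + len(hp):]
    return {"chr1": genome}, (pos, pos + stem), \
        (pos + stem + loop, pos + len(hp))


def sample_hp_reads(rng, genome, arm5, arm3, depth=1200, ratio=5.0,
                    length_probs=((20, 0.075), (21, 0.78), (22, 0.075),
                                  (24, 0.07))):
    lengths = [l for l, _ in length_probs]
    probs = [p for _, p in length_probs]
    p3 = ratio / (ratio + 1)
    counts: dict[tuple[int, int], int] = {}
    for _ in range(depth):
        arm = arm3 if rng.random() < p3 else arm5
        ln = int(rng.choice(lengths, p=probs))
        s = int(rng.integers(arm[0], arm[1] - ln))
        counts[(s, ln)] = counts.get((s, ln), 0) + 1
    return [Placement(CleanRead(genome["chr1"][s:s + ln], {"L1": c}),
                      "chr1", s, s + ln, "+")
            for (s, ln), c in sorted(counts.items())]
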