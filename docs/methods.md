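# Methods

This note documents the models and procedures implemented in `mossrna`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the choices made where the analysis recipe leaves
room for interpretation.

## Preprocessing

The 3′ adapter is located by an exhaustive longest-substring search: the
longest substring of the adapter occurring anywhere in the read marks the
adapter start, with ties broken by the leftmost occurrence in the read
(keeping the shortest insert is the conservative resolution; the choice
only matters for pathological repeats). A best match of 6 nt or less is
not accepted as adapter evidence — such reads are classed "no adapter"
and discarded, since an insert without an adapter was longer than the
sequencing read and its 3′ end is unknown.

"Low quality" is operationalized as mean Phred < 20 over the trimmed
insert (the classic recipe leaves the criterion unstated; mean-Q20 is
standard practice and the filter can be disabled by passing
`min_mean_quality=None`). Discard reasons apply in a fixed precedence —
no-adapter → quality → ambiguous → too-short — so each read is tallied
once and `kept + discarded = input` holds exactly.

Qualified inserts (≥ 17 nt, no N) are collapsed to unique sequences with
per-library counts. No maximum length is imposed; long inserts fall out
of downstream size-class filters naturally.

## Alignment and clustering

Reads are placed with zero mismatches on both strands; every occurrence
is reported and each placement records the genome-wide hit count of its
sequence. Multi-mapped reads are counted in full at every placement:
this keeps locus filters monotone in read support, and the hit count is
retained so stricter policies can be layered on top. Clustering is
single-linkage: placements join one locus when their gap is at most the
window (50 nt for siRNA clusters; 0 — i.e. overlap/adjacency — when
merging read stacks into miRNA loci). Loci are strand-separated for
miRNA discovery (hairpins are strand-specific) and strand-merged for
siRNA clustering (RdRP-derived loci accumulate both polarities).
Internally all coordinates are 0-based half-open; GFF3 output is 1-based
closed.

## miRNA discovery

Reads equal to a known mature sequence up to ±2-nt terminal trimming or
extension are reported as known-miRNA expression and excluded from novel
discovery — the same zero-mismatch regime as the alignment, allowing
only the 5′/3′-end heterogeneity seen in real libraries. The ±60-nt
neighbourhood of every known-mature placement is likewise excluded from
novel discovery: the star and isomiR reads of a known locus belong to
the known annotation, and left in the pool they can re-nucleate their
own precursor as a spurious "novel" call. Each remaining
locus is extended 300 nt on both sides and 250-nt windows are slid at a
25-nt step (the step is a free choice; 25 guarantees that any precursor
up to ~200 nt lies wholly inside at least one window). Loci whose total
support cannot reach the mature-count criterion are skipped before
folding; this cannot remove a true call because the criterion is a lower
bound on reads stacked within one window of one locus.

Each window is folded — ViennaRNA minimum free energy by default, or a
max-base-pairing Nussinov-style dynamic program (minimum loop 3) as a
deterministic, dependency-free test backend. The candidate mature is the
most abundant distinct read stacked in the window; reads whose ends both
lie within ±2 nt count toward the mature (isomiRs). Acceptance requires
all of:

1. **Support** — mature count strictly greater than 10 reads.
2. **Hairpin** — at least 60% of mature bases paired in the window fold,
   none within the mature itself; the partners define a duplex register
   `D = i + partner(i)` whose median locates the star arm. Additionally
   the mature + star reads must account for at least half of the
   window's read output. This dominance rule operationalizes
   "hairpin-derived": Dicer processing of a pre-miRNA yields
   essentially only the duplex strands, whereas long-hairpin (hpRNA)
   arms emit dispersed reads at many registers. Without it, any
   sufficiently deep hpRNA locus contains read stacks that satisfy the
   other three criteria by chance. The rule is monotone in mature depth.
3. **Star evidence** — the star interval is the mature's pairing region
   shifted so each strand's 3′ end overhangs by 2 nt; at least one
   sequenced read must match it within ±2 nt.
4. **Duplex geometry** — mature and star sequences, re-annealed as a free
   duplex over all antiparallel registers, must show 3′ overhangs of
   2 ± 1 nt on both ends (the ~2-nt geometry left by Dicer) and pair at
   ≥ 75% — the community duplex criterion of at most ~5 unpaired
   positions, deliberately stricter than the 60% fold-pairing floor of
   criterion 2 (two coincidentally phased 21-nt stacks can reach ~65%
   pairing, a genuine Dicer duplex essentially never falls below 75%).
   This check is independent of the genomic fold, so incidental pairing
   of overhang bases with loop or flank sequence cannot flip it.

Accepted windows describing the same mature (±2 nt) collapse to one
annotation; the best-paired duplex is kept.

## siRNA discovery

After removal of all reads aligned to miRNA loci (novel precursor
intervals, plus a ±60-nt precursor-scale neighbourhood around every
known-mature hit so star and isomiR reads leave with their locus),
clusters are filtered by two strict rules: at least 10 mapped reads, and
strictly more than 70% of mapped reads (count-weighted) exactly 21 nt
long. The two filters commute. Classification then proceeds:

* **TAS-like** — at least one trigger binding site (any known or newly
  annotated miRNA, scored in miRNA mode at cutoff 4) within the cluster
  ± 300 nt, searched on both context orientations since the cleaved
  precursor transcript may run on either strand.
* **hpRNA** — the cluster ± 500 nt folds with a dominant stem of ≥ 80
  paired nucleotides and the cluster has reads on both arms. The
  dominant stem is isolated by the modal pairing register (tolerance
  ±30 nt for bulges), which separates a long foldback from incidental
  pairing in random flanking sequence. The 80-pair floor sits well above
  miRNA-precursor stems (~20 pairs) and well below the 180/370-bp
  hairpins this class describes.
* **other** — neither.

The 21-nt phasing register fraction (dominant mod-21 class of 5′ ends)
is reported as a diagnostic only; the locus filter is deliberately the
stated two-criteria rule and nothing more. Transcript (cDNA) space is
searched with the same filters; a cDNA cluster sharing any read with an
accepted genomic cluster is treated as the same locus and dropped
(genome coordinates win), so only cDNA-exclusive clusters are added.

hpRNA summaries partition reads into 5′ arm / loop / 3′ arm by placement
midpoint against the folded context and report the 3′:5′ arm read ratio
(undefined, reported as null, when the 5′ arm is empty) and the
20–22-nt size-class fraction.

## Target prediction and degradome validation

Scoring follows the plant-standard penalty scheme over small-RNA
positions 1..L from the 5′ end: match 0, G:U wobble 0.5, mismatch 1,
gap 1; penalties at positions 2–13 are doubled in miRNA mode. siRNA
mode removes the doubling at positions 2–7 only (siRNAs need not obey
the miRNA seed rule), keeping 8–13 doubled; the exemption applies to all
penalty types. One single-nucleotide gap is allowed, modelled on the
small-RNA side (an internal small-RNA position aligned to nothing, so
the target footprint is L−1); terminal gaps are disallowed. Target-side
bulges are not modelled — the per-position state vector cannot represent
them — which is the one asymmetry against TargetFinder-style scoring.
Site scans are fully vectorized (penalty-matrix lookups over sliding
windows), return every placement at or below the cutoff, and sort by
score, transcript, position.

The canonical cleavage position is the target nucleotide opposite
small-RNA position 10. A predicted site is validated when the degradome
5′-end count within ±1 nt of that position is at least 5 raw reads and
no position inside the binding interval exceeds it; peaks are
categorized transcript-dominant / window-dominant / sub-peak. The
5-read floor and ±1-nt slop are configurable (the recipe requires only
"sufficient" reads). Cutoff 8 is intended for degradome-integrated runs;
cutoff 4 stands alone.

## Expression

RPM = count × 10⁶ / (genome-mapped qualified reads in the library);
mature and star are tallied separately, siRNA clusters as locus totals.
DE between (case, control) uses fold = (RPM_case + c)/(RPM_control + c)
with pseudocount c = 1 RPM, called when fold ≥ 2 or ≤ 0.5. No p-values
are computed — with single libraries per condition there is no
dispersion to estimate, and pure fold change is the honest statistic.
Note the boundary: a locus at exactly 2-fold falls just below the
threshold after pseudocounting ((2d+c)/(d+c) < 2), so boundary calls
appear only through sampling noise; `drop_zero_rows` selects the
alternative zero-handling.

## Synthetic data

The generator plants, on one random chromosome (default 200 kb):

* **miRNA precursors** — mature (21 nt) + 15-nt loop + star, where
  star = revcomp(mature[:-2]) + 2 free bases, so the free duplex anneals
  with exactly 2-nt 3′ overhangs on both ends; arms and strands
  alternate across loci. Mature depths decay geometrically from 150
  reads (floor 15) as a stand-in for the heavy-tailed abundance of real
  libraries; star depth is mature/8 (min 2). 21-nt matures co-test the
  21-nt siRNA rule: mature/star discrimination must not rest on length.
* **TAS-like loci** — a perfect trigger binding site, then 21-nt reads
  on the phase register set by the trigger's canonical cleavage
  position (site end − 9), 8 phases, 60 reads.
* **hpRNAs** — stems of 180 and 370 bp with one substitution per ~10 nt
  in the 3′ arm: highly annealed, but every ≥ 20-nt read maps to a
  single arm (a perfect inverted repeat would double-map every read and
  force an apparent arm ratio of 1 under full multi-map counting).
  Reads sample the arms 5:1 (3′:5′) at sizes 20/21/22/24 nt with
  probabilities 0.075/0.78/0.075/0.07 — the 20–22 class sums to 93%,
  21-heavy so the locus passes the strict >70% 21-nt filter, as the
  real loci this class models do.
* **Degradome profiles** — a pileup of 20 reads at each planted cleavage
  position over a uniform 0.2 reads/nt background (background alone
  stays below the 5-read peak floor in expectation).
* **Background** — 1000 uniform genomic 17–30-mers per library, emitted
  once each, so they exercise the ≥10-read filters as true negatives.
* **Conditions** — per-locus, per-condition depth multipliers (defaults
  2, 3.2 and 0.125 on three miRNA loci) with deterministic counts by
  default; `count_noise="poisson"` adds sampling noise. Reads carry the
  adapter suffix, Phred+33 "I" qualities, and an optional uniform
  substitution rate (off by default) to exercise the zero-mismatch
  filter.

Everything derives from a single seed (three independent substreams for
genome, reads, degradome); a fixed seed reproduces all outputs byte for
byte. Locus packing is deterministic-feasible: loci are laid out with
≥ 800-nt margins and random slack, failing explicitly when the genome
cannot hold them.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: base-quality error models, PCR duplication,
genomic repeat families (multi-mapping beyond the planted inverted
repeats), transcript splicing, partial adapter dimers, isomiR ladders
beyond exact reads, basal-to-loop processing gradients along hairpin
stems, and realistic library-size imbalance. Recovery rates of 100% on
synthetic data demonstrate the correctness of the filters' logic and
boundaries, not expected sensitivity on real libraries.

## Numerical and engineering choices

* Folding backends are deterministic; the max-pairing DP breaks ties
  toward leaving the 5′ base unpaired, and its traceback is validated
  against the matrix.
* Duplex annealing tries every antiparallel register and prefers (on
  equal pair counts) the register with overhangs closest to 2 nt.
* `candidate_windows` emits windows while they fit in the extended
  locus; an extension shorter than one window yields the whole region.
* Degenerate inputs are explicit: empty reads trim to empty, empty
  annotation sets yield empty tables, an all-loop hpRNA reports a null
  arm ratio, a missing degradome profile yields an unvalidated call with
  a "no-profile" category, zero library totals and infeasible packing
  raise.
* Problem sizes in the test and acceptance runs (500-kb genomes, 20
  precursors, ~1500-read hairpins, 20-seed DE replicates) were chosen as
  the smallest sizes at which the stochastic summaries are stable to
  well within their tolerance bands.

## Known limitations

* No conservation analysis, AGO/DCL assignment, methylation analysis,
  or translational-repression prediction.
* The exact-match placer is quadratic in the worst case (fine at
  synthetic scale); for genome-scale work, ingest SAM from an external
  zero-mismatch aligner instead.
* Known-miRNA matching needs mature sequences only; precursor
  coordinates, when available, would sharpen the ±60-nt locus-removal
  neighbourhood.
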