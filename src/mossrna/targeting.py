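"""Small-RNA target prediction and degradome validation.

Complementarity between a small RNA and a transcript is scored with the
plant-standard (Allen-style) penalty scheme: per small-RNA position, a
Watson-Crick match costs 0, a G:U wobble 0.5, a mismatch 1 and a
single-nucleotide gap 1.  Penalties inside the 5' "seed-extended" region
(small-RNA positions 2-13, counted from the 5' end) are doubled in miRNA
mode; siRNA mode exempts positions 2-7 from doubling (siRNAs need not obey
the miRNA seed rule) while keeping the doubling at 8-13.  Lower scores mean
better sites; the default reporting cutoff is 4, relaxed to 8 when degradome
evidence is required downstream.

A gap is modelled on the small-RNA side: one internal small-RNA position is
aligned to nothing, so the target footprint is one nucleotide shorter than
the small RNA.  At most one gap is allowed and terminal gaps are not.

Degradome (PARE) 5'-end profiles validate predicted sites: a small-RNA
guided cleavage leaves uncapped mRNA whose 5' end sits opposite small-RNA
positions 10/11, so a site is validated when the profile carries a
sufficiently tall 5'-end peak at that canonical position and the peak is the
maximum within the binding window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seq import encode

MATCH, WOBBLE, MISMATCH, GAP = "match", "wobble", "mismatch", "gap"

#: per-position penalty by state
PENALTY = {MATCH: 0.0, WOBBLE: 0.5, MISMATCH: 1.0, GAP: 1.0}

#: 1-based small-RNA positions whose penalties are doubled
DOUBLED_REGION = {"miRNA": range(2, 14), "siRNA": range(8, 14)}

DEFAULT_CUTOFF = 4.0
DEGRADOME_CUTOFF = 8.0
DEFAULT_MIN_DEGRADOME_READS = 5
DEFAULT_CLEAVAGE_SLOP = 1

# penalty lookup: rows = small-RNA base code, cols = target base code
# (both read 5'->3'; the small RNA anneals antiparallel to the target, so a
# match means the target base is the WC complement of the small-RNA base)
_PEN = np.ones((4, 4))
for _sr, _t in ((0, 3), (1, 2), (2, 1), (3, 0)):  # A:T C:G G:C T:A
    _PEN[_sr, _t] = 0.0
_PEN[2, 3] = 0.5  # G opposite U(T)
_PEN[3, 2] = 0.5  # U(T) opposite G
_STATE = np.full((4, 4), MISMATCH, dtype=object)
for _sr in range(4):
    for _t in range(4):
        if _PEN[_sr, _t] == 0.0:
            _STATE[_sr, _t] = MATCH
        elif _PEN[_sr, _t] == 0.5:
            _STATE[_sr, _t] = WOBBLE


@dataclass
class TargetAlignment:
    """One scored small-RNA/target site.

    ``target_interval`` is 1-based inclusive on the transcript; small-RNA
    position 1 (5' end) pairs with the last base of the interval.
    ``per_position_state`` runs over small-RNA positions 1..L (5'->3').
    """

    small_rna: str
    small_rna_id: str
    transcript_id: str
    target_interval: tuple[int, int]
    per_position_state: list[str]
    score: float
    mode: str
    gap_position: int | None = None  # 1-based small-RNA position, if any

    @property
    def symbols(self) -> str:
        """Serialize states 3'->5' on the small RNA (the printing convention
        that lays the query under the 5'->3' target): ':' match, '.' wobble,
        ' ' mismatch, '-' gap."""
        sym = {MATCH: ":", WOBBLE: ".", MISMATCH: " ", GAP: "-"}
        return "".join(sym[s] for s in reversed(self.per_position_state))

    def cleavage_position(self) -> int:
        """1-based transcript coordinate opposite small-RNA position 10."""
        return self._target_coord_of(10)

    def _target_coord_of(self, srna_pos: int) -> int:
        start, end = self.target_interval
        coord = end
        for pos in range(1, srna_pos + 1):
            if self.per_position_state[pos - 1] == GAP:
                continue
            here = coord
            coord -= 1
        return here


def position_weights(length: int, mode: str) -> np.ndarray:
    w = np.ones(length)
    for pos in DOUBLED_REGION[mode]:
        if pos <= length:
            w[pos - 1] = 2.0
    return w


def _states_ungapped(sr_codes: np.ndarray, window_codes: np.ndarray) -> list[str]:
    # window_codes 5'->3' on target; small-RNA pos i pairs window[-i]
    return [_STATE[sr_codes[i], window_codes[-(i + 1)]]
            for i in range(len(sr_codes))]


def score_states(states: Sequence[str], mode: str) -> float:
    w = position_weights(len(states), mode)
    return float(sum(PENALTY[s] * w[i] for i, s in enumerate(states)))


def best_alignment(small_rna: str, target: str, mode: str,
                   *, small_rna_id: str = "query",
                   transcript_id: str = "target",
                   max_gaps: int = 1) -> TargetAlignment | None:
    """Best-scoring placement of ``small_rna`` anywhere on ``target``.

    Considers every ungapped placement and, if ``max_gaps`` is 1, every
    placement with a single internal small-RNA gap.  Ties are broken by
    smaller end position, then ungapped before gapped.
    """
    sites = find_target_sites(small_rna, {transcript_id: target}, mode,
                              cutoff=float("inf"), small_rna_id=small_rna_id,
                              max_gaps=max_gaps)
    return sites[0] if sites else None


def _ungapped_scores(sr_codes, t_codes, weights):
    L = len(sr_codes)
    if len(t_codes) < L:
        return np.empty((0,)), 0
    win = np.lib.stride_tricks.sliding_window_view(t_codes, L)[:, ::-1]
    pen = _PEN[sr_codes[np.newaxis, :], win]
    return pen @ weights, win.shape[0]


def find_target_sites(small_rna: str, transcripts: dict[str, str], mode: str,
                      cutoff: float = DEFAULT_CUTOFF, *,
                      small_rna_id: str = "query",
                      max_gaps: int = 1) -> list[TargetAlignment]:
    """Scan transcripts for sites with score <= cutoff.

    Results are sorted ascending by score, ties by transcript id then site
    position.  Overlapping placements are all reported; callers interested in
    distinct sites typically keep the best per region.
    """
    if mode not in DOUBLED_REGION:
        raise ValueError(f"unknown scoring mode: {mode!r}")
    sr_codes = encode(small_rna)
    if (sr_codes < 0).any():
        raise ValueError("small RNA contains non-ACGT base")
    L = len(sr_codes)
    weights = position_weights(L, mode)
    out: list[TargetAlignment] = []
    for tid in sorted(transcripts):
        t_codes = encode(transcripts[tid].upper())
        tseq = transcripts[tid].upper()
        scores, n = _ungapped_scores(sr_codes, t_codes, weights)
        for s in np.nonzero(scores <= cutoff)[0]:
            states = _states_ungapped(sr_codes, t_codes[s:s + L])
            out.append(TargetAlignment(small_rna, small_rna_id, tid,
                                       (int(s) + 1, int(s) + L), states,
                                       float(scores[s]), mode))
        if max_gaps >= 1 and len(t_codes) >= L - 1:
            winlen = L - 1
            win = np.lib.stride_tricks.sliding_window_view(t_codes, winlen)[:, ::-1]
            # rev_win column c holds the target base opposite the c-th
            # small-RNA pairing position counted from the 5' end
            for g in range(2, L):  # 1-based gap position, internal only
                sr_wo_gap = np.concatenate([sr_codes[:g - 1], sr_codes[g:]])
                w_wo_gap = np.concatenate([weights[:g - 1], weights[g:]])
                pen = _PEN[sr_wo_gap[np.newaxis, :], win]
                gscores = pen @ w_wo_gap + PENALTY[GAP] * weights[g - 1]
                for s in np.nonzero(gscores <= cutoff)[0]:
                    wseq = t_codes[s:s + winlen]
                    states_wo = _states_ungapped(sr_wo_gap, wseq)
                    states = states_wo[:g - 1] + [GAP] + states_wo[g - 1:]
                    out.append(TargetAlignment(
                        small_rna, small_rna_id, tid,
                        (int(s) + 1, int(s) + winlen), states,
                        float(gscores[s]), mode, gap_position=g))
    out.sort(key=lambda a: (a.score, a.transcript_id, a.target_interval,
                            a.gap_position is not None, a.gap_position or 0))
    return out


def score_alignment(small_rna: str, target_window: str, mode: str,
                    **kw) -> TargetAlignment | None:
    """Score a small RNA against a candidate target window (best placement)."""
    return best_alignment(small_rna, target_window, mode, **kw)


# ---------------------------------------------------------------------------
# degradome integration
# ---------------------------------------------------------------------------

@dataclass
class DegradomeProfile:
    """Per-transcript 5'-end counts of uncapped-mRNA reads (1-based)."""

    transcript_id: str
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def library_size(self) -> int:
        return sum(self.counts.values())

    def max_count(self) -> int:
        return max(self.counts.values(), default=0)


@dataclass
class CleavageCall:
    alignment: TargetAlignment
    cleavage_position: int
    site_count: int
    peak_category: str  # dominant-on-transcript | dominant-in-window | sub-peak | no-profile
    validated: bool


def read_degradome_tsv(path) -> dict[str, DegradomeProfile]:
    """Read a (transcript_id, position_1based, count) TSV into profiles."""
    df = pd.read_csv(path, sep="\t")
    profiles: dict[str, DegradomeProfile] = {}
    for tid, sub in df.groupby("transcript_id"):
        profiles[str(tid)] = DegradomeProfile(
            str(tid), dict(zip(sub["position_1based"].astype(int),
                               sub["count"].astype(int))))
    return profiles


def write_degradome_tsv(profiles: dict[str, DegradomeProfile], path) -> None:
    rows = [(tid, pos, cnt)
            for tid in sorted(profiles)
            for pos, cnt in sorted(profiles[tid].counts.items())]
    pd.DataFrame(rows, columns=["transcript_id", "position_1based", "count"]
                 ).to_csv(path, sep="\t", index=False)


def validate_with_degradome(alignments: Iterable[TargetAlignment],
                            profiles: dict[str, DegradomeProfile], *,
                            min_reads: int = DEFAULT_MIN_DEGRADOME_READS,
                            slop: int = DEFAULT_CLEAVAGE_SLOP,
                            ) -> list[CleavageCall]:
    """Check each predicted site for a canonical cleavage 5'-end peak.

    ``site_count`` is the maximum profile count within ``slop`` nt of the
    canonical cleavage position.  A site is validated when site_count >=
    ``min_reads`` and no position inside the binding interval exceeds it.
    """
    calls = []
    for aln in alignments:
        cleave = aln.cleavage_position()
        profile = profiles.get(aln.transcript_id)
        if profile is None:
            calls.append(CleavageCall(aln, cleave, 0, "no-profile", False))
            continue
        site_count = max((profile.counts.get(cleave + d, 0)
                          for d in range(-slop, slop + 1)), default=0)
        lo, hi = aln.target_interval
        window_max = max((cnt for pos, cnt in profile.counts.items()
                          if lo <= pos <= hi), default=0)
        if site_count >= window_max and site_count >= profile.max_count():
            category = "dominant-on-transcript"
        elif site_count >= window_max:
            category = "dominant-in-window"
        else:
            category = "sub-peak"
        validated = site_count >= min_reads and site_count >= window_max
        calls.append(CleavageCall(aln, cleave, site_count, category, validated))
    return calls


def write_sites_tsv(alignments: Sequence[TargetAlignment], path) -> None:
    rows = [(a.small_rna_id, a.small_rna, a.transcript_id,
             f"{a.target_interval[0]}-{a.target_interval[1]}", a.score,
             a.mode, a.symbols) for a in alignments]
    pd.DataFrame(rows, columns=["small_rna_id", "small_rna", "transcript",
                                "range", "score", "mode", "alignment"]
                 ).to_csv(path, sep="\t", index=False)


def write_cleavage_tsv(calls: Sequence[CleavageCall], path) -> None:
    rows = [(c.alignment.small_rna_id, c.alignment.transcript_id,
             f"{c.alignment.target_interval[0]}-{c.alignment.target_interval[1]}",
             c.alignment.score, c.cleavage_position, c.site_count,
             c.peak_category, c.validated) for c in calls]
    pd.DataFrame(rows, columns=["small_rna_id", "transcript", "range", "score",
                                "cleavage_position", "site_count",
                                "peak_category", "validated"]
                 ).to_csv(path, sep="\t", index=False)
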