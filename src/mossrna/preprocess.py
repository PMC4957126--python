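"""Raw small-RNA read preprocessing.

Turns raw FASTQ reads into *qualified* reads: the 3' sequencing adapter is
located by the longest-substring rule, reads with no adapter evidence, low
mean base quality, ambiguous bases or a trimmed length below the minimum are
discarded, and the survivors are collapsed to unique sequences with
per-library counts.

The adapter rule: the longest substring of the adapter occurring anywhere in
the read marks the adapter start.  A read whose longest shared substring with
the adapter is 6 nt or shorter is considered to carry no adapter at all and
is left untouched (and subsequently discarded as unqualified).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

#: discard reasons in precedence order; a read failing several filters is
#: tallied once, under the first reason that applies.
DISCARD_REASONS = ("no_adapter", "low_quality", "ambiguous", "too_short")

MIN_ADAPTER_MATCH = 6  # matches of this length or shorter are not adapter evidence
DEFAULT_MIN_LENGTH = 17
DEFAULT_MIN_MEAN_QUALITY = 20.0


@dataclass
class RawRead:
    """One FASTQ record."""

    id: str
    sequence: str
    qualities: Sequence[int]
    library: str = ""


@dataclass
class TrimResult:
    trimmed_sequence: str
    adapter_found: bool
    matched_substring_length: int


@dataclass
class CleanRead:
    """A collapsed, adapter-trimmed small-RNA sequence with per-library counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


def trim_adapter(read_sequence: str, adapter: str,
                 min_match: int = MIN_ADAPTER_MATCH) -> TrimResult:
    """Locate and remove the 3' adapter by the longest-substring rule.

    Finds the longest substring of ``adapter`` occurring within the read; if
    that longest occurrence exceeds ``min_match`` nt the read is truncated at
    the start of the occurrence.  Ties on length are broken by the leftmost
    occurrence in the read.
    """
    if not read_sequence:
        return TrimResult("", False, 0)
    n = len(read_sequence)
    best_len = 0
    best_pos = 0
    # Longest adapter substring present in the read, leftmost on ties.
    # Scan lengths downward so the first hit at a length is final.
    for length in range(min(n, len(adapter)), 0, -1):
        if length <= best_len:
            break
        subs = {adapter[j:j + length] for j in range(len(adapter) - length + 1)}
        for i in range(n - length + 1):
            if read_sequence[i:i + length] in subs:
                best_len, best_pos = length, i
                break
        if best_len:
            break
    if best_len > min_match:
        return TrimResult(read_sequence[:best_pos], True, best_len)
    return TrimResult(read_sequence, False, best_len)


def read_fastq(path, library: str | None = None) -> Iterator[RawRead]:
    """Parse a Phred+33 FASTQ file into RawReads."""
    lib = library if library is not None else str(path)
    for rec in SeqIO.parse(str(path), "fastq"):
        yield RawRead(rec.id, str(rec.seq).upper(),
                      rec.letter_annotations["phred_quality"], lib)


def classify_read(read: RawRead, adapter: str, *, min_length: int = DEFAULT_MIN_LENGTH,
                  min_mean_quality: float | None = DEFAULT_MIN_MEAN_QUALITY,
                  min_match: int = MIN_ADAPTER_MATCH) -> tuple[str | None, str]:
    """Classify one raw read; returns (discard_reason | None, trimmed_sequence)."""
    trim = trim_adapter(read.sequence, adapter, min_match)
    if not trim.adapter_found:
        return "no_adapter", trim.trimmed_sequence
    insert = trim.trimmed_sequence
    if min_mean_quality is not None and read.qualities:
        quals = read.qualities[:len(insert)] if insert else read.qualities
        if quals and sum(quals) / len(quals) < min_mean_quality:
            return "low_quality", insert
    if any(b not in "ACGT" for b in insert):
        return "ambiguous", insert
    if len(insert) < min_length:
        return "too_short", insert
    return None, insert


def filter_qualified(reads: Iterable[RawRead], adapter: str, *,
                     min_length: int = DEFAULT_MIN_LENGTH,
                     min_mean_quality: float | None = DEFAULT_MIN_MEAN_QUALITY,
                     min_match: int = MIN_ADAPTER_MATCH,
                     ) -> tuple[list[CleanRead], dict[str, int]]:
    """Trim, filter and collapse a raw read stream.

    Returns the collapsed qualified reads (sorted by descending total count,
    then sequence, for determinism) and a tally of discarded reads by reason,
    first failing reason wins.  The tally also carries the number kept under
    the key ``"kept"`` so that kept + discarded equals the input count.
    """
    tally = {reason: 0 for reason in DISCARD_REASONS}
    tally["kept"] = 0
    collapsed: dict[str, dict[str, int]] = {}
    for read in reads:
        reason, insert = classify_read(
            read, adapter, min_length=min_length,
            min_mean_quality=min_mean_quality, min_match=min_match)
        if reason is not None:
            tally[reason] += 1
            continue
        tally["kept"] += 1
        libs = collapsed.setdefault(insert, {})
        libs[read.library] = libs.get(read.library, 0) + 1
    clean = [CleanRead(seq, counts) for seq, counts in collapsed.items()]
    clean.sort(key=lambda r: (-r.total_count, r.sequence))
    return clean, tally


def write_collapsed_fasta(clean_reads: Sequence[CleanRead], path) -> None:
    """Write collapsed reads as ``>seq<k>_x<total_count>`` FASTA."""
    with open(path, "w") as fh:
        for k, read in enumerate(clean_reads, start=1):
            fh.write(f">seq{k}_x{read.total_count}\n{read.sequence}\n")


def write_count_table(clean_reads: Sequence[CleanRead], path) -> None:
    libraries = sorted({lib for r in clean_reads for lib in r.counts})
    with open(path, "w") as fh:
        fh.write("sequence\t" + "\t".join(libraries) + "\n")
        for read in clean_reads:
            row = "\t".join(str(read.counts.get(lib, 0)) for lib in libraries)
            fh.write(f"{read.sequence}\t{row}\n")
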