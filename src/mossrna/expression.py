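"""Normalized expression tables and fold-change differential-expression calls.

Abundances are expressed as reads per million genome-mapped qualified reads
(RPM).  With single libraries per condition there is nothing to estimate a
dispersion from, so differential expression is pure fold change: a feature
is called DE between (case, control) when the pseudocounted RPM ratio is at
least 2 in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2
from typing import Mapping, Sequence

import pandas as pd

DEFAULT_PSEUDOCOUNT = 1.0   # in RPM units
DEFAULT_FOLD_THRESHOLD = 2.0


@dataclass
class DECall:
    id: str
    condition_pair: tuple[str, str]      # (case, control)
    log2_fold_change: float
    direction: str                       # {up, down}


def build_table(counts: Mapping[str, Mapping[str, float]],
                library_totals: Mapping[str, int]) -> pd.DataFrame:
    """RPM table from per-feature per-library raw counts.

    ``counts`` maps feature id -> {library -> raw count}; ``library_totals``
    are genome-mapped qualified-read totals per library.  Missing cells are
    zero.  Raises on a zero or missing library total.
    """
    libraries = sorted(library_totals)
    for lib in libraries:
        if library_totals[lib] <= 0:
            raise ValueError(f"library {lib!r} has non-positive mapped total")
    df = pd.DataFrame.from_dict(
        {fid: {lib: c.get(lib, 0) for lib in libraries}
         for fid, c in counts.items()},
        orient="index", columns=libraries, dtype=float)
    if df.empty:
        return pd.DataFrame(columns=libraries, dtype=float)
    for lib in libraries:
        df[lib] = df[lib] * 1e6 / library_totals[lib]
    return df.sort_index()


def call_de(table: pd.DataFrame, pairs: Sequence[tuple[str, str]], *,
            pseudocount: float = DEFAULT_PSEUDOCOUNT,
            fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
            drop_zero_rows: bool = False) -> list[DECall]:
    """Call >=2-fold differential expression for each (case, control) pair.

    fold = (RPM_case + c) / (RPM_control + c); DE when fold >= threshold or
    fold <= 1/threshold.  With ``drop_zero_rows`` features at zero RPM in
    both members of a pair are skipped instead of pseudocounted.
    """
    calls: list[DECall] = []
    for case, control in pairs:
        if case not in table.columns or control not in table.columns:
            raise KeyError(f"unknown condition in pair ({case}, {control})")
        for fid, row in table.iterrows():
            a, b = row[case], row[control]
            if drop_zero_rows and a == 0 and b == 0:
                continue
            fold = (a + pseudocount) / (b + pseudocount)
            if fold >= fold_threshold:
                calls.append(DECall(str(fid), (case, control), log2(fold), "up"))
            elif fold <= 1.0 / fold_threshold:
                calls.append(DECall(str(fid), (case, control), log2(fold), "down"))
    return calls


def de_calls_frame(calls: Sequence[DECall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.id, c.condition_pair[0], c.condition_pair[1],
          c.log2_fold_change, c.direction) for c in calls],
        columns=["id", "case", "control", "log2_fold_change", "direction"])
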