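"""Compare pipeline calls against planted ground truth.

Used on synthetic datasets: reports per-class precision/recall for miRNA
precursors, TAS-like loci and hpRNA loci, plus target-validation recall.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import gff


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and a[1] > b[0]


def _match_sets(truth_ivs, called_ivs):
    tp = sum(1 for t in truth_ivs if any(_overlaps(t, c) for c in called_ivs))
    fp = sum(1 for c in called_ivs if not any(_overlaps(c, t) for t in truth_ivs))
    return tp, fp


def _pr(tp: int, fp: int, n_truth: int) -> dict:
    return {
        "n_truth": n_truth,
        "n_called": tp + fp,
        "true_positives": tp,
        "precision": tp / (tp + fp) if tp + fp else None,
        "recall": tp / n_truth if n_truth else None,
    }


def evaluate_run(truth_dir, run_dir) -> dict:
    """Score a pipeline run directory against a simulated-truth directory."""
    truth_dir, run_dir = Path(truth_dir), Path(run_dir)
    truth_recs = gff.read_gff(truth_dir / "truth.gff3")
    report: dict = {}

    truth_mirna = [(r["start"], r["end"]) for r in truth_recs
                   if r["feature"] == "miRNA_primary_transcript"
                   and r["attributes"].get("known") != "true"]
    called_recs = gff.read_gff(run_dir / "mirna.gff3")
    called_mirna = [(r["start"], r["end"]) for r in called_recs
                    if r["feature"] == "miRNA_primary_transcript"]
    report["novel_mirna"] = _pr(*_match_sets(truth_mirna, called_mirna),
                                len(truth_mirna))

    sirna_recs = gff.read_gff(run_dir / "sirna.gff3") \
        if (run_dir / "sirna.gff3").exists() else []
    for feature, cls in (("tasiRNA_locus", "TAS-like"), ("hpRNA", "hpRNA")):
        truth_ivs = [(r["start"], r["end"]) for r in truth_recs
                     if r["feature"] == feature]
        called = [(r["start"], r["end"]) for r in sirna_recs
                  if r["attributes"].get("class") == cls
                  and r["chrom"].startswith("chr")]
        report[cls] = _pr(*_match_sets(truth_ivs, called), len(truth_ivs))

    events = pd.read_csv(truth_dir / "truth_targets.tsv", sep="\t")
    calls_path = run_dir / "cleavage_calls.tsv"
    validated = 0
    if calls_path.exists() and calls_path.stat().st_size:
        calls = pd.read_csv(calls_path, sep="\t")
        if not calls.empty:
            ok = calls[calls["validated"]]
            for _, ev in events.iterrows():
                hit = ok[(ok["transcript"] == ev["transcript_id"])
                         & (ok["cleavage_position"] - ev["cleavage_position"]).abs().le(1)]
                validated += int(len(hit) > 0)
    report["cleavage_events"] = {"n_truth": int(len(events)),
                                 "validated": validated,
                                 "recall": validated / len(events)
                                 if len(events) else None}
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
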