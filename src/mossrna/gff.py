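"""Minimal GFF3 writing for annotation output and planted-truth files.

Internal coordinates are 0-based half-open; GFF3 lines are 1-based closed.
"""

from __future__ import annotations

from typing import Iterable

SOURCE = "mossrna"


def gff_line(chrom: str, feature: str, start0: int, end0: int, strand: str,
             attributes: dict[str, str], score: str = ".") -> str:
    attrs = ";".join(f"{k}={v}" for k, v in attributes.items())
    return (f"{chrom}\t{SOURCE}\t{feature}\t{start0 + 1}\t{end0}\t{score}\t"
            f"{strand}\t.\t{attrs}")


def write_gff(path, lines: Iterable[str]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in lines:
            fh.write(line + "\n")


def write_mirna_gff(annotations, path) -> None:
    """miRNA annotations as miRNA_primary_transcript + miRNA features."""
    lines = []
    for k, ann in enumerate(annotations, start=1):
        name = getattr(ann, "name", "") or f"novel-miR{k}"
        lines.append(gff_line(ann.chrom, "miRNA_primary_transcript",
                              *ann.precursor, ann.strand,
                              {"ID": name, "status": ann.status}))
        lines.append(gff_line(ann.chrom, "miRNA", *ann.mature, ann.strand,
                              {"ID": f"{name}.mature",
                               "Parent": name,
                               "reads": str(ann.mature_count)}))
        lines.append(gff_line(ann.chrom, "miRNA_star", *ann.star, ann.strand,
                              {"ID": f"{name}.star",
                               "Parent": name,
                               "reads": str(ann.star_count)}))
    write_gff(path, lines)


def write_sirna_gff(clusters, path) -> None:
    lines = []
    for k, cl in enumerate(clusters, start=1):
        attrs = {"ID": f"sirna{k}",
                 "class": cl.classification,
                 "fraction_21nt": f"{cl.fraction_21nt:.3f}",
                 "total_count": str(cl.total_count),
                 "phase_register_fraction": f"{cl.phase_register_fraction:.3f}"}
        if cl.trigger_sites:
            attrs["trigger"] = cl.trigger_sites[0].small_rna_id
        lines.append(gff_line(cl.locus.chrom, "siRNA_locus",
                              cl.locus.start, cl.locus.end, ".", attrs))
    write_gff(path, lines)


def write_truth_gff(truth, path) -> None:
    lines = []
    for mt in truth.mirna_loci:
        lines.append(gff_line(mt.chrom, "miRNA_primary_transcript",
                              *mt.precursor, mt.strand,
                              {"ID": mt.locus_id,
                               "known": str(mt.known).lower()}))
        lines.append(gff_line(mt.chrom, "miRNA", *mt.mature, mt.strand,
                              {"ID": f"{mt.locus_id}.mature",
                               "Parent": mt.locus_id, "arm": mt.arm}))
        lines.append(gff_line(mt.chrom, "miRNA_star", *mt.star, mt.strand,
                              {"ID": f"{mt.locus_id}.star",
                               "Parent": mt.locus_id}))
    for tt in truth.tas_loci:
        lines.append(gff_line(tt.chrom, "tasiRNA_locus", *tt.interval, "+",
                              {"ID": tt.locus_id,
                               "trigger": tt.trigger_id,
                               "phase_offset": str(tt.phase_offset)}))
        lines.append(gff_line(tt.chrom, "trigger_site", *tt.trigger_site, "+",
                              {"ID": f"{tt.locus_id}.site",
                               "Parent": tt.locus_id}))
    for ht in truth.hpRNA_loci:
        lines.append(gff_line(ht.chrom, "hpRNA", *ht.interval, "+",
                              {"ID": ht.locus_id}))
    write_gff(path, lines)


def read_gff(path) -> list[dict]:
    """Parse a GFF3 file into dicts with 0-based half-open coordinates."""
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, source, feature, start, end, score, strand, frame, attrs = \
                line.rstrip("\n").split("\t")
            attributes = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
            records.append({"chrom": chrom, "feature": feature,
                            "start": int(start) - 1, "end": int(end),
                            "strand": strand, "attributes": attributes})
    return records
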