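"""Readers and writers for the plain-text interchange formats.

Internally all coordinates are 0-based half-open; BED output keeps that
convention, GFF3 output is 1-based inclusive as the format requires.
"""

from __future__ import annotations

import ast
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .events import ClipCluster, ClipRead, SpliceEvent


def write_genome_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_reads_fasta(reads: Iterable[str], path: str | Path, prefix: str = "r") -> None:
    records = [SeqRecord(Seq(r), id=f"{prefix}{i}", description="")
               for i, r in enumerate(reads)]
    SeqIO.write(records, str(path), "fasta")


def read_reads_fasta(path: str | Path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]


def write_annotation_gff3(annotation, path: str | Path) -> None:
    """Gene and region features as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for gene in annotation.genes:
        attrs = f"ID={gene.gene_id};utr_type={gene.utr_type}"
        lines.append("\t".join([
            gene.chrom, "spliceclip", "gene", str(gene.start + 1), str(gene.end),
            ".", gene.strand, ".", attrs,
        ]))
        for name, (s, e) in sorted(gene.regions.items(), key=lambda kv: kv[1]):
            lines.append("\t".join([
                gene.chrom, "spliceclip", "region", str(s + 1), str(e),
                ".", gene.strand, ".",
                f"ID={gene.gene_id}.{name};Parent={gene.gene_id};region={name}",
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation_gff3(path: str | Path):
    """Reconstruct gene models (regions, strand, UTR type) from GFF3.

    Returns :class:`~spliceclip.synthetic.GeneModel` objects; the synthetic
    truth and genome are not part of the annotation file.
    """
    from .synthetic import GeneModel

    genes: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, kind, start, end, _score, strand, _frame, attrs = line.split("\t")
        fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if kind == "gene":
            genes[fields["ID"]] = {
                "chrom": chrom, "strand": strand, "start": int(start) - 1,
                "end": int(end), "utr_type": fields.get("utr_type", "tandem"),
                "regions": {},
            }
        elif kind == "region":
            gid = fields["Parent"]
            genes[gid]["regions"][fields["region"]] = (int(start) - 1, int(end))
    out = []
    for gid, g in genes.items():
        sense = {}
        for name, (s, e) in g["regions"].items():
            if g["strand"] == "+":
                sense[name] = (s - g["start"], e - g["start"])
            else:
                sense[name] = (g["end"] - e, g["end"] - s)
        out.append(GeneModel(gid, g["chrom"], g["strand"], g["start"], g["end"],
                             g["utr_type"], g["regions"], sense))
    return out


def write_events_tsv(events: Sequence[SpliceEvent], path: str | Path) -> None:
    rows = []
    for ev in events:
        for name, (s, e) in ev.intervals.items():
            rows.append((ev.event_id, ev.event_class, ev.gene_id, ev.chrom,
                         ev.strand, name, s, e))
    pd.DataFrame(rows, columns=["event_id", "event_class", "gene_id", "chrom",
                                "strand", "interval", "start", "end"]
                 ).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[SpliceEvent]:
    df = pd.read_csv(path, sep="\t")
    events = []
    for (event_id, klass, gene_id, chrom, strand), grp in df.groupby(
            ["event_id", "event_class", "gene_id", "chrom", "strand"], sort=False):
        intervals = {r.interval: (int(r.start), int(r.end))
                     for r in grp.itertuples(index=False)}
        events.append(SpliceEvent(event_id, klass, gene_id, chrom, strand, intervals))
    return events


def write_clip_bed(
    reads: Sequence[ClipRead], bed_path: str | Path, sidecar_path: str | Path
) -> None:
    """Reads as BED6 plus a substitution sidecar TSV
    (read_id, offset, ref_base, read_base)."""
    bed_lines = []
    sub_rows = []
    for r in reads:
        bed_lines.append(f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id}\t0\t{r.strand}")
        for off, ref, alt in r.substitutions:
            sub_rows.append((r.read_id, off, ref, alt))
    Path(bed_path).write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))
    pd.DataFrame(sub_rows, columns=["read_id", "offset", "ref_base", "read_base"]
                 ).to_csv(sidecar_path, sep="\t", index=False)


def read_clip_bed(bed_path: str | Path, sidecar_path: str | Path) -> list[ClipRead]:
    subs: dict[str, list[tuple[int, str, str]]] = {}
    sc = pd.read_csv(sidecar_path, sep="\t")
    for rec in sc.itertuples(index=False):
        subs.setdefault(str(rec.read_id), []).append(
            (int(rec.offset), str(rec.ref_base), str(rec.read_base)))
    reads = []
    for line in Path(bed_path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, end, name, _score, strand = line.split("\t")
        reads.append(ClipRead(chrom, int(start), int(end), strand, name,
                              tuple(sorted(subs.get(name, [])))))
    return reads


def write_clusters_bed(clusters: Sequence[ClipCluster], path: str | Path) -> None:
    """Clusters as BED6 with the supporting read count in the score column."""
    lines = [
        f"{c.chrom}\t{c.start}\t{c.end}\tcluster{i}\t{c.read_count}\t{c.strand}"
        for i, c in enumerate(clusters)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_clusters_bed(path: str | Path) -> list[ClipCluster]:
    clusters = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, end, _name, score, strand = line.split("\t")
        clusters.append(ClipCluster(chrom, int(start), int(end), strand,
                                    int(score), 0))
    return clusters
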