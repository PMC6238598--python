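"""Readers and writers for the text formats the pipeline exchanges.

Coordinate conventions: everything in memory is 0-based half-open.
GTF is written/read 1-based closed; BED6 is 0-based half-open.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------- FASTA/FASTQ

def write_fasta(path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path, reads: Iterable) -> None:
    """Write reads with ``read_id``, ``sequence`` and integer ``quality`` attributes."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quality)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list:
    from .preprocess import RawRead

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(RawRead(read_id=rec.id, sequence=str(rec.seq),
                           quality=tuple(rec.letter_annotations["phred_quality"])))
    return out


# ------------------------------------------------------------------------ GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attrs(attr: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr))


def write_gtf(path, transcripts: Sequence) -> None:
    """Write TranscriptRecords as GTF (transcript + exon rows, 1-based closed)."""
    with open(path, "w") as fh:
        for t in transcripts:
            start, end = t.span
            attrs = (f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                     f'biotype "{t.biotype}"; source_tag "{t.source_tag}";')
            fh.write("\t".join([t.chrom, t.source_tag, "transcript", str(start + 1),
                                str(end), ".", t.strand, ".", attrs]) + "\n")
            for (es, ee) in t.exons:
                fh.write("\t".join([t.chrom, t.source_tag, "exon", str(es + 1),
                                    str(ee), ".", t.strand, ".", attrs]) + "\n")


def read_gtf(path) -> list:
    """Read exon rows of a GTF into TranscriptRecords (grouped by transcript_id)."""
    from .annotation import TranscriptRecord

    cols = ["chrom", "source", "feature", "start", "end", "score", "strand",
            "frame", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols,
                     dtype={"chrom": str})
    df = df[df["feature"] == "exon"]
    records: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        attrs = _parse_attrs(row.attributes)
        tid = attrs["transcript_id"]
        rec = records.setdefault(tid, {
            "transcript_id": tid,
            "gene_id": attrs.get("gene_id", tid),
            "chrom": row.chrom, "strand": row.strand,
            "biotype": attrs.get("biotype", "lincRNA"),
            "source_tag": attrs.get("source_tag", row.source),
            "exons": [],
        })
        rec["exons"].append((int(row.start) - 1, int(row.end)))
    out = []
    for rec in records.values():
        rec["exons"] = tuple(sorted(rec["exons"]))
        out.append(TranscriptRecord(**rec))
    return out


# ------------------------------------------------------------------------ BED

def write_bed6(path, intervals: Iterable[tuple]) -> None:
    """Intervals are (chrom, start, end, name, score, strand) tuples, 0-based half-open."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end = iv[0], iv[1], iv[2]
            name = iv[3] if len(iv) > 3 else "."
            score = iv[4] if len(iv) > 4 else 0
            strand = iv[5] if len(iv) > 5 else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed6(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]),
                        f[3] if len(f) > 3 else ".",
                        float(f[4]) if len(f) > 4 and f[4] != "." else 0.0,
                        f[5] if len(f) > 5 else "."))
    return out


# ------------------------------------------------------------------------ TSV

def write_tsv(path, df: pd.DataFrame, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
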