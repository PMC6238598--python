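"""TSS quality control, region partitioning, Mtr4:PolII ratios, metaplots.

Premature termination leaves a characteristic footprint: exosome-associated
(Mtr4 CRAC) fragments accumulate in the 1-kb "sense PROMPT" window
downstream of the TSS relative to elongating polymerase (NET-seq).  To
quantify this per gene, each candidate TSS first passes seven QC criteria
(peak support, NET-seq level, dominance among the gene's TSSes, absence of
stronger unannotated windows, sense/antisense RNA-seq asymmetry, no snoRNA
overlap, minimum transcript size); the transcript is then partitioned into
sense-PROMPT / antisense-PROMPT / exonic / intronic regions and read-count
ratios computed per region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import (Interval, TranscriptRecord, intersect_length,
                         merge_intervals)

logger = logging.getLogger(__name__)

CRITERIA = ("peak_within_500", "prompt_netseq_min", "strongest_tss",
            "no_stronger_window", "sense_rnaseq_ratio", "no_snorna_overlap",
            "min_transcript_size")


@dataclass
class TssRecord:
    gene_id: str
    transcript_id: str
    coordinate: int
    strand: str
    pass_flags: dict[str, bool]
    accepted: bool


@dataclass
class RegionSet:
    """Disjoint strand-aware regions for one accepted transcript."""

    gene_id: str
    chrom: str
    strand: str
    sense_prompt: Interval
    antisense_prompt: Interval
    exonic: tuple[Interval, ...]
    intronic: tuple[Interval, ...]


# ------------------------------------------------------------- read counting

def count_midpoints(reads: pd.DataFrame, chrom: str, start: int, end: int,
                    strand: Optional[str] = None) -> int:
    """Count reads whose midpoint falls in [start, end) on ``chrom``.

    ``reads`` columns: chrom, start, end, strand.  When ``strand`` is given
    only matching reads count.
    """
    sel = reads["chrom"] == chrom
    if strand is not None:
        sel &= reads["strand"] == strand
    mid = (reads["start"] + reads["end"]) // 2
    return int((sel & (mid >= start) & (mid < end)).sum())


# --------------------------------------------------------------------- QC

def qc_tss(
    candidates: Sequence[TranscriptRecord],
    peaks: Sequence[tuple],
    netseq: pd.DataFrame,
    rnaseq: pd.DataFrame,
    snornas: Sequence[tuple] = (),
    prompt_len: int = 1000,
    peak_max_dist: int = 500,
    min_prompt_netseq: int = 20,
    window_fold: float = 2.0,
    rnaseq_fold: float = 1.5,
    min_span: int = 2000,
    min_exonic: int = 1000,
    window_step: int = 100,
    min_coding_distance: Optional[float] = None,
    coding_distance: Optional[dict[str, float]] = None,
) -> list[TssRecord]:
    """Apply the seven primary-TSS criteria to each candidate transcript.

    Candidates sharing a ``gene_id`` compete under the dominance criterion.
    ``peaks``/``snornas`` are (chrom, start, end, ...) interval tuples.  An
    optional stringent extra predicate requires ``coding_distance[gene] >
    min_coding_distance`` when both are supplied.
    """
    peak_by_chrom: dict[str, list[Interval]] = {}
    for p in peaks:
        peak_by_chrom.setdefault(p[0], []).append((p[1], p[2]))
    sno_by_chrom: dict[str, list[Interval]] = {}
    for s in snornas:
        sno_by_chrom.setdefault(s[0], []).append((s[1], s[2]))

    prompt_counts = {
        t.transcript_id: count_midpoints(netseq, t.chrom, *_prompt_interval(t, prompt_len),
                                         strand=t.strand)
        for t in candidates
    }
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for t in candidates:
        by_gene.setdefault(t.gene_id, []).append(t)

    out = []
    for t in candidates:
        tss = t.tss
        flags: dict[str, bool] = {}

        # (i) H3K4me3 peak within 0.5 kb of the TSS
        dist = min((_point_interval_distance(tss, iv)
                    for iv in peak_by_chrom.get(t.chrom, ())), default=np.inf)
        flags["peak_within_500"] = dist <= peak_max_dist

        # (ii) moderate NET-seq signal in the sense PROMPT
        own = prompt_counts[t.transcript_id]
        flags["prompt_netseq_min"] = own >= min_prompt_netseq

        # (iii) strongest among the gene's TSSes
        others = [prompt_counts[o.transcript_id] for o in by_gene[t.gene_id]
                  if o.transcript_id != t.transcript_id and o.tss != tss]
        flags["strongest_tss"] = all(own > c for c in others)

        # (iv) no unannotated 1-kb window with > window_fold x the PROMPT signal
        flags["no_stronger_window"] = _no_stronger_window(
            t, by_gene[t.gene_id], netseq, own, prompt_len, window_fold, window_step)

        # (v) sense RNA-seq >= rnaseq_fold x upstream antisense RNA-seq (2 kb)
        opp = "-" if t.strand == "+" else "+"
        if t.strand == "+":
            sense = count_midpoints(rnaseq, t.chrom, tss, tss + 2000, strand="+")
            anti = count_midpoints(rnaseq, t.chrom, max(tss - 2000, 0), tss, strand=opp)
        else:
            sense = count_midpoints(rnaseq, t.chrom, max(tss - 1999, 0), tss + 1, strand="-")
            anti = count_midpoints(rnaseq, t.chrom, tss + 1, tss + 2001, strand=opp)
        flags["sense_rnaseq_ratio"] = sense >= rnaseq_fold * anti

        # (vi) no snoRNA overlap over the transcript span
        flags["no_snorna_overlap"] = intersect_length(
            [t.span], sno_by_chrom.get(t.chrom, ())) == 0

        # (vii) transcript > min_span nt with >= min_exonic exonic nt
        span_len = t.span[1] - t.span[0]
        flags["min_transcript_size"] = span_len > min_span and t.exonic_length >= min_exonic

        if min_coding_distance is not None and coding_distance is not None:
            flags["coding_distance"] = coding_distance.get(t.gene_id, np.inf) > min_coding_distance

        out.append(TssRecord(gene_id=t.gene_id, transcript_id=t.transcript_id,
                             coordinate=tss, strand=t.strand, pass_flags=flags,
                             accepted=all(flags.values())))
    return out


def _prompt_interval(t: TranscriptRecord, prompt_len: int) -> Interval:
    tss = t.tss
    if t.strand == "+":
        return (tss, tss + prompt_len)
    return (max(tss - prompt_len + 1, 0), tss + 1)


def _point_interval_distance(p: int, iv: Interval) -> float:
    if iv[0] <= p < iv[1]:
        return 0.0
    return float(min(abs(p - iv[0]), abs(p - (iv[1] - 1))))


def _no_stronger_window(t, gene_candidates, netseq, own_count, prompt_len,
                        fold, step) -> bool:
    """Scan 1-kb windows inside the gene span, skipping annotated PROMPTs."""
    span = (min(o.span[0] for o in gene_candidates),
            max(o.span[1] for o in gene_candidates))
    prompts = [_prompt_interval(o, prompt_len) for o in gene_candidates]
    for ws in range(span[0], max(span[0] + 1, span[1] - prompt_len + 1), step):
        win = (ws, ws + prompt_len)
        if any(win[0] < pe and ps < win[1] for ps, pe in prompts):
            continue
        c = count_midpoints(netseq, t.chrom, win[0], win[1], strand=t.strand)
        if c > fold * own_count:
            return False
    return True


# ---------------------------------------------------------------- partition

def partition_regions(tss: TssRecord, transcript: TranscriptRecord,
                      prompt_len: int = 1000) -> RegionSet:
    """Split the transcript into sense-PROMPT / antisense-PROMPT / exons / introns.

    Exonic (and intronic) intervals exclude any overlap with the sense
    PROMPT so the regions are disjoint.
    """
    sp = _prompt_interval(transcript, prompt_len)
    if transcript.strand == "+":
        ap = (max(tss.coordinate - prompt_len, 0), tss.coordinate)
    else:
        ap = (tss.coordinate + 1, tss.coordinate + 1 + prompt_len)
    exonic = _subtract(transcript.exons, sp)
    intronic = _subtract(transcript.introns, sp)
    return RegionSet(gene_id=transcript.gene_id, chrom=transcript.chrom,
                     strand=transcript.strand, sense_prompt=sp,
                     antisense_prompt=ap, exonic=exonic, intronic=intronic)


def _subtract(intervals: Sequence[Interval], cut: Interval) -> tuple[Interval, ...]:
    out = []
    for s, e in merge_intervals(intervals):
        if e <= cut[0] or s >= cut[1]:
            out.append((s, e))
            continue
        if s < cut[0]:
            out.append((s, cut[0]))
        if e > cut[1]:
            out.append((cut[1], e))
    return tuple(out)


# ------------------------------------------------------------------- ratios

REGIONS = ("sense_PROMPT", "antisense_PROMPT", "exon", "intron")


def count_in_regions(reads: pd.DataFrame, region_sets: Sequence[RegionSet],
                     dataset: str = "reads") -> pd.DataFrame:
    """Midpoint-and-strand counting of reads per gene region.

    Antisense-PROMPT regions count reads on the strand opposite the gene;
    all other regions count sense reads.  Returns a tidy frame with columns
    gene_id, region, count.
    """
    opposite = {"+": "-", "-": "+"}
    rows = []
    for rs in region_sets:
        for region, ivs, strand in (
            ("sense_PROMPT", (rs.sense_prompt,), rs.strand),
            ("antisense_PROMPT", (rs.antisense_prompt,), opposite[rs.strand]),
            ("exon", rs.exonic, rs.strand),
            ("intron", rs.intronic, rs.strand),
        ):
            n = sum(count_midpoints(reads, rs.chrom, s, e, strand=strand)
                    for s, e in ivs)
            rows.append({"gene_id": rs.gene_id, "region": region, "count": n})
    df = pd.DataFrame(rows)
    df["dataset"] = dataset
    return df


def compute_ratios(mtr4_counts: pd.DataFrame, netseq_counts: pd.DataFrame,
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """Per gene and region, ratio = (mtr4 + pc) / (netseq + pc).

    With ``pseudocount`` 0 a zero denominator yields a missing ratio rather
    than infinity.
    """
    m = mtr4_counts.rename(columns={"count": "mtr4_count"})[
        ["gene_id", "region", "mtr4_count"]]
    n = netseq_counts.rename(columns={"count": "netseq_count"})[
        ["gene_id", "region", "netseq_count"]]
    df = m.merge(n, on=["gene_id", "region"], how="inner")
    num = df["mtr4_count"] + pseudocount
    den = df["netseq_count"] + pseudocount
    df["ratio"] = np.where(den > 0, num / den, np.nan)
    return df


def compare_ratio_classes(ratios: pd.DataFrame, biotypes: pd.Series) -> pd.DataFrame:
    """Wilcoxon rank-sum lincRNA vs mRNA ratio comparison per region."""
    df = ratios.copy()
    df["biotype"] = df["gene_id"].map(biotypes)
    rows = []
    for region, grp in df.groupby("region"):
        linc = grp.loc[grp["biotype"] == "lincRNA", "ratio"].dropna()
        mrna = grp.loc[grp["biotype"] == "mRNA", "ratio"].dropna()
        if len(linc) and len(mrna):
            stat, p = stats.ranksums(linc, mrna)
        else:
            stat, p = np.nan, np.nan
        rows.append({"region": region, "n_lincRNA": len(linc), "n_mRNA": len(mrna),
                     "median_lincRNA": float(linc.median()) if len(linc) else np.nan,
                     "median_mRNA": float(mrna.median()) if len(mrna) else np.nan,
                     "statistic": stat, "p_value": p})
    return pd.DataFrame(rows).set_index("region")


# ----------------------------------------------------------------- metaplots

def choose_representative(transcripts: Sequence[TranscriptRecord],
                          seed: int = 0) -> list[TranscriptRecord]:
    """One transcript per gene: longest exonic, random tie-break under seed."""
    rng = np.random.default_rng(seed)
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    out = []
    for gid in sorted(by_gene):
        ts = by_gene[gid]
        best_len = max(t.exonic_length for t in ts)
        ties = sorted([t for t in ts if t.exonic_length == best_len],
                      key=lambda t: t.transcript_id)
        out.append(ties[int(rng.integers(len(ties)))] if len(ties) > 1 else ties[0])
    return out


def metaplot_exons(reads: pd.DataFrame, transcripts: Sequence[TranscriptRecord],
                   bin_size: int = 5, flank: int = 50,
                   n_exons: int = 3) -> pd.DataFrame:
    """Average max-normalised read-midpoint profile around exon boundaries.

    For each transcript, windows of ``+-flank`` nt (``bin_size``-nt bins)
    anchor at the start and end of the first ``n_exons`` exons and the last
    exon (strand-oriented).  Bin totals are divided by the transcript's
    maximum bin total and averaged across transcripts; transcripts with no
    reads in any bin are excluded (max-normalisation undefined, logged).
    """
    anchors_per_tx = []
    for t in transcripts:
        exons = t.exons if t.strand == "+" else tuple(reversed(t.exons))
        chosen = list(exons[:n_exons])
        if len(exons) > n_exons:
            chosen.append(exons[-1])
        anchors = []
        for s, e in chosen:
            if t.strand == "+":
                anchors.extend([("exon_start", s), ("exon_end", e - 1)])
            else:
                anchors.extend([("exon_start", e - 1), ("exon_end", s)])
        anchors_per_tx.append((t, anchors))

    n_bins = 2 * flank // bin_size
    profiles = []
    max_anchors = max((len(a) for _, a in anchors_per_tx), default=0)
    for t, anchors in anchors_per_tx:
        prof = np.full((max_anchors, n_bins), np.nan)
        for ai, (_, pos) in enumerate(anchors):
            prof[ai] = _binned_counts(reads, t.chrom, pos, t.strand, flank, bin_size)
        mx = np.nanmax(prof) if np.isfinite(prof).any() else 0
        if not mx > 0:
            logger.info("transcript %s has no reads in metaplot bins; excluded",
                        t.transcript_id)
            continue
        profiles.append(prof / mx)
    if not profiles:
        raise ValueError("no transcripts with signal for metaplot")
    mean_prof = np.nanmean(np.stack(profiles), axis=0)
    idx = [f"anchor{i}" for i in range(max_anchors)]
    cols = np.arange(-flank, flank, bin_size)
    return pd.DataFrame(mean_prof, index=idx, columns=cols)


def _binned_counts(reads, chrom, pos, strand, flank, bin_size,
                   read_strand="sense") -> np.ndarray:
    """Offsets are oriented by ``strand``; ``read_strand`` picks which reads
    count: "sense"/"antisense" relative to the anchor, or "both"."""
    sel = reads["chrom"] == chrom
    if read_strand == "sense":
        sel &= reads["strand"] == strand
    elif read_strand == "antisense":
        sel &= reads["strand"] != strand
    elif read_strand != "both":
        raise ValueError("read_strand must be sense, antisense or both")
    mid = ((reads["start"] + reads["end"]) // 2)[sel]
    offset = (mid - pos) if strand == "+" else (pos - mid)
    offset = offset[(offset >= -flank) & (offset < flank)]
    bins = ((offset + flank) // bin_size).astype(int)
    return np.bincount(bins, minlength=2 * flank // bin_size).astype(float)


def pileup_anchored(reads: pd.DataFrame, anchors: Sequence[tuple],
                    window: int = 2000, bin_size: int = 10,
                    normalize: bool = True,
                    read_strand: str = "both") -> pd.Series:
    """Read-midpoint pileup around anchor points.

    ``anchors`` are (chrom, position, strand) tuples; offsets are
    strand-oriented (negative = upstream of the anchor).  ``read_strand``
    selects the reads counted relative to the anchor orientation: "both"
    (default, e.g. nucleosome dyads) or "sense"/"antisense" (TSS plots).
    With ``normalize`` each anchor's bin vector is divided by its maximum
    before averaging (anchors with no reads are skipped); otherwise raw
    bin totals are summed.
    """
    half = window // 2
    n_bins = window // bin_size
    acc = np.zeros(n_bins)
    n_used = 0
    for chrom, pos, strand in anchors:
        v = _binned_counts(reads, chrom, pos, strand, half, bin_size,
                           read_strand=read_strand)
        if normalize:
            if v.max() <= 0:
                continue
            v = v / v.max()
        acc += v
        n_used += 1
    if normalize and n_used:
        acc /= n_used
    return pd.Series(acc, index=np.arange(-half, half, bin_size))
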