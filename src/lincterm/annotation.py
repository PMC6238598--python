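"""Merged lincRNA/mRNA catalogue construction and the quality-filter cascade.

Candidate lincRNA transcripts from several annotation sources are first
purged of anything overlapping protein-coding or classical noncoding genes
(either strand, full span), then overlapping survivors are merged into gene
clusters.  Each cluster is annotated with exonic length, repeat content,
distance to the nearest coding gene and normalised expression per kb, and
two boolean flags are derived: ``high_quality`` (the main catalogue filter)
and ``shortlist`` (a stricter candidate filter that additionally caps local
gene density).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Interval = tuple[int, int]  # 0-based half-open


# ----------------------------------------------------------- interval helpers

def merge_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Union of intervals as a sorted disjoint tuple."""
    ivs = sorted(intervals)
    if not ivs:
        return ()
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def intervals_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def intersect_length(a: Iterable[Interval], b: Iterable[Interval]) -> int:
    """Total nt shared between two interval sets."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    total = i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def spans_overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


# ------------------------------------------------------------------ datatypes

@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript from one annotation source.

    ``exons`` are sorted, non-overlapping, 0-based half-open intervals on
    ``chrom``; the TSS is the strand-aware 5' end of the first exon.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    biotype: str = "lincRNA"
    source_tag: str = "unknown"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.exons) == 0:
            raise ValueError("transcript needs at least one exon")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError("exons must be sorted and non-overlapping")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def tss(self) -> int:
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple((e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]))


@dataclass
class GeneCluster:
    """A merged transcription unit: connected component of overlapping transcripts."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    members: tuple[str, ...]
    merged_exons: tuple[Interval, ...]
    biotype: str = "lincRNA"
    exonic_length: int = 0
    repeat_fraction: float = 0.0
    distance_to_coding: float = np.inf
    expr_per_kb: Optional[np.ndarray] = None
    high_quality: Optional[bool] = None
    shortlist: Optional[bool] = None
    fail_reasons: tuple[str, ...] = ()

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class FilterThresholds:
    """Catalogue filter cut-offs; defaults are the main analysis settings.

    ``preset('results')`` returns the stricter expression preset
    (>10 reads/kb) used in some summaries.
    """

    min_exonic_nt: int = 1000
    max_repeat_fraction: float = 0.5
    min_coding_distance_nt: int = 5000
    min_expr_per_kb: float = 5.0
    cluster_span_cap_nt: int = 100_000
    shortlist_min_expr_per_kb: float = 30.0
    density_cap: int = 20          # genes per density window
    density_window_nt: int = 100_000

    def __post_init__(self):
        for f in ("min_exonic_nt", "max_repeat_fraction", "min_coding_distance_nt",
                  "min_expr_per_kb", "cluster_span_cap_nt",
                  "shortlist_min_expr_per_kb", "density_cap", "density_window_nt"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")

    @classmethod
    def preset(cls, name: str) -> "FilterThresholds":
        if name == "methods":
            return cls()
        if name == "results":
            return cls(min_expr_per_kb=10.0)
        raise ValueError(f"unknown preset {name!r}")


# ----------------------------------------------------------------- operations

def exclude_coding_overlaps(
    transcripts: Sequence[TranscriptRecord],
    coding_set: Sequence[TranscriptRecord],
    classical_ncrna_set: Sequence[TranscriptRecord] = (),
) -> list[TranscriptRecord]:
    """Drop candidates whose full span overlaps any exclusion-set transcript.

    Overlap is strand-blind and uses the whole transcript span (exons and
    introns), the conservative reading of overlap "in either orientation".
    Exclusion-set members on chromosomes absent from the candidates are
    ignored with a warning.
    """
    cand_chroms = {t.chrom for t in transcripts}
    by_chrom: dict[str, list[Interval]] = {}
    for t in list(coding_set) + list(classical_ncrna_set):
        if t.chrom not in cand_chroms:
            logger.warning("exclusion transcript %s on unknown chromosome %s ignored",
                           t.transcript_id, t.chrom)
            continue
        by_chrom.setdefault(t.chrom, []).append(t.span)
    merged = {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}
    kept = []
    for t in transcripts:
        excl = merged.get(t.chrom, ())
        if intersect_length([t.span], excl) == 0:
            kept.append(t)
    return kept


def cluster_into_genes(
    transcripts: Sequence[TranscriptRecord],
    span_cap: int = 100_000,
    ignore_strand: bool = False,
    gene_prefix: str = "LINC",
) -> list[GeneCluster]:
    """Merge span-overlapping transcripts into gene clusters.

    Clustering is strand-aware by default (antisense overlaps stay separate
    genes); clusters wider than ``span_cap`` are dropped as unresolvable
    regions.  Output order and content are invariant to input order.
    """
    groups: dict[tuple, list[TranscriptRecord]] = {}
    for t in transcripts:
        key = (t.chrom,) if ignore_strand else (t.chrom, t.strand)
        groups.setdefault(key, []).append(t)

    clusters: list[GeneCluster] = []
    for key in sorted(groups):
        ts = sorted(groups[key], key=lambda t: (t.span, t.transcript_id))
        # sweep: overlapping spans form connected components
        comp: list[TranscriptRecord] = []
        comp_end = -1
        comps: list[list[TranscriptRecord]] = []
        for t in ts:
            s, e = t.span
            if comp and s < comp_end:
                comp.append(t)
                comp_end = max(comp_end, e)
            else:
                if comp:
                    comps.append(comp)
                comp = [t]
                comp_end = e
        if comp:
            comps.append(comp)
        for members in comps:
            start = min(t.span[0] for t in members)
            end = max(t.span[1] for t in members)
            if end - start > span_cap:
                logger.info("cluster %s:%d-%d (%d nt) exceeds span cap %d; dropped "
                            "(genes cannot be distinguished)",
                            members[0].chrom, start, end, end - start, span_cap)
                continue
            merged_ex = merge_intervals([iv for t in members for iv in t.exons])
            biotypes = {t.biotype for t in members}
            clusters.append(GeneCluster(
                gene_id="",
                chrom=members[0].chrom,
                strand=members[0].strand if not ignore_strand else ".",
                start=start, end=end,
                members=tuple(sorted(t.transcript_id for t in members)),
                merged_exons=merged_ex,
                biotype=members[0].biotype if len(biotypes) == 1 else "mixed",
                exonic_length=intervals_length(merged_ex),
            ))
    clusters.sort(key=lambda c: (c.chrom, c.start, c.strand))
    for i, c in enumerate(clusters, 1):
        c.gene_id = f"{gene_prefix}{i:05d}"
    return clusters


def annotate_cluster_stats(
    cluster: GeneCluster,
    repeats: Sequence[Interval] | dict[str, Sequence[Interval]],
    coding_clusters: Sequence[GeneCluster],
    counts: Optional[pd.Series | np.ndarray] = None,
    size_factors: Optional[np.ndarray] = None,
) -> GeneCluster:
    """Fill exonic length, repeat fraction, coding distance and expression/kb.

    ``repeats`` may be a chrom->intervals mapping or intervals on the
    cluster's chromosome.  ``counts`` are raw per-sample counts for this
    cluster; expression per kb = count / size_factor * 1000 / exonic_length.
    """
    if isinstance(repeats, dict):
        repeats = repeats.get(cluster.chrom, ())
    exonic = intervals_length(cluster.merged_exons)
    if exonic == 0:
        raise ValueError(f"cluster {cluster.gene_id} has zero exonic length")
    rep_nt = intersect_length(cluster.merged_exons, repeats)

    dist = np.inf
    for other in coding_clusters:
        if other.chrom != cluster.chrom:
            continue
        if spans_overlap(cluster.span, other.span):
            dist = 0.0
            break
        gap = max(other.start - cluster.end, cluster.start - other.end)
        dist = min(dist, float(gap))

    expr = None
    if counts is not None:
        counts = np.asarray(counts, dtype=float)
        sf = np.ones_like(counts) if size_factors is None else np.asarray(size_factors, float)
        expr = counts / sf * 1000.0 / exonic

    cluster.exonic_length = exonic
    cluster.repeat_fraction = rep_nt / exonic
    cluster.distance_to_coding = dist
    cluster.expr_per_kb = expr
    return cluster


def flag_high_quality(
    clusters: Sequence[GeneCluster],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[GeneCluster]:
    """Apply the four catalogue filters; record per-cluster failure reasons.

    A cluster passes iff exonic length > min, repeat fraction < max,
    distance to coding > min, and max expression/kb over samples >= min.
    Idempotent: re-flagging flagged clusters gives identical results.
    """
    out = []
    for c in clusters:
        reasons = []
        if not c.exonic_length > thresholds.min_exonic_nt:
            reasons.append("exonic_length")
        if not c.repeat_fraction < thresholds.max_repeat_fraction:
            reasons.append("repeat_fraction")
        if not c.distance_to_coding > thresholds.min_coding_distance_nt:
            reasons.append("distance_to_coding")
        max_expr = float(np.max(c.expr_per_kb)) if c.expr_per_kb is not None else 0.0
        if not max_expr >= thresholds.min_expr_per_kb:
            reasons.append("expression")
        c = replace_fields(c, high_quality=not reasons, fail_reasons=tuple(reasons))
        out.append(c)
    return out


def shortlist(
    clusters: Sequence[GeneCluster],
    thresholds: FilterThresholds = FilterThresholds(),
    all_genes: Optional[Sequence[GeneCluster]] = None,
    low_coding_potential: Optional[dict[str, bool]] = None,
) -> list[GeneCluster]:
    """Stricter candidate filter on top of ``high_quality``.

    Requires expression above the shortlist threshold in >=1 sample, local
    gene density below ``density_cap`` genes in a ``density_window_nt``
    window centred on the cluster (density counted over ``all_genes``,
    defaulting to the clusters themselves), and, when provided, an external
    low-coding-potential call.
    """
    universe = list(all_genes) if all_genes is not None else list(clusters)
    mids: dict[str, np.ndarray] = {}
    for g in universe:
        mids.setdefault(g.chrom, [])
    by_chrom: dict[str, list[int]] = {}
    for g in universe:
        by_chrom.setdefault(g.chrom, []).append(g.midpoint)
    mids = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}

    half = thresholds.density_window_nt // 2
    out = []
    for c in clusters:
        ok = bool(c.high_quality)
        max_expr = float(np.max(c.expr_per_kb)) if c.expr_per_kb is not None else 0.0
        if not max_expr > thresholds.shortlist_min_expr_per_kb:
            ok = False
        m = mids.get(c.chrom, np.empty(0))
        n_in_window = int(np.searchsorted(m, c.midpoint + half, side="right")
                          - np.searchsorted(m, c.midpoint - half, side="left"))
        if n_in_window >= thresholds.density_cap:
            ok = False
        if low_coding_potential is not None and not low_coding_potential.get(c.gene_id, False):
            ok = False
        out.append(replace_fields(c, shortlist=ok))
    return out


def replace_fields(cluster: GeneCluster, **kw) -> GeneCluster:
    d = {f: getattr(cluster, f) for f in cluster.__dataclass_fields__}
    d.update(kw)
    return GeneCluster(**d)


def clusters_to_frame(clusters: Sequence[GeneCluster]) -> pd.DataFrame:
    """Tabular catalogue mirror with a high.quality.biotype-style column."""
    rows = []
    for c in clusters:
        hq = {True: f"{c.biotype}.high_quality", False: c.biotype, None: c.biotype}
        rows.append({
            "gene_id": c.gene_id, "chrom": c.chrom, "strand": c.strand,
            "start": c.start, "end": c.end, "biotype": c.biotype,
            "exonic_length": c.exonic_length,
            "repeat_fraction": c.repeat_fraction,
            "distance_to_coding": c.distance_to_coding,
            "max_expr_per_kb": (float(np.max(c.expr_per_kb))
                                if c.expr_per_kb is not None else np.nan),
            "high.quality.biotype": hq[c.high_quality],
            "high_quality": c.high_quality,
            "shortlist": c.shortlist,
            "fail_reasons": ",".join(c.fail_reasons),
        })
    return pd.DataFrame(rows).set_index("gene_id")
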