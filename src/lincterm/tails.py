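"""Non-genome-encoded 3' tail detection and termination 3'-end profiling.

The 5' portion of each cleaned read is aligned to the genome (exact-seed +
extend, both strands); whatever 3' suffix cannot be explained by the genome
is the candidate non-templated tail.  Reads explained better by a spliced
transcript than by the genome are excluded (their "tails" are exonic
sequence across a junction).  Oligo(A) events are selected, assigned to
sense-PROMPT / antisense-PROMPT / intron / exon regions, thinned to one
read per gene and region, and the genomic sequence context around their
3' ends summarised as a per-position base-composition profile.

Scoring: +1 per match, -2 per mismatch over the aligned prefix; a valid
alignment needs >= ``min_match`` aligned nt at >= ``min_identity``.  Ties
prefer the longer genomic extension, so a templated A adjacent to an A-tail
is counted as genomic and tails are the shortest consistent suffix (a known
+/-1 uncertainty on the 3' end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")

MATCH_SCORE = 1
MISMATCH_PENALTY = 2
BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PrefixAlignment:
    """Best genomic alignment of a read's 5' prefix.

    ``start``/``end`` delimit the genome-encoded portion (0-based
    half-open, reference coordinates); ``tail_seq`` is the unaligned 3'
    suffix of the read; ``spliced_score`` is the best score against the
    provided spliced-transcript sequences (-inf when none supplied).
    """

    read_id: str
    chrom: str
    strand: str
    start: int
    end: int
    matched_length: int
    score: float
    tail_seq: str
    spliced_score: float = float("-inf")

    @property
    def end_coord(self) -> int:
        """Reference position of the last genome-encoded (3'-most) base."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class TailEvent:
    read_id: str
    tail_seq: str
    chrom: str
    strand: str
    end_coord: int
    region_class: str = "other"
    intron_AG: Optional[bool] = None
    gene_id: str = ""


class GenomeIndex:
    """Exact k-mer index over both strands of a small genome."""

    def __init__(self, chrom_seqs: dict[str, str], k: int = 12):
        self.k = k
        self.chrom_seqs = chrom_seqs
        # oriented sequences: '+' is the reference, '-' its reverse complement
        self.oriented = {}
        for chrom, seq in chrom_seqs.items():
            self.oriented[(chrom, "+")] = seq
            self.oriented[(chrom, "-")] = revcomp(seq)
        self.index: dict[str, list[tuple[str, str, int]]] = {}
        for (chrom, strand), seq in sorted(self.oriented.items()):
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i:i + k], []).append((chrom, strand, i))

    def seed_hits(self, kmer: str):
        return self.index.get(kmer, ())


def _score_prefix(read: str, seq: str, pos: int, min_match: int,
                  min_identity: float) -> tuple[float, int]:
    """Best (score, prefix length) for the read laid on ``seq`` at ``pos``."""
    best_score, best_len = float("-inf"), 0
    matches = 0
    limit = min(len(read), len(seq) - pos)
    for j in range(limit):
        if read[j] == seq[pos + j]:
            matches += 1
        L = j + 1
        if L < min_match or matches < min_identity * L - 1e-9:
            continue
        score = matches * MATCH_SCORE - (L - matches) * MISMATCH_PENALTY
        # ties keep the shorter prefix: extending through a mismatch must
        # pay for itself, while exact extension always raises the score
        if score > best_score:
            best_score, best_len = score, L
    return best_score, best_len


def align_prefix(
    read_id: str,
    sequence: str,
    index: GenomeIndex,
    transcript_seqs: Optional[dict[str, str]] = None,
    min_match: int = 18,
    min_identity: float = 0.95,
    max_seeds: int = 4,
) -> Optional[PrefixAlignment]:
    """Seed-and-extend alignment of the read's 5' prefix to the genome.

    Seeds are consecutive k-mers from the read's 5' end (several, so one
    sequencing error cannot hide the locus).  Returns None (logged) when no
    placement reaches ``min_match`` nt at ``min_identity``.
    """
    k = index.k
    candidates: set[tuple[str, str, int]] = set()
    for s in range(max_seeds):
        off = s * k
        if off + k > len(sequence):
            break
        for chrom, strand, pos in index.seed_hits(sequence[off:off + k]):
            if pos - off >= 0:
                candidates.add((chrom, strand, pos - off))

    best: Optional[tuple[float, int, tuple]] = None
    for chrom, strand, pos in sorted(candidates):
        seq = index.oriented[(chrom, strand)]
        score, L = _score_prefix(sequence, seq, pos, min_match, min_identity)
        if L == 0:
            continue
        key = (score, -L, (chrom, strand, pos))
        if best is None or (key[0], key[1]) > (best[0], best[1]) or \
                ((key[0], key[1]) == (best[0], best[1]) and key[2] < best[2]):
            best = key
    if best is None:
        logger.info("read %s unmapped", read_id)
        return None
    score, negL, (chrom, strand, pos) = best
    L = -negL
    clen = len(index.chrom_seqs[chrom])
    if strand == "+":
        start, end = pos, pos + L
    else:
        start, end = clen - pos - L, clen - pos

    spliced = float("-inf")
    if transcript_seqs:
        for tseq in transcript_seqs.values():
            for oriented in (tseq, revcomp(tseq)):
                for p in _find_seed_positions(sequence, oriented, k, max_seeds):
                    s2, L2 = _score_prefix(sequence, oriented, p, min_match, min_identity)
                    if L2 and s2 > spliced:
                        spliced = s2

    return PrefixAlignment(read_id=read_id, chrom=chrom, strand=strand,
                           start=start, end=end, matched_length=L, score=score,
                           tail_seq=sequence[L:], spliced_score=spliced)


def _find_seed_positions(read: str, seq: str, k: int, max_seeds: int):
    positions = set()
    for s in range(max_seeds):
        off = s * k
        if off + k > len(read):
            break
        start = 0
        while True:
            p = seq.find(read[off:off + k], start)
            if p == -1:
                break
            if p - off >= 0:
                positions.add(p - off)
            start = p + 1
    return sorted(positions)


def align_prefix_bruteforce(
    read_id: str,
    sequence: str,
    chrom_seqs: dict[str, str],
    min_match: int = 18,
    min_identity: float = 0.95,
) -> Optional[PrefixAlignment]:
    """Exhaustive maximisation over all strands x positions x prefix lengths.

    Independent reference for :func:`align_prefix`: enumerates every
    (position, prefix length) pair on both strands with the same scoring
    and tie-break rules, no seeding.  Vectorised but still O(genome x
    read length) per read — small fixtures only.
    """
    best = None
    oriented = {}
    for chrom, seq in chrom_seqs.items():
        oriented[(chrom, "+")] = seq
        oriented[(chrom, "-")] = revcomp(seq)
    read_arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    m = len(read_arr)
    for (chrom, strand), seq in sorted(oriented.items()):
        s = np.frombuffer(seq.encode(), dtype=np.uint8)
        n = len(s)
        maxL = min(m, n)
        match = np.zeros((n, maxL), dtype=np.int16)
        for j in range(maxL):
            match[:n - j, j] = (s[j:] == read_arr[j])
        cum = match.cumsum(axis=1)
        Ls = np.arange(1, maxL + 1)
        score = (MATCH_SCORE + MISMATCH_PENALTY) * cum - MISMATCH_PENALTY * Ls
        valid = ((Ls >= min_match)
                 & (cum >= min_identity * Ls - 1e-9)
                 & (np.arange(n)[:, None] + Ls <= n))
        score = np.where(valid, score, np.iinfo(np.int32).min).astype(np.int64)
        top = int(score.max())
        if top == np.iinfo(np.int32).min:
            continue
        pos_idx, L_idx = np.nonzero(score == top)
        # tie-break: shortest prefix, then smallest position
        order = np.lexsort((pos_idx, L_idx))
        pos, L = int(pos_idx[order[0]]), int(L_idx[order[0]]) + 1
        key = (top, -L, (chrom, strand, pos))
        if best is None or (key[0], key[1]) > (best[0], best[1]) or \
                ((key[0], key[1]) == (best[0], best[1]) and key[2] < best[2]):
            best = key
    if best is None:
        return None
    score, negL, (chrom, strand, pos) = best
    L = -negL
    clen = len(chrom_seqs[chrom])
    if strand == "+":
        start, end = pos, pos + L
    else:
        start, end = clen - pos - L, clen - pos
    return PrefixAlignment(read_id=read_id, chrom=chrom, strand=strand,
                           start=start, end=end, matched_length=L, score=score,
                           tail_seq=sequence[L:])


# ----------------------------------------------------------------- tail calls

def call_tails(alignments: Iterable[Optional[PrefixAlignment]],
               min_tail: int = 0) -> list[TailEvent]:
    """One event per mapped read; reads better explained by a spliced
    transcript than by the genome are excluded."""
    events = []
    for aln in alignments:
        if aln is None:
            continue
        if aln.spliced_score > aln.score:
            continue
        if len(aln.tail_seq) < min_tail:
            continue
        events.append(TailEvent(read_id=aln.read_id, tail_seq=aln.tail_seq,
                                chrom=aln.chrom, strand=aln.strand,
                                end_coord=aln.end_coord))
    return events


def select_oligoA(events: Sequence[TailEvent], min_len: int = 2,
                  mode: str = "strict") -> list[TailEvent]:
    """Keep A-tailed events.

    ``strict``: tail is all A and >= min_len (homopolymeric oligo(A));
    ``lax``: >= min_len A's and >= 80% A content.
    """
    out = []
    for ev in events:
        t = ev.tail_seq
        if len(t) < min_len:
            continue
        if mode == "strict":
            ok = set(t) == {"A"}
        elif mode == "lax":
            ok = t.count("A") >= min_len and t.count("A") >= 0.8 * len(t)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if ok:
            out.append(ev)
    return out


def select_control_tails(events: Sequence[TailEvent], min_len: int = 2) -> list[TailEvent]:
    """Oligo(C/G/T) homopolymer tails — the negative-control set."""
    return [ev for ev in events
            if len(ev.tail_seq) >= min_len and len(set(ev.tail_seq)) == 1
            and ev.tail_seq[0] in "CGT"]


# -------------------------------------------------------------------- regions

@dataclass(frozen=True)
class GeneRegions:
    """Strand-aware region intervals for one gene (reference coordinates)."""

    gene_id: str
    chrom: str
    strand: str                  # gene strand
    sense_prompt: tuple[int, int]
    antisense_prompt: tuple[int, int]
    introns: tuple[tuple[int, int], ...]
    exons: tuple[tuple[int, int], ...]


def build_gene_regions(transcripts, chrom_lengths: dict[str, int],
                       prompt_len: int = 1000) -> list[GeneRegions]:
    """Derive per-gene region sets from transcript annotations.

    Sense PROMPT: ``prompt_len`` nt downstream of the TSS on the gene
    strand; antisense PROMPT: the same distance upstream, read on the
    opposite strand.  Both are clipped at chromosome edges (logged).
    """
    out = []
    for t in transcripts:
        clen = chrom_lengths[t.chrom]
        tss = t.tss
        if t.strand == "+":
            sp = (tss, min(tss + prompt_len, clen))
            ap = (max(tss - prompt_len, 0), tss)
        else:
            sp = (max(tss - prompt_len + 1, 0), tss + 1)
            ap = (tss + 1, min(tss + 1 + prompt_len, clen))
        if sp[1] - sp[0] < prompt_len or ap[1] - ap[0] < prompt_len:
            logger.info("PROMPT regions for %s clipped at chromosome edge", t.gene_id)
        out.append(GeneRegions(gene_id=t.gene_id, chrom=t.chrom, strand=t.strand,
                               sense_prompt=sp, antisense_prompt=ap,
                               introns=t.introns, exons=t.exons))
    return out


def assign_region(event: TailEvent, regions: Sequence[GeneRegions],
                  chrom_seqs: Optional[dict[str, str]] = None) -> TailEvent:
    """Classify the event's 3' end against gene region sets.

    Precedence sense_PROMPT > antisense_PROMPT > intron > exon; strand must
    match the region's orientation (antisense PROMPTs collect events on the
    strand opposite the gene).  Intron events are additionally flagged when
    the two genomic nt ending at the 3' end read "AG" in sense orientation.
    """
    pos = event.end_coord
    opposite = {"+": "-", "-": "+"}
    for want in ("sense_PROMPT", "antisense_PROMPT", "intron", "exon"):
        for g in regions:
            if g.chrom != event.chrom:
                continue
            if want == "sense_PROMPT":
                ivs, strand = (g.sense_prompt,), g.strand
            elif want == "antisense_PROMPT":
                ivs, strand = (g.antisense_prompt,), opposite[g.strand]
            elif want == "intron":
                ivs, strand = g.introns, g.strand
            else:
                ivs, strand = g.exons, g.strand
            if event.strand != strand:
                continue
            if any(s <= pos < e for s, e in ivs):
                ev = replace(event, region_class=want, gene_id=g.gene_id)
                if want == "intron" and chrom_seqs is not None:
                    ev = replace(ev, intron_AG=_ends_with_ag(ev, chrom_seqs))
                return ev
    return replace(event, region_class="other", gene_id="")


def _ends_with_ag(event: TailEvent, chrom_seqs: dict[str, str]) -> bool:
    seq = chrom_seqs[event.chrom]
    p = event.end_coord
    if event.strand == "+":
        if p < 1:
            return False
        return seq[p - 1:p + 1] == "AG"
    if p + 2 > len(seq):
        return False
    return revcomp(seq[p:p + 2]) == "AG"


def dedupe_per_gene(events: Sequence[TailEvent], seed: int = 0) -> list[TailEvent]:
    """One uniformly chosen event per (gene, region class); deterministic
    for a given seed."""
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, str], list[TailEvent]] = {}
    order: list[tuple[str, str]] = []
    for ev in events:
        key = (ev.gene_id, ev.region_class)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(ev)
    out = []
    for key in order:
        grp = groups[key]
        out.append(grp[int(rng.integers(len(grp)))] if len(grp) > 1 else grp[0])
    return out


# -------------------------------------------------------------------- profile

def nucleotide_profile(events: Sequence[TailEvent], chrom_seqs: dict[str, str],
                       window: int = 201) -> pd.DataFrame:
    """Average base composition of windows centred on event 3' ends.

    Returns a 4 x window frame (rows A,C,G,T; columns are offsets relative
    to the 3' end, strand-oriented so that positive offsets lie downstream
    in the read's direction).  Columns sum to 1.  Events whose window runs
    off the chromosome are dropped with a log message.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    half = window // 2
    counts = np.zeros((4, window), dtype=float)
    n_used = 0
    for ev in events:
        seq = chrom_seqs[ev.chrom]
        p = ev.end_coord
        if p - half < 0 or p + half + 1 > len(seq):
            logger.info("event %s at chromosome edge dropped from profile", ev.read_id)
            continue
        win = seq[p - half:p + half + 1]
        if ev.strand == "-":
            win = revcomp(win)
        for j, base in enumerate(win):
            i = BASES.find(base)
            if i >= 0:
                counts[i, j] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no events with full windows; empty profile")
    freq = counts / counts.sum(axis=0, keepdims=True)
    return pd.DataFrame(freq, index=list(BASES),
                        columns=np.arange(-half, half + 1))


def events_to_frame(events: Sequence[TailEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "read_id": ev.read_id, "gene_id": ev.gene_id, "chrom": ev.chrom,
        "strand": ev.strand, "end_coord": ev.end_coord,
        "tail_seq": ev.tail_seq, "tail_len": len(ev.tail_seq),
        "region_class": ev.region_class, "intron_AG": ev.intron_AG,
    } for ev in events])
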