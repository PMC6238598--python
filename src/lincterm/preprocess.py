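"""Read-cleaning cascade for CRAC and NET-seq libraries.

Stages, in pipeline order: (i) 3' adapter clipping, (ii) quality trimming
and filtering, (iii) PCR-duplicate collapse on the (UMI, sequence) pair,
(iv) low-complexity 3' trimming (CRAC only — oligo(A) tails otherwise cause
spurious unique mapping of repeat reads), (v) DUST-style low-complexity
read filtering.  A separate rule classifies aligned reads as repeat vs
nonrepeat from their per-index alignment scores.

All operations are pure; the pipeline driver conserves reads across the
accepted/rejected partition and logs per-stage counts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RawRead:
    """A sequencing read; ``umi`` is filled by :func:`extract_umi`."""

    read_id: str
    sequence: str
    quality: tuple[int, ...]
    umi: str = ""
    copies: int = 1  # PCR duplicates represented after collapse

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence and quality lengths differ")


@dataclass(frozen=True)
class AlignmentCandidate:
    """A scored alignment of one read against one index."""

    read_id: str
    index_tag: str  # genome | cDNA | repeat
    score: float
    locus: Optional[tuple] = None  # (chrom, start, end, strand)


@dataclass
class StageLog:
    stage: str
    n_in: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    reasons: Counter = field(default_factory=Counter)


# ----------------------------------------------------------------- operations

def clip_adapter(read: RawRead, adapter: str, min_match: int = 1,
                 mismatch_per_10nt: int = 1) -> tuple[RawRead, bool]:
    """Remove the longest read suffix matching an adapter prefix.

    A suffix of length L matches when it equals the first L nt of the
    adapter (L capped at the adapter length; longer suffixes must contain
    the full adapter) with at most ``mismatch_per_10nt`` mismatches per
    10 nt of overlap.  Only matches of >= ``min_match`` nt are clipped; the
    flag reports whether an adapter was found.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_match < 1:
        raise ValueError("min_match must be >= 1")
    seq = read.sequence
    n = len(seq)
    for start in range(max(0, n - len(adapter) - _max_extra(n, len(adapter))), n):
        overlap = min(n - start, len(adapter))
        if overlap < min_match:
            break
        allowed = (overlap // 10) * mismatch_per_10nt
        mism = sum(1 for a, b in zip(seq[start:start + overlap], adapter[:overlap])
                   if a != b)
        if mism <= allowed:
            clipped = replace(read, sequence=seq[:start], quality=read.quality[:start])
            return clipped, True
    return read, False


def _max_extra(read_len: int, adapter_len: int) -> int:
    # a clip point may sit anywhere; scan the whole read
    return read_len


def quality_filter(read: RawRead, trim_q: int = 25, min_q: int = 20,
                   min_frac: float = 0.90) -> tuple[Optional[RawRead], str]:
    """3' quality trimming then whole-read quality filtering.

    Trailing bases below ``trim_q`` are removed; the read is rejected when
    fewer than ``min_frac`` of the remaining bases reach ``min_q``, or when
    nothing remains.  Returns (read or None, reason).
    """
    qual = read.quality
    end = len(qual)
    while end > 0 and qual[end - 1] < trim_q:
        end -= 1
    if end == 0:
        return None, "trimmed_to_zero"
    trimmed = replace(read, sequence=read.sequence[:end], quality=qual[:end])
    frac = sum(1 for q in trimmed.quality if q >= min_q) / len(trimmed.quality)
    if frac < min_frac:
        return None, "quality_fraction"
    return trimmed, ""


def min_quality_filter(read: RawRead, min_q: int = 30) -> tuple[Optional[RawRead], str]:
    """Keep only reads where every position reaches ``min_q`` (tail branch)."""
    if all(q >= min_q for q in read.quality):
        return read, ""
    return None, "position_below_min_q"


def extract_umi(read: RawRead, umi_length: int = 5) -> Optional[RawRead]:
    """Move the 5' inline UMI from the sequence into the ``umi`` field."""
    if len(read.sequence) <= umi_length:
        return None
    return replace(read, umi=read.sequence[:umi_length],
                   sequence=read.sequence[umi_length:],
                   quality=read.quality[umi_length:])


def collapse_duplicates(reads: Sequence[RawRead]) -> list[RawRead]:
    """One representative per distinct (UMI, sequence) pair.

    The first occurrence survives with ``copies`` set to the duplicate
    count; order of first occurrence is preserved.
    """
    seen: dict[tuple[str, str], int] = {}
    reps: list[RawRead] = []
    for r in reads:
        key = (r.umi, r.sequence)
        if key in seen:
            i = seen[key]
            reps[i] = replace(reps[i], copies=reps[i].copies + 1)
        else:
            seen[key] = len(reps)
            reps.append(r)
    return reps


def trim_low_complexity_3p(read: RawRead, modal_frac: float = 0.8,
                           min_len: int = 18) -> tuple[Optional[RawRead], str]:
    """Iteratively strip 3' runs dominated by a single nucleotide.

    At each pass the longest suffix of length >= 2 whose modal base makes
    up >= ``modal_frac`` of the suffix is removed, until no suffix
    qualifies.  Reads shorter than ``min_len`` afterwards are rejected.
    """
    seq = read.sequence
    while True:
        cut = _longest_lc_suffix(seq, modal_frac)
        if cut == 0:
            break
        seq = seq[:len(seq) - cut]
    if len(seq) < min_len:
        return None, "low_complexity_min_len"
    if len(seq) == len(read.sequence):
        return read, ""
    return replace(read, sequence=seq, quality=read.quality[:len(seq)]), ""


def _longest_lc_suffix(seq: str, modal_frac: float) -> int:
    for L in range(len(seq), 1, -1):
        suffix = seq[len(seq) - L:]
        counts = Counter(suffix)
        if counts.most_common(1)[0][1] >= modal_frac * L:
            return L
    return 0


def dust_score(seq: str) -> float:
    """DUST-style 0-100 low-complexity score over overlapping 3-mers.

    100 for a homopolymer, near 0 for random sequence; reads scoring at or
    above the threshold (default 20, as for prinseq's dust filter) are
    treated as low complexity.
    """
    n = len(seq) - 2
    if n < 2:
        return 0.0
    counts = Counter(seq[i:i + 3] for i in range(n))
    raw = sum(c * (c - 1) / 2 for c in counts.values())
    return 100.0 * raw / (n * (n - 1) / 2)


def dust_filter(read: RawRead, threshold: float = 20.0,
                min_len: int = 18) -> tuple[Optional[RawRead], str]:
    if len(read.sequence) < min_len:
        return None, "min_len"
    if dust_score(read.sequence) >= threshold:
        return None, "dust"
    return read, ""


def classify_nonrepeat(candidates: Sequence[AlignmentCandidate]) -> str:
    """Label a read nonrepeat iff it maps strictly better to genome/cDNA.

    ``nonrepeat`` when max(genome, cDNA score) > max(repeat score); ties go
    to ``repeat``.  A read with no repeat-index candidate is nonrepeat; with
    no genome/cDNA candidate it is repeat.
    """
    if not candidates:
        raise ValueError("need at least one alignment candidate")
    best_gen = max((c.score for c in candidates if c.index_tag in ("genome", "cDNA")),
                   default=float("-inf"))
    best_rep = max((c.score for c in candidates if c.index_tag == "repeat"),
                   default=float("-inf"))
    if best_rep == float("-inf"):
        return "nonrepeat"
    return "nonrepeat" if best_gen > best_rep else "repeat"


# ------------------------------------------------------------------- pipeline

def preprocess_reads(
    reads: Sequence[RawRead],
    adapter: str,
    dataset: str = "CRAC",
    umi_length: int = 5,
    trim_q: int = 25,
    min_q: int = 20,
    min_frac: float = 0.90,
    dust_threshold: float = 20.0,
    min_len: int = 18,
) -> tuple[list[RawRead], list[tuple[str, str]], list[StageLog]]:
    """Run the full cleaning cascade; returns (accepted, rejected, stage logs).

    ``rejected`` holds (read_id, reason, copies) triples; ``copies`` > 1
    when a collapsed PCR-duplicate representative is rejected downstream.
    Read conservation holds at every stage: input reads = sum of copies over
    accepted + sum of copies over rejected.
    """
    logs: list[StageLog] = []
    rejected: list[tuple[str, str, int]] = []
    current = list(reads)

    # (i) adapter clipping (never rejects)
    log = StageLog("clip_adapter", n_in=len(current))
    clipped = []
    for r in current:
        c, found = clip_adapter(r, adapter, min_match=1)
        clipped.append(c)
        log.reasons["adapter_found" if found else "no_adapter"] += 1
    log.n_accepted = len(clipped)
    logs.append(log)
    current = clipped

    # (ii) quality trim + filter
    log = StageLog("quality_filter", n_in=len(current))
    kept = []
    for r in current:
        out, reason = quality_filter(r, trim_q, min_q, min_frac)
        if out is None:
            rejected.append((r.read_id, reason, r.copies))
            log.n_rejected += 1
            log.reasons[reason] += 1
        else:
            kept.append(out)
    log.n_accepted = len(kept)
    logs.append(log)
    current = kept

    # UMI extraction (part of stage iii bookkeeping)
    log = StageLog("extract_umi", n_in=len(current))
    kept = []
    for r in current:
        out = extract_umi(r, umi_length)
        if out is None:
            rejected.append((r.read_id, "too_short_for_umi", r.copies))
            log.n_rejected += 1
            log.reasons["too_short_for_umi"] += 1
        else:
            kept.append(out)
    log.n_accepted = len(kept)
    logs.append(log)
    current = kept

    # (iii) duplicate collapse
    log = StageLog("collapse_duplicates", n_in=len(current))
    collapsed = collapse_duplicates(current)
    log.n_accepted = len(collapsed)
    log.n_rejected = len(current) - len(collapsed)
    log.reasons["pcr_duplicate"] = log.n_rejected
    logs.append(log)
    current = collapsed

    # (iv) low-complexity 3' trimming — CRAC only
    if dataset.upper() == "CRAC":
        log = StageLog("trim_low_complexity_3p", n_in=len(current))
        kept = []
        for r in current:
            out, reason = trim_low_complexity_3p(r, min_len=min_len)
            if out is None:
                rejected.append((r.read_id, reason, r.copies))
                log.n_rejected += 1
                log.reasons[reason] += 1
            else:
                kept.append(out)
        log.n_accepted = len(kept)
        logs.append(log)
        current = kept

    # (v) DUST filter
    log = StageLog("dust_filter", n_in=len(current))
    kept = []
    for r in current:
        out, reason = dust_filter(r, dust_threshold, min_len)
        if out is None:
            rejected.append((r.read_id, reason, r.copies))
            log.n_rejected += 1
            log.reasons[reason] += 1
        else:
            kept.append(out)
    log.n_accepted = len(kept)
    logs.append(log)

    for lg in logs:
        logger.info("stage %-24s in=%d accepted=%d rejected=%d",
                    lg.stage, lg.n_in, lg.n_accepted, lg.n_rejected)
    return kept, rejected, logs


def preprocess_for_tails(
    reads: Sequence[RawRead],
    adapter: str,
    umi_length: int = 5,
    adapter_min_match: int = 7,
    min_q: int = 30,
    dust_threshold: float = 20.0,
    min_len: int = 18,
) -> tuple[list[RawRead], list[tuple[str, str]]]:
    """Stricter branch feeding the tail caller.

    Keeps only reads with a detectable 3' adapter (>= 7 nt), every position
    at Q>=30, passing the low-complexity filter; duplicates then collapsed
    on (UMI, sequence).
    """
    rejected: list[tuple[str, str]] = []
    kept: list[RawRead] = []
    for r in reads:
        clipped, found = clip_adapter(r, adapter, min_match=adapter_min_match)
        if not found:
            rejected.append((r.read_id, "no_adapter"))
            continue
        out, reason = min_quality_filter(clipped, min_q)
        if out is None:
            rejected.append((r.read_id, reason))
            continue
        out2 = extract_umi(out, umi_length)
        if out2 is None:
            rejected.append((r.read_id, "too_short_for_umi"))
            continue
        out3, reason = dust_filter(out2, dust_threshold, min_len)
        if out3 is None:
            rejected.append((r.read_id, reason))
            continue
        kept.append(out3)
    return collapse_duplicates(kept), rejected
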