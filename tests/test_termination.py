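"""TSS QC criteria, region partitioning, ratios and metaplots."""

import numpy as np
import pandas as pd
import pytest

from lincterm.annotation import TranscriptRecord, intervals_length
from lincterm.termination import (CRITERIA, choose_representative,
                                  compare_ratio_classes, compute_ratios,
                                  count_in_regions, count_midpoints,
                                  metaplot_exons, partition_regions,
                                  pileup_anchored, qc_tss)


def tx(tid, exons, strand="+", gene=None, chrom="c"):
    return TranscriptRecord(transcript_id=tid, gene_id=gene or tid.split(".")[0],
                            chrom=chrom, strand=strand, exons=tuple(exons),
                            biotype="mRNA")


def reads_at(positions, strand="+", chrom="c"):
    return pd.DataFrame([{"chrom": chrom, "start": int(p) - 10,
                          "end": int(p) + 10, "strand": strand}
                         for p in positions])


def scene():
    """A single fully compliant gene: every criterion passes."""
    cand = tx("g1.t1", [(10_000, 11_500), (12_500, 14_000)])
    peaks = [("c", 9_900, 10_300)]
    netseq = reads_at(np.linspace(10_100, 10_900, 50))
    rnaseq = pd.concat([reads_at(np.linspace(10_500, 11_800, 30)),
                        reads_at(np.linspace(8_500, 9_500, 10), strand="-")],
                       ignore_index=True)
    snornas = [("c", 500, 700)]
    return cand, peaks, netseq, rnaseq, snornas


class TestTssQc:
    def test_compliant_gene_accepted_with_all_flags(self):
        cand, peaks, netseq, rnaseq, snornas = scene()
        rec, = qc_tss([cand], peaks, netseq, rnaseq, snornas)
        assert rec.accepted and all(rec.pass_flags.values())
        assert set(rec.pass_flags) == set(CRITERIA)

    def test_peak_600nt_away_fails_only_criterion_i(self):
        cand, _, netseq, rnaseq, snornas = scene()
        rec, = qc_tss([cand], [("c", 10_600, 10_900)], netseq, rnaseq, snornas)
        assert not rec.accepted
        assert self._failed(rec) == {"peak_within_500"}

    def test_prompt_netseq_19_fails_only_criterion_ii(self):
        cand, peaks, _, rnaseq, snornas = scene()
        net19 = reads_at(np.linspace(10_100, 10_900, 19))
        rec, = qc_tss([cand], peaks, net19, rnaseq, snornas)
        assert self._failed(rec) == {"prompt_netseq_min"}
        net20 = reads_at(np.linspace(10_100, 10_900, 20))
        rec, = qc_tss([cand], peaks, net20, rnaseq, snornas)
        assert rec.accepted

    def test_weaker_tss_fails_only_criterion_iii(self):
        cand, peaks, netseq, rnaseq, snornas = scene()
        other = tx("g1.t2", [(12_000, 13_200), (13_800, 15_000)], gene="g1")
        peaks = peaks + [("c", 11_900, 12_300)]
        net = pd.concat([netseq, reads_at(np.linspace(12_100, 12_900, 120))],
                        ignore_index=True)
        rnaseq2 = pd.concat([rnaseq,
                             reads_at(np.linspace(12_100, 13_900, 40))],
                            ignore_index=True)
        recs = qc_tss([cand, other], peaks, net, rnaseq2, snornas)
        rec1 = next(r for r in recs if r.transcript_id == "g1.t1")
        assert self._failed(rec1) == {"strongest_tss"}

    def test_stronger_unannotated_window_fails_only_criterion_iv(self):
        cand, peaks, netseq, rnaseq, snornas = scene()
        net = pd.concat([netseq, reads_at(np.linspace(13_020, 13_980, 150))],
                        ignore_index=True)
        rec, = qc_tss([cand], peaks, net, rnaseq, snornas)
        assert self._failed(rec) == {"no_stronger_window"}

    def test_antisense_rnaseq_excess_fails_only_criterion_v(self):
        cand, peaks, netseq, _, snornas = scene()
        rnaseq = pd.concat([reads_at(np.linspace(10_500, 11_800, 30)),
                            reads_at(np.linspace(8_100, 9_900, 40), strand="-")],
                           ignore_index=True)
        rec, = qc_tss([cand], peaks, netseq, rnaseq, snornas)
        assert self._failed(rec) == {"sense_rnaseq_ratio"}

    def test_snorna_overlap_fails_only_criterion_vi(self):
        cand, peaks, netseq, rnaseq, _ = scene()
        rec, = qc_tss([cand], peaks, netseq, rnaseq, [("c", 13_000, 13_150)])
        assert self._failed(rec) == {"no_snorna_overlap"}

    def test_short_transcript_fails_only_criterion_vii(self):
        _, peaks, netseq, rnaseq, snornas = scene()
        short = tx("g1.t1", [(10_000, 10_800), (11_200, 11_900)])  # span 1900
        rec, = qc_tss([short], peaks, netseq, rnaseq, snornas)
        assert self._failed(rec) == {"min_transcript_size"}

    def test_monotone_in_prompt_signal(self):
        """Adding NET-seq reads to the sense PROMPT never flips an accepted
        TSS to rejected via criteria (ii)/(iii)."""
        cand, peaks, netseq, rnaseq, snornas = scene()
        rec, = qc_tss([cand], peaks, netseq, rnaseq, snornas)
        assert rec.accepted
        more = pd.concat([netseq, reads_at(np.linspace(10_050, 10_950, 200))],
                         ignore_index=True)
        rec2, = qc_tss([cand], peaks, more, rnaseq, snornas)
        assert rec2.pass_flags["prompt_netseq_min"]
        assert rec2.pass_flags["strongest_tss"]

    @staticmethod
    def _failed(rec):
        return {k for k, v in rec.pass_flags.items() if not v}


# ---------------------------------------------------------------- partition

def test_first_exon_overlap_subtracted_from_exonic():
    cand, peaks, netseq, rnaseq, snornas = scene()
    t = tx("g1.t1", [(10_000, 11_500), (12_500, 14_000)])
    rec, = qc_tss([t], peaks, netseq, rnaseq, snornas)
    rs = partition_regions(rec, t)
    assert rs.sense_prompt == (10_000, 11_000)
    assert rs.exonic[0] == (11_000, 11_500)  # exonic starts where the PROMPT ends
    assert rs.antisense_prompt == (9_000, 10_000)


def test_intronless_transcript_has_empty_intronic():
    t = tx("g1.t1", [(10_000, 13_000)])
    _, peaks, netseq, rnaseq, snornas = scene()
    rec, = qc_tss([t], peaks, netseq, rnaseq, snornas)
    rs = partition_regions(rec, t)
    assert rs.intronic == ()


def test_region_totals_equal_interval_arithmetic_oracle():
    rng = np.random.default_rng(23)
    _, peaks, netseq, rnaseq, snornas = scene()
    for trial in range(10):
        exons = []
        pos = 10_000
        for _ in range(int(rng.integers(1, 5))):
            pos += int(rng.integers(0, 800))
            L = int(rng.integers(300, 1200))
            exons.append((pos, pos + L))
            pos += L
        strand = "+" if rng.random() < 0.5 else "-"
        t = tx("g1.t1", exons, strand=strand)
        rec, = qc_tss([t], peaks, netseq, rnaseq, snornas)
        rs = partition_regions(rec, t)
        span_nt = t.span[1] - t.span[0]
        prompt_in_span = max(0, min(rs.sense_prompt[1], t.span[1])
                             - max(rs.sense_prompt[0], t.span[0]))
        total = (prompt_in_span + intervals_length(rs.exonic)
                 + intervals_length(rs.intronic))
        assert total == span_nt, (trial, exons, strand)


# ----------------------------------------------------------------- counting

def test_midpoint_counting_is_half_open_and_stranded():
    rs_reads = reads_at([999, 1000], strand="+")
    assert count_midpoints(rs_reads, "c", 0, 1000, "+") == 1
    assert count_midpoints(rs_reads, "c", 0, 1001, "+") == 2
    assert count_midpoints(rs_reads, "c", 0, 1001, "-") == 0


def test_antisense_prompt_counts_only_antisense_reads():
    cand, peaks, netseq, rnaseq, snornas = scene()
    rec, = qc_tss([cand], peaks, netseq, rnaseq, snornas)
    rs = partition_regions(rec, cand)
    sense_over_ap = reads_at([9_500], strand="+")
    anti_over_ap = reads_at([9_500], strand="-")
    c1 = count_in_regions(sense_over_ap, [rs])
    c2 = count_in_regions(anti_over_ap, [rs])
    ap1 = c1[c1["region"] == "antisense_PROMPT"]["count"].iloc[0]
    ap2 = c2[c2["region"] == "antisense_PROMPT"]["count"].iloc[0]
    assert ap1 == 0 and ap2 == 1


def test_counts_match_per_read_membership_oracle():
    rng = np.random.default_rng(3)
    cand, peaks, netseq, rnaseq, snornas = scene()
    rec, = qc_tss([cand], peaks, netseq, rnaseq, snornas)
    rs = partition_regions(rec, cand)
    pos = rng.integers(8_000, 15_000, 500)
    strands = np.where(rng.random(500) < 0.5, "+", "-")
    reads = pd.DataFrame({"chrom": "c", "start": pos - 10, "end": pos + 10,
                          "strand": strands})
    got = count_in_regions(reads, [rs]).set_index("region")["count"]
    opp = {"+": "-", "-": "+"}
    for region, ivs, strand in [
        ("sense_PROMPT", [rs.sense_prompt], rs.strand),
        ("antisense_PROMPT", [rs.antisense_prompt], opp[rs.strand]),
        ("exon", rs.exonic, rs.strand),
        ("intron", rs.intronic, rs.strand),
    ]:
        expect = sum(1 for p, s in zip(pos, strands)
                     if s == strand and any(a <= p < b for a, b in ivs))
        assert got[region] == expect, region


# ------------------------------------------------------------------- ratios

def test_ratio_arithmetic_and_zero_denominator():
    m = pd.DataFrame({"gene_id": ["g"], "region": ["exon"], "count": [50]})
    n = pd.DataFrame({"gene_id": ["g"], "region": ["exon"], "count": [25]})
    assert compute_ratios(m, n, pseudocount=0)["ratio"].iloc[0] == 2.0
    n0 = pd.DataFrame({"gene_id": ["g"], "region": ["exon"], "count": [0]})
    out = compute_ratios(m, n0, pseudocount=1)
    assert np.isfinite(out["ratio"].iloc[0])
    out0 = compute_ratios(m, n0, pseudocount=0)
    assert np.isnan(out0["ratio"].iloc[0])


def test_class_shift_detected_only_in_prompt_region():
    """Planted lincRNA-vs-mRNA shift in sense-PROMPT ratios is significant;
    matched exonic ratios are not."""
    rng = np.random.default_rng(11)
    rows_m, rows_n = [], []
    biotypes = {}
    for i in range(40):
        for bio, boost in (("lincRNA", 4.0), ("mRNA", 1.0)):
            g = f"{bio}_{i}"
            biotypes[g] = bio
            rows_m += [{"gene_id": g, "region": "sense_PROMPT",
                        "count": rng.poisson(25 * boost)},
                       {"gene_id": g, "region": "exon",
                        "count": rng.poisson(50)}]
            rows_n += [{"gene_id": g, "region": "sense_PROMPT",
                        "count": rng.poisson(25)},
                       {"gene_id": g, "region": "exon",
                        "count": rng.poisson(50)}]
    ratios = compute_ratios(pd.DataFrame(rows_m), pd.DataFrame(rows_n))
    res = compare_ratio_classes(ratios, pd.Series(biotypes))
    assert res.loc["sense_PROMPT", "p_value"] < 0.01
    assert res.loc["exon", "p_value"] > 0.05


# ---------------------------------------------------------------- metaplots

def test_metaplot_max_normalisation_and_average():
    t1 = tx("g1.t1", [(1_000, 1_100)])
    # one anchor window: reads in three bins with totals 2, 4, 8
    pos = [1_002] * 2 + [1_007] * 4 + [1_012] * 8
    reads = reads_at(pos)
    prof = metaplot_exons(reads, [t1], bin_size=5, flank=15)
    row = prof.loc["anchor0"]
    assert row[0] == pytest.approx(0.25)
    assert row[5] == pytest.approx(0.5)
    assert row[10] == pytest.approx(1.0)

    # two transcripts: the average halves the first transcript's bins
    t2 = tx("g2.t1", [(5_000, 5_100)], gene="g2")
    prof2 = metaplot_exons(reads, [t1, t2], bin_size=5, flank=15)
    # t2 has no reads -> excluded from the average entirely
    assert prof2.loc["anchor0", 10] == pytest.approx(1.0)

    reads3 = pd.concat([reads, reads_at([5_012] * 4)], ignore_index=True)
    prof3 = metaplot_exons(reads3, [t1, t2], bin_size=5, flank=15)
    assert prof3.loc["anchor0", 10] == pytest.approx((1.0 + 1.0) / 2)
    assert prof3.loc["anchor0", 0] == pytest.approx((0.25 + 0.0) / 2)


def test_metaplot_all_zero_raises():
    t1 = tx("g1.t1", [(1_000, 1_100)])
    with pytest.raises(ValueError):
        metaplot_exons(reads_at([50_000]), [t1])


def test_choose_representative_longest_exonic():
    a = tx("g1.t1", [(0, 1_000)])
    b = tx("g1.t2", [(0, 3_000)])
    rep, = choose_representative([a, b], seed=0)
    assert rep.transcript_id == "g1.t2"


def test_pileup_unit_peak_and_mirroring():
    reads = reads_at([5_000])
    prof = pileup_anchored(reads, [("c", 5_000, "+")], window=2_000, bin_size=10)
    assert prof[0] == 1.0 and prof.sum() == 1.0

    reads_off = reads_at([5_100])
    fwd = pileup_anchored(reads_off, [("c", 5_000, "+")], window=2_000, bin_size=10)
    rev = pileup_anchored(reads_off, [("c", 5_000, "-")], window=2_000, bin_size=10)
    assert fwd[100] == 1.0 and rev[-100] == 1.0


def test_pileup_planted_upstream_enrichment_appears_left_of_centre():
    rng = np.random.default_rng(2)
    anchors = [("c", int(p), "+") for p in rng.integers(10_000, 50_000, 30)]
    reads = reads_at(np.concatenate(
        [[p - 150 + rng.integers(-20, 20)] for _, p, _ in
         [(c, p, s) for c, p, s in anchors for _ in range(5)]]))
    prof = pileup_anchored(reads, anchors, window=2_000, bin_size=10,
                          normalize=False)
    assert prof.idxmax() < 0
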