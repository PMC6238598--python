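"""Seeded generators for every input the pipeline consumes.

A small multi-chromosome genome is generated with intron-containing mRNA
genes and lincRNA genes, repeat/snoRNA intervals, H3K4me3 peaks near
active TSSes and nucleosome dyads.  T-rich termination motifs are planted
immediately downstream of designated premature-termination sites, and
intron 3' ends carry the canonical AG.  On top of the genome the module
simulates: CRAC reads (inline 5' UMI + genomic body + optional
non-templated oligo(A) tail + 3' adapter), NET-seq occupancy with elevated
PROMPT density at termination-prone genes, an actinomycin-D decay time
course with constant spike-ins, single-cell negative-binomial counts with
subpopulations / jackpot genes / cis-co-expressed pairs, and clonal
perturbation lines with planted neighbour-gene effects and batch shifts.

Every generator is deterministic for a given config: the same
(config, seed) yields byte-identical outputs, and each emitted entity
appears exactly once in the returned ground-truth tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io
from .annotation import TranscriptRecord
from .preprocess import RawRead

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")

READ_CLASSES = ("sense_PROMPT", "antisense_PROMPT", "intron", "exon")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ------------------------------------------------------------------- configs

@dataclass(frozen=True)
class DecaySimConfig:
    halflife_range: tuple[float, float] = (30.0, 480.0)
    timepoints: tuple[int, ...] = (0, 30, 90, 240)
    include_mock: bool = True
    replicates: int = 2
    n0_range: tuple[float, float] = (200.0, 2000.0)
    n_spikes: int = 20
    spike_mean_range: tuple[float, float] = (60.0, 600.0)
    n_low_spikes: int = 2          # spikes below the mean-count floor
    depth_factor_range: tuple[float, float] = (0.5, 2.0)
    poisson_noise: bool = True

    def validate(self) -> None:
        if 0 not in self.timepoints or 240 not in self.timepoints:
            raise ValueError("timepoints must include 0 and 240")


@dataclass(frozen=True)
class ScSimConfig:
    n_cells: int = 200
    subpop_proportions: tuple[float, ...] = (1.0,)
    marker_fold: float = 4.0
    marker_fraction: float = 0.1
    dispersion: float = 0.2
    n_jackpot: int = 0
    jackpot_dispersion_mult: float = 5.0
    n_cis_pairs: int = 0
    cis_strength: float = 0.0
    cis_max_distance: float = 20_000.0
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    mean_range: tuple[float, float] = (1.0, 30.0)
    mapped_reads_mean: float = 1.5e6
    low_quality_fraction: float = 0.1
    mito_beta: tuple[float, float] = (2.0, 30.0)

    def validate(self) -> None:
        if abs(sum(self.subpop_proportions) - 1.0) > 1e-9:
            raise ValueError("subpopulation proportions must sum to 1")
        for p in self.subpop_proportions:
            if not 0 <= p <= 1:
                raise ValueError("proportions must be in [0, 1]")


@dataclass(frozen=True)
class PerturbSimConfig:
    n_control: int = 20
    lines_per_group: int = 4
    n_loci: int = 2
    neighbor_log2_effect: float = -1.0   # planted cis effect on nearest neighbour
    locus_log2_effect: float = -3.0      # knockdown of the targeted lincRNA itself
    n_affected_neighbors: int = 1
    neighbor_max_distance: float = 50_000.0
    n_batches: int = 2
    batch_log2_sd: float = 0.3
    noise_log2_sd: float = 0.2
    base_log2_mean: float = 8.0
    base_log2_sd: float = 1.5


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the synthetic study; defaults are the study conditions."""

    seed: int = 0
    # genome
    n_chroms: int = 3
    chrom_length: int = 200_000
    n_mrna: int = 30
    n_linc: int = 20
    intron_count_range: tuple[int, int] = (1, 3)       # mRNAs; lincRNAs use 0-1
    intron_length_range: tuple[int, int] = (300, 900)
    exon_length_range: tuple[int, int] = (200, 600)
    gene_gap_range: tuple[int, int] = (3000, 8000)
    margin: int = 2000
    prompt_len: int = 1000
    active_fraction: float = 0.8
    termination_fraction: float = 0.5   # of active genes
    term_site_offset: int = 300         # nt downstream of the TSS
    trich_window: int = 25
    trich_t_prob: float = 0.7
    n_repeats_per_chrom: int = 8
    repeat_length_range: tuple[int, int] = (500, 3000)
    n_snornas_per_chrom: int = 3
    snorna_length_range: tuple[int, int] = (100, 200)
    peak_halfwidth: int = 200
    nucleosome_spacing: int = 200
    # CRAC reads
    n_crac_reads: int = 5000
    class_weights: tuple[float, ...] = (0.3, 0.2, 0.25, 0.25)  # READ_CLASSES order
    tail_fraction: dict = field(default_factory=lambda: {
        "sense_PROMPT": 0.10, "antisense_PROMPT": 0.08,
        "intron": 0.05, "exon": 0.01})
    tail_mean: float = 3.0
    tail_max: int = 15
    error_rate: float = 0.0
    read_length_range: tuple[int, int] = (25, 60)
    umi_length: int = 5
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    base_quality: int = 38
    quality_decay_prob: float = 0.0     # per-base chance of a low-quality 3' run
    term_end_prob: float = 0.8          # sense-PROMPT reads ending at the term site
    intron_end_prob: float = 0.5        # intron reads ending exactly on the AG
    # NET-seq
    n_netseq_reads: int = 5000
    netseq_prompt_boost: float = 3.0    # PROMPT density multiplier, termination-prone
    inactive_weight: float = 0.1
    decay: DecaySimConfig = field(default_factory=DecaySimConfig)
    sc: ScSimConfig = field(default_factory=ScSimConfig)
    perturb: PerturbSimConfig = field(default_factory=PerturbSimConfig)

    def __post_init__(self):
        for name, frac in [("active_fraction", self.active_fraction),
                           ("termination_fraction", self.termination_fraction),
                           ("error_rate", self.error_rate)]:
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for cls, frac in self.tail_fraction.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"tail_fraction[{cls}] must be in [0, 1]")
        self.decay.validate()
        self.sc.validate()


# ------------------------------------------------------------------- fixture

@dataclass
class GenomeFixture:
    """Synthetic genome plus annotations and planted ground truth.

    ``genes`` is the truth table: one row per gene with its structure,
    activity, termination site, half-life and single-cell base mean.
    Interval lists are BED-like (chrom, start, end, name, score, strand).
    """

    config: SimulationConfig
    chrom_names: list[str]
    chrom_seqs: dict[str, str]
    transcripts: list[TranscriptRecord]
    repeats: list[tuple]
    snornas: list[tuple]
    peaks: list[tuple]
    nucleosomes: list[tuple]        # (chrom, dyad_pos, strand)
    genes: pd.DataFrame
    structures: dict = field(default_factory=dict)  # gene -> sense-local exon/intron intervals

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chrom_seqs.items()}

    def validate(self) -> None:
        lengths = self.chrom_lengths
        for t in self.transcripts:
            s, e = t.span
            assert 0 <= s < e <= lengths[t.chrom], f"{t.transcript_id} out of bounds"
        for ivs in (self.repeats, self.snornas, self.peaks):
            for iv in ivs:
                assert 0 <= iv[1] < iv[2] <= lengths[iv[0]]
        assert self.genes.index.is_unique

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(outdir / "genome.fa", self.chrom_seqs)
        io.write_gtf(outdir / "annotations.gtf", self.transcripts)
        io.write_bed6(outdir / "repeats.bed", self.repeats)
        io.write_bed6(outdir / "snornas.bed", self.snornas)
        io.write_bed6(outdir / "peaks.bed", self.peaks)
        io.write_bed6(outdir / "nucleosomes.bed",
                      [(c, p, p + 1, "dyad", 0, s) for c, p, s in self.nucleosomes])
        io.write_tsv(outdir / "genes_truth.tsv", self.genes)


# -------------------------------------------------------------- genome build

def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def make_genome(config: SimulationConfig) -> GenomeFixture:
    """Generate the genome, annotations and per-gene ground truth."""
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    seqs = {c: _random_seq(rng, config.chrom_length) for c in chrom_names}

    n_genes = config.n_mrna + config.n_linc
    biotypes = ["mRNA"] * config.n_mrna + ["lincRNA"] * config.n_linc
    rng.shuffle(biotypes)
    per_chrom = np.array_split(np.arange(n_genes), config.n_chroms)

    transcripts: list[TranscriptRecord] = []
    rows = []
    structures: dict[str, dict] = {}
    repeats, snornas, peaks, nucleosomes = [], [], [], []
    gi = 0
    for ci, chrom in enumerate(chrom_names):
        cursor = config.margin
        for _ in per_chrom[ci]:
            biotype = biotypes[gi]
            strand = "+" if rng.random() < 0.5 else "-"
            cursor += int(rng.integers(*config.gene_gap_range))
            exons_local, introns_local = _gene_structure(rng, config, biotype)
            span = exons_local[-1][1]
            if cursor + span > config.chrom_length - config.margin:
                raise ValueError(
                    f"chromosome {chrom} too short for requested gene count; "
                    f"increase chrom_length or reduce genes")
            gid = f"G{gi + 1:04d}"
            tid = f"{gid}.1"
            structures[gid] = {"exons": exons_local, "introns": introns_local,
                               "span": span}
            gstart, gend = cursor, cursor + span
            exons_ref = _map_intervals(exons_local, gstart, gend, strand)
            transcripts.append(TranscriptRecord(
                transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
                exons=exons_ref, biotype=biotype, source_tag="synthetic"))
            tss = gstart if strand == "+" else gend - 1

            active = rng.random() < config.active_fraction
            term = active and rng.random() < config.termination_fraction
            term_local = config.term_site_offset
            term_ref = _map_point(term_local, gstart, gend, strand)
            # plant AG at each intron 3' end (sense orientation)
            for (is_, ie_) in introns_local:
                _plant(seqs[chrom], "AG", (ie_ - 2, ie_), gstart, gend, strand)
            if term:
                # T-rich motif just downstream of the premature 3' end
                motif = "".join("T" if rng.random() < config.trich_t_prob
                                else str(BASES[rng.integers(0, 4)])
                                for _ in range(config.trich_window))
                _plant(seqs[chrom], "T" + motif,
                       (term_local + 1, term_local + 2 + config.trich_window),
                       gstart, gend, strand)
            if active:
                centre = tss + int(rng.integers(-300, 301))
                peaks.append((chrom, max(0, centre - config.peak_halfwidth),
                              min(config.chrom_length, centre + config.peak_halfwidth),
                              f"peak_{gid}", 0, "."))
            if biotype == "mRNA":
                for d in range(100, min(span, 2000), config.nucleosome_spacing):
                    nucleosomes.append((chrom, _map_point(d, gstart, gend, strand),
                                        strand))
            rows.append({
                "gene_id": gid, "transcript_id": tid, "chrom": chrom,
                "strand": strand, "start": gstart, "end": gend, "tss": tss,
                "biotype": biotype, "n_introns": len(introns_local),
                "active": active, "termination_prone": term,
                "term_site": term_ref if term else -1,
                "halflife": float(np.exp(rng.uniform(
                    np.log(config.decay.halflife_range[0]),
                    np.log(config.decay.halflife_range[1])))),
                "sc_mean": float(np.exp(rng.uniform(
                    np.log(config.sc.mean_range[0]),
                    np.log(config.sc.mean_range[1])))),
            })
            cursor = gend
            gi += 1
        for _ in range(config.n_repeats_per_chrom):
            L = int(rng.integers(*config.repeat_length_range))
            s = int(rng.integers(0, config.chrom_length - L))
            repeats.append((chrom, s, s + L, "repeat", 0, "."))
        for _ in range(config.n_snornas_per_chrom):
            L = int(rng.integers(*config.snorna_length_range))
            s = int(rng.integers(0, config.chrom_length - L))
            snornas.append((chrom, s, s + L, "snoRNA", 0,
                            "+" if rng.random() < 0.5 else "-"))

    fixture = GenomeFixture(
        config=config, chrom_names=chrom_names,
        chrom_seqs={c: "".join(s) for c, s in seqs.items()},
        transcripts=transcripts, repeats=repeats, snornas=snornas,
        peaks=peaks, nucleosomes=nucleosomes,
        genes=pd.DataFrame(rows).set_index("gene_id"),
        structures=structures)
    fixture.validate()
    return fixture


def _gene_structure(rng, config, biotype):
    """Exon/intron intervals in sense-local coordinates starting at 0."""
    if biotype == "mRNA":
        n_introns = int(rng.integers(config.intron_count_range[0],
                                     config.intron_count_range[1] + 1))
    else:
        n_introns = int(rng.integers(0, 2))
    exons, introns = [], []
    pos = 0
    for i in range(n_introns + 1):
        elen = int(rng.integers(*config.exon_length_range))
        exons.append((pos, pos + elen))
        pos += elen
        if i < n_introns:
            ilen = int(rng.integers(*config.intron_length_range))
            introns.append((pos, pos + ilen))
            pos += ilen
    return exons, introns


def _map_point(local: int, gstart: int, gend: int, strand: str) -> int:
    return gstart + local if strand == "+" else gend - 1 - local


def _map_intervals(local_ivs, gstart, gend, strand):
    if strand == "+":
        return tuple((gstart + s, gstart + e) for s, e in local_ivs)
    return tuple(sorted((gend - e, gend - s) for s, e in local_ivs))


def _plant(seq_arr: np.ndarray, motif: str, local_iv, gstart, gend, strand):
    """Write a sense-oriented motif into the reference sequence array."""
    a, b = local_iv
    motif = motif[:b - a]
    if strand == "+":
        seq_arr[gstart + a:gstart + a + len(motif)] = list(motif)
    else:
        rc = _revcomp(motif)
        seq_arr[gend - a - len(motif):gend - a] = list(rc)


# --------------------------------------------------------------- CRAC reads

def simulate_crac_reads(
    fixture: GenomeFixture,
    config: Optional[SimulationConfig] = None,
    n_reads: Optional[int] = None,
) -> tuple[list[RawRead], pd.DataFrame]:
    """Simulate raw CRAC reads with class-dependent oligo(A) tails.

    Each read is 5' UMI + genome-encoded body (with substitution errors) +
    optional non-templated oligo(A) tail + 3' adapter.  When a tail is
    planted, the 3'-end position is chosen so the next templated base in
    sense orientation is not A, keeping the planted tail length
    unambiguous.  The truth table records one row per read.
    """
    config = config or fixture.config
    n_reads = n_reads if n_reads is not None else config.n_crac_reads
    rng = np.random.default_rng(config.seed + 1)
    genes = fixture.genes
    tx = {t.gene_id: t for t in fixture.transcripts}
    eligible = _class_eligibility(fixture, config)
    weights = np.asarray(config.class_weights, dtype=float)
    weights /= weights.sum()

    reads, rows = [], []
    for i in range(n_reads):
        cls = READ_CLASSES[rng.choice(len(READ_CLASSES), p=weights)]
        pool = eligible[cls]
        if not pool:
            cls = "sense_PROMPT"
            pool = eligible[cls]
        gid = pool[int(rng.integers(len(pool)))]
        g = genes.loc[gid]
        t = tx[gid]
        has_tail = rng.random() < config.tail_fraction[cls]
        body = None
        for _ in range(50):  # resample until the 3' context is unambiguous
            body = _sample_body(rng, fixture, config, t, g, cls)
            if body is None:
                break
            if not has_tail or body["next_sense_base"] != "A":
                break
        if body is None:
            continue
        tail_len = 0
        if has_tail:
            tail_len = min(1 + rng.geometric(1.0 / config.tail_mean) - 1,
                           config.tail_max)
            tail_len = max(tail_len, 1)
        seq = body["seq"]
        if config.error_rate > 0:
            seq = _mutate(rng, seq, config.error_rate)
        umi = "".join(BASES[rng.integers(0, 4, size=config.umi_length)])
        full = umi + seq + "A" * tail_len + config.adapter
        qual = _qualities(rng, len(full), config)
        rid = f"crac{i:06d}"
        reads.append(RawRead(read_id=rid, sequence=full, quality=qual))
        rows.append({"read_id": rid, "gene_id": gid, "region_class": cls,
                     "chrom": t.chrom, "strand": body["strand"],
                     "body_start": body["start"], "body_end": body["end"],
                     "end_coord": body["end_coord"], "tail_len": tail_len,
                     "tail_seq": "A" * tail_len, "umi": umi})
    return reads, pd.DataFrame(rows).set_index("read_id")


def _class_eligibility(fixture: GenomeFixture,
                       config: SimulationConfig) -> dict[str, list[str]]:
    """Genes usable per read class, in sense-local coordinates.

    Intron and exon events must lie beyond the sense-PROMPT window so that
    the truth class matches the positional region-assignment rules.
    """
    out: dict[str, list[str]] = {c: [] for c in READ_CLASSES}
    for gid, st in fixture.structures.items():
        out["sense_PROMPT"].append(gid)
        out["antisense_PROMPT"].append(gid)
        if any(ie - 1 >= config.prompt_len for _, ie in st["introns"]):
            out["intron"].append(gid)
        if any(min(ee, st["span"]) - max(es, config.prompt_len) >= 2
               for es, ee in st["exons"]):
            out["exon"].append(gid)
    return out


def _sample_body(rng, fixture, config, t, g, cls):
    """Pick a 3' end inside the class region and cut the genomic body."""
    chrom_seq = fixture.chrom_seqs[t.chrom]
    clen = len(chrom_seq)
    gstart, gend, strand = int(g["start"]), int(g["end"]), t.strand
    st = fixture.structures[t.gene_id]
    read_strand = strand
    if cls == "sense_PROMPT":
        if g["termination_prone"] and rng.random() < config.term_end_prob:
            local_end = config.term_site_offset
        else:
            local_end = int(rng.integers(30, config.prompt_len))
        end_ref = _map_point(local_end, gstart, gend, strand)
    elif cls == "antisense_PROMPT":
        read_strand = "-" if strand == "+" else "+"
        up = int(rng.integers(30, config.prompt_len))
        tss = int(g["tss"])
        end_ref = tss - up if strand == "+" else tss + up
        if not (0 <= end_ref < clen):
            return None
    elif cls == "intron":
        usable = [(is_, ie) for is_, ie in st["introns"]
                  if ie - 1 >= config.prompt_len]
        is_, ie = usable[int(rng.integers(len(usable)))]
        lo = max(is_ + 2, config.prompt_len)
        if rng.random() < config.intron_end_prob or ie - 1 <= lo:
            local_end = ie - 1     # exactly on the G of the intron-terminal AG
        else:
            local_end = int(rng.integers(lo, ie - 2))
        end_ref = _map_point(local_end, gstart, gend, strand)
    else:  # exon
        usable = [(max(es, config.prompt_len), min(ee, st["span"]))
                  for es, ee in st["exons"]]
        usable = [(a, b) for a, b in usable if b - a >= 2]
        a, b = usable[int(rng.integers(len(usable)))]
        local_end = int(rng.integers(a, b))
        end_ref = _map_point(local_end, gstart, gend, strand)
    L = int(rng.integers(*config.read_length_range))
    if read_strand == "+":
        start = max(0, end_ref - L + 1)
        end = end_ref + 1
        seq = chrom_seq[start:end]
        nxt = chrom_seq[end] if end < clen else "N"
    else:
        start = end_ref
        end = min(clen, end_ref + L)
        seq = _revcomp(chrom_seq[start:end])
        nxt = _revcomp(chrom_seq[start - 1]) if start > 0 else "N"
    if len(seq) < 20:
        return None
    return {"seq": seq, "start": start, "end": end, "strand": read_strand,
            "end_coord": end_ref, "next_sense_base": nxt}


def _mutate(rng, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def _qualities(rng, n: int, config) -> tuple[int, ...]:
    q = np.full(n, config.base_quality, dtype=int)
    if config.quality_decay_prob > 0 and rng.random() < config.quality_decay_prob:
        run = int(rng.integers(1, max(2, n // 4)))
        q[-run:] = rng.integers(2, 20, size=run)
    return tuple(int(x) for x in q)


# ----------------------------------------------------------------- NET-seq

def simulate_netseq(
    fixture: GenomeFixture,
    config: Optional[SimulationConfig] = None,
    n_reads: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Poisson NET-seq occupancy; PROMPTs of termination-prone genes boosted.

    Returns (aligned reads frame, truth frame of per-region expected counts).
    """
    config = config or fixture.config
    n_reads = n_reads if n_reads is not None else config.n_netseq_reads
    rng = np.random.default_rng(config.seed + 2)
    if n_reads == 0:
        empty = pd.DataFrame(columns=["read_id", "chrom", "start", "end", "strand"])
        return empty, pd.DataFrame(columns=["gene_id", "region", "lam"])

    regions = []  # (gene, region, chrom, start, end, strand, weight)
    for t in fixture.transcripts:
        g = fixture.genes.loc[t.gene_id]
        act = 1.0 if g["active"] else config.inactive_weight
        tss = int(g["tss"])
        if t.strand == "+":
            prompt = (tss, min(tss + config.prompt_len, fixture.chrom_lengths[t.chrom]))
        else:
            prompt = (max(0, tss - config.prompt_len + 1), tss + 1)
        boost = config.netseq_prompt_boost if g["termination_prone"] else 1.0
        regions.append((t.gene_id, "sense_PROMPT", t.chrom, *prompt, t.strand,
                        act * boost * (prompt[1] - prompt[0])))
        body = (int(g["start"]), int(g["end"]))
        regions.append((t.gene_id, "body", t.chrom, *body, t.strand,
                        act * (body[1] - body[0])))
    w = np.array([r[-1] for r in regions], dtype=float)
    lam = n_reads * w / w.sum()
    counts = rng.poisson(lam)

    rows, truth = [], []
    rid = 0
    for (gid, region, chrom, s, e, strand, _), lam_i, c in zip(regions, lam, counts):
        truth.append({"gene_id": gid, "region": region, "lam": float(lam_i),
                      "count": int(c)})
        if c == 0:
            continue
        starts = rng.integers(s, max(s + 1, e - 30), size=c)
        lens = rng.integers(20, 41, size=c)
        for st, ln in zip(starts, lens):
            rows.append({"read_id": f"net{rid:06d}", "chrom": chrom,
                         "start": int(st), "end": int(min(e, st + ln)),
                         "strand": strand})
            rid += 1
    return pd.DataFrame(rows), pd.DataFrame(truth)


# -------------------------------------------------------------------- decay

def simulate_decay(
    fixture: GenomeFixture,
    config: Optional[SimulationConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Exponential-decay count tables with constant spike-ins.

    Gene counts follow N0 * 2**(-t/t_half) scaled by a per-sample depth
    factor; spike-ins are constant before depth scaling; the mock sample
    is collected at 240 min without shut-off.  Returns (counts, sample
    metadata, truth) where truth holds per-gene N0/half-life and
    per-sample depth factors live in the metadata.
    """
    config = config or fixture.config
    dc = config.decay
    rng = np.random.default_rng(config.seed + 3)
    genes = fixture.genes
    n0 = np.exp(rng.uniform(np.log(dc.n0_range[0]), np.log(dc.n0_range[1]),
                            size=len(genes)))
    spike_ids = [f"ERCC-{i + 1:04d}" for i in range(dc.n_spikes)]
    spike_means = np.exp(rng.uniform(np.log(dc.spike_mean_range[0]),
                                     np.log(dc.spike_mean_range[1]),
                                     size=dc.n_spikes))
    spike_means[:dc.n_low_spikes] = rng.uniform(10, 45, size=dc.n_low_spikes)

    samples = []
    for t in dc.timepoints:
        for r in range(dc.replicates):
            samples.append((f"t{t}_rep{r + 1}", t, r + 1, False))
    if dc.include_mock:
        for r in range(dc.replicates):
            samples.append((f"mock_rep{r + 1}", 240, r + 1, True))

    cols, meta_rows = {}, []
    for sid, t, rep, mock in samples:
        depth = float(np.exp(rng.uniform(np.log(dc.depth_factor_range[0]),
                                         np.log(dc.depth_factor_range[1]))))
        decayed = n0 if mock else n0 * 2.0 ** (-t / genes["halflife"].to_numpy())
        gene_mu = decayed * depth
        spike_mu = spike_means * depth
        mu = np.concatenate([gene_mu, spike_mu])
        cols[sid] = rng.poisson(mu) if dc.poisson_noise else mu
        meta_rows.append({"sample_id": sid, "timepoint": t, "replicate": rep,
                          "is_mock": mock, "depth_factor": depth})
    counts = pd.DataFrame(cols, index=list(genes.index) + spike_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = pd.DataFrame({"n0": n0, "halflife": genes["halflife"].to_numpy()},
                         index=genes.index)
    truth_spikes = pd.DataFrame({"n0": spike_means, "halflife": np.inf},
                                index=spike_ids)
    return counts, meta, pd.concat([truth, truth_spikes])


# -------------------------------------------------------------- single cell

def simulate_sc(
    fixture: GenomeFixture,
    config: Optional[SimulationConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Negative-binomial single-cell counts with planted structure.

    Counts are gamma-Poisson with per-gene mean (from the fixture truth),
    per-cell size factor, subpopulation marker fold changes, inflated
    dispersion for jackpot genes and a shared log-normal latent factor for
    cis pairs.  Metadata includes mapped-read totals, mitochondrial
    fractions and capture annotations for QC.  Truth: subpopulation
    labels, jackpot genes, cis pair table.
    """
    config = config or fixture.config
    sc = config.sc
    rng = np.random.default_rng(config.seed + 4)
    genes = fixture.genes
    n_genes, n_cells = len(genes), sc.n_cells
    mu = genes["sc_mean"].to_numpy(dtype=float)

    subpop = rng.choice(len(sc.subpop_proportions), size=n_cells,
                        p=np.asarray(sc.subpop_proportions))
    marker_sets = []
    for _ in sc.subpop_proportions:
        n_mark = int(round(sc.marker_fraction * n_genes))
        marker_sets.append(rng.choice(n_genes, size=n_mark, replace=False))

    jackpot_idx = (rng.choice(n_genes, size=sc.n_jackpot, replace=False)
                   if sc.n_jackpot else np.array([], dtype=int))
    disp = np.full(n_genes, sc.dispersion)
    disp[jackpot_idx] *= sc.jackpot_dispersion_mult

    cis_pairs = _pick_cis_pairs(genes, sc.n_cis_pairs, sc.cis_max_distance, rng)
    sf = np.exp(rng.uniform(np.log(sc.size_factor_range[0]),
                            np.log(sc.size_factor_range[1]), size=n_cells))

    M = np.tile(mu[:, None], (1, n_cells)) * sf[None, :]
    for s, cells in ((s, np.flatnonzero(subpop == s))
                     for s in range(len(sc.subpop_proportions))):
        if len(sc.subpop_proportions) > 1 and len(cells):
            M[np.ix_(marker_sets[s], cells)] *= sc.marker_fold
    gene_pos = {g: i for i, g in enumerate(genes.index)}
    for _, pr in cis_pairs.iterrows():
        f = np.exp(sc.cis_strength * rng.standard_normal(n_cells))
        for g in (pr["gene_a"], pr["gene_b"]):
            M[gene_pos[g], :] *= f

    if np.all(disp <= 0):
        counts = rng.poisson(M)
    else:
        shape = 1.0 / np.maximum(disp, 1e-12)
        lam = rng.gamma(shape[:, None], M / shape[:, None])
        counts = rng.poisson(lam)
    counts = pd.DataFrame(counts, index=genes.index,
                          columns=[f"cell{j + 1:04d}" for j in range(n_cells)])

    mapped = np.exp(rng.normal(np.log(sc.mapped_reads_mean), 0.2, size=n_cells))
    low = rng.random(n_cells) < sc.low_quality_fraction
    mapped[low] *= 0.2
    mito = rng.beta(*sc.mito_beta, size=n_cells)
    capture = np.where(rng.random(n_cells) < 0.95, "ok", "doublet")
    meta = pd.DataFrame({
        "mapped_reads": mapped, "mito_fraction": mito,
        "capture_annotation": capture, "subpop": subpop,
        "size_factor": sf,
    }, index=counts.columns)
    truth = {"subpop": pd.Series(subpop, index=counts.columns),
             "jackpot_genes": list(genes.index[jackpot_idx]),
             "cis_pairs": cis_pairs,
             "marker_sets": [list(genes.index[m]) for m in marker_sets]}
    return counts, meta, truth


def _pick_cis_pairs(genes: pd.DataFrame, n_pairs: int, max_dist: float,
                    rng) -> pd.DataFrame:
    """Adjacent lincRNA-involving gene pairs closer than ``max_dist``."""
    cols = ["gene_a", "gene_b", "genomic_distance"]
    if n_pairs == 0:
        return pd.DataFrame(columns=cols)
    cand = []
    srt = genes.sort_values(["chrom", "start"])
    for (a, ra), (b, rb) in zip(srt.iloc[:-1].iterrows(), srt.iloc[1:].iterrows()):
        if ra["chrom"] != rb["chrom"]:
            continue
        gap = max(0, rb["start"] - ra["end"])
        if gap <= max_dist and ("lincRNA" in (ra["biotype"], rb["biotype"])):
            cand.append((a, b, float(gap)))
    if not cand:
        return pd.DataFrame(columns=cols)
    idx = rng.choice(len(cand), size=min(n_pairs, len(cand)), replace=False)
    return pd.DataFrame([cand[i] for i in sorted(idx)], columns=cols)


# ------------------------------------------------------------- perturbation

def simulate_perturbation_lines(
    fixture: GenomeFixture,
    config: Optional[SimulationConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Clonal-line counts with planted neighbour effects and batch shifts.

    Control lines plus, per targeted lincRNA locus, a deletion group and a
    ribozyme group.  In log2 space: base mean + per-batch scalar offset +
    noise; targeted lines additionally carry the locus knockdown and the
    planted effect on the nearest neighbour gene(s).  Returns (counts,
    line metadata, truth effect table).
    """
    config = config or fixture.config
    pc = config.perturb
    rng = np.random.default_rng(config.seed + 5)
    genes = fixture.genes
    lincs = genes.index[genes["biotype"] == "lincRNA"]
    loci = list(lincs[rng.choice(len(lincs), size=min(pc.n_loci, len(lincs)),
                                 replace=False)])
    base = rng.normal(pc.base_log2_mean, pc.base_log2_sd, size=len(genes))

    lines = [("control", i) for i in range(pc.n_control)]
    for locus in loci:
        lines += [(f"deletion:{locus}", i) for i in range(pc.lines_per_group)]
        lines += [(f"ribozyme:{locus}", i) for i in range(pc.lines_per_group)]
    batch_offsets = rng.normal(0, pc.batch_log2_sd, size=pc.n_batches)

    effects = []
    effect_map: dict[str, dict[str, float]] = {}
    for locus in loci:
        row = genes.loc[locus]
        nb = genes[(genes["chrom"] == row["chrom"]) & (genes.index != locus)].copy()
        gap = np.maximum(nb["start"] - row["end"], row["start"] - nb["end"])
        nb["distance"] = np.maximum(gap, 0)
        nb = nb[nb["distance"] <= pc.neighbor_max_distance].sort_values("distance")
        targets = list(nb.index[:pc.n_affected_neighbors])
        emap = {locus: pc.locus_log2_effect}
        for g in targets:
            emap[g] = pc.neighbor_log2_effect
            effects.append({"locus": locus, "gene": g,
                            "distance": float(nb.loc[g, "distance"]),
                            "log2_effect": pc.neighbor_log2_effect})
        effect_map[locus] = emap

    cols, meta_rows = {}, []
    for li, (group, rep) in enumerate(lines):
        batch = li % pc.n_batches
        x = base + batch_offsets[batch] + rng.normal(0, pc.noise_log2_sd,
                                                     size=len(genes))
        if group != "control":
            locus = group.split(":", 1)[1]
            for g, eff in effect_map[locus].items():
                x[genes.index.get_loc(g)] += eff
        lid = f"line{li + 1:03d}"
        cols[lid] = np.round(2.0 ** x).astype(int)
        meta_rows.append({"line_id": lid, "group": group, "batch": f"batch{batch}"})
    counts = pd.DataFrame(cols, index=genes.index)
    meta = pd.DataFrame(meta_rows).set_index("line_id")
    truth = pd.DataFrame(effects, columns=["locus", "gene", "distance",
                                           "log2_effect"])
    return counts, meta, truth


# ----------------------------------------------------------------- pipeline

def simulate_all(config: SimulationConfig, outdir) -> GenomeFixture:
    """Generate every dataset and write the full text-file layout."""
    outdir = Path(outdir)
    fixture = make_genome(config)
    fixture.write(outdir)
    reads, truth = simulate_crac_reads(fixture, config)
    io.write_fastq(outdir / "crac_reads.fastq", reads)
    io.write_tsv(outdir / "crac_truth.tsv", truth)
    net, net_truth = simulate_netseq(fixture, config)
    io.write_tsv(outdir / "netseq_reads.tsv", net, index=False)
    io.write_tsv(outdir / "netseq_truth.tsv", net_truth, index=False)
    counts, meta, truth_d = simulate_decay(fixture, config)
    io.write_tsv(outdir / "decay_counts.tsv", counts)
    io.write_tsv(outdir / "decay_samples.tsv", meta)
    io.write_tsv(outdir / "decay_truth.tsv", truth_d)
    sc_counts, sc_meta, sc_truth = simulate_sc(fixture, config)
    io.write_tsv(outdir / "sc_counts.tsv", sc_counts)
    io.write_tsv(outdir / "sc_cells.tsv", sc_meta)
    io.write_tsv(outdir / "sc_cis_pairs_truth.tsv", sc_truth["cis_pairs"],
                 index=False)
    p_counts, p_meta, p_truth = simulate_perturbation_lines(fixture, config)
    io.write_tsv(outdir / "perturb_counts.tsv", p_counts)
    io.write_tsv(outdir / "perturb_lines.tsv", p_meta)
    io.write_tsv(outdir / "perturb_truth.tsv", p_truth, index=False)
    return fixture
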