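# Methods

This note documents the models and procedures implemented in `lincterm`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Coordinate conventions

All in-memory coordinates are 0-based half-open. GTF is written and read
1-based closed; BED6 is 0-based half-open. A tail event's `end_coord` is
the 0-based reference position of the last genome-encoded base of the
read, strand-aware (for a minus-strand read this is the leftmost aligned
base).

## Catalogue filters (annotation)

Candidate lincRNA transcripts are removed if their full span (exons and
introns) overlaps a protein-coding or classical-noncoding transcript on
either strand — the conservative reading of "overlap in either
orientation". Survivors are clustered by span overlap into genes.
Clustering is strand-aware by default: overlapping transcripts on
opposite strands remain separate genes, because antisense transcription
is a distinct biotype in this analysis; `ignore_strand` merges them.
Clusters wider than 100 kb are dropped as regions where individual genes
cannot be distinguished; this cap is applied after coding-overlap
exclusion (the ordering is not dictated by the procedure's definition, so
it is configurable).

Per-cluster statistics: exonic length is the union of member exons;
repeat fraction is exonic nt overlapping repeat intervals divided by
exonic nt; distance to coding genes is edge-to-edge in nt on the same
chromosome (different chromosome ⇒ +∞, and exactly 5,000 nt fails the
"> 5 kb" rule — strict inequalities throughout); expression per kb is
raw count / size factor × 1000 / exonic length. The `high_quality` flag
requires all four filters; the default expression floor is 5 normalised
counts/kb, with a stricter 10/kb preset available
(`FilterThresholds.preset("results")`). The shortlist additionally
requires > 30 counts/kb, local density below 20 genes in a 100-kb window
centred on the cluster midpoint, and (when supplied) external
low-coding-potential calls.

## Read preprocessing (preprocess)

Pipeline order: adapter clip → quality trim/filter → UMI extraction →
duplicate collapse → low-complexity 3′ trim (CRAC only) → DUST filter.
Every operation is pure and each stage logs in/accepted/rejected counts;
rejected entries carry the number of PCR copies they represent so the
accepted/rejected partition always sums to the input.

Choices where the underlying tools' behaviour had to be pinned down:

- Adapter matching tolerates 1 mismatch per 10 nt of overlap
  (configurable); matches shorter than 10 nt must be exact. The tail
  branch requires a detected adapter of ≥ 7 nt.
- Quality trimming removes 3′ bases below Q25, then rejects reads with
  < 90% of remaining bases at ≥ Q20. The tail branch instead requires
  every position at ≥ Q30.
- The UMI is a 5-nt inline 5′ tag (length configurable); duplicate
  collapse keys on the (UMI, post-UMI sequence) pair.
- Low-complexity 3′ trimming iteratively removes the longest suffix of
  length ≥ 2 whose modal base makes up ≥ 80% of the suffix; reads left
  under 18 nt are rejected.
- The DUST-style score counts repeated overlapping 3-mers, scaled 0–100
  (homopolymer = 100), threshold 20. This is an approximation to the
  dust method of the trimming tools it replaces, documented as such.
- Nonrepeat classification: a read is nonrepeat iff its best genome or
  cDNA alignment score is strictly greater than its best repeat-index
  score; ties go to repeat.

## Tail detection (tails)

The genome-scale aligners used on real data are replaced, at desk scale,
by an exact-k-mer seed (k = 12, several consecutive seeds so one error
cannot hide a locus) plus greedy extension over both strands. Scoring is
+1/match, −2/mismatch over the aligned prefix; a valid alignment needs
≥ 18 aligned nt at ≥ 95% identity. The best (score, position, prefix
length) is chosen with ties resolved toward the **shorter** prefix and
then the lexicographically smallest locus. With exact matches the score
strictly increases along a templated extension, so a genomic A adjacent
to an A-tail is absorbed into the alignment (tails are the shortest
suffix consistent with the genome — a known ±1 uncertainty on the 3′
end); the shorter-prefix tie-break only prevents extending through
mismatches that do not pay for themselves. An exhaustive, vectorised
enumeration over every position × prefix length implements the same rules
as an independent oracle in the tests.

Reads scoring higher against a provided spliced-transcript sequence than
against the genome are excluded from tail calls — their apparent tails
are exonic sequence across a junction. Oligo(A) selection is
homopolymeric by default (tail entirely A, length ≥ 2, consistent with
the "oligo(A)" reading); a laxer mode (≥ 2 A's and ≥ 80% A) is available.
Oligo(C/G/T) homopolymer tails are retrievable as a negative-control set.

Region assignment uses the event's 3′-end coordinate with strand
matching, precedence sense-PROMPT > antisense-PROMPT > intron > exon
(PROMPT regions are positional windows that may overlap the first exon).
Sense PROMPT = 1 kb downstream of the TSS in the sense direction;
antisense PROMPT = 1 kb upstream, read on the opposite strand. Intron
events are flagged when the two genomic nt ending at the 3′ end read
"AG" in sense orientation, separating events at the intron terminus from
mid-intron events. Where several A-tailed reads map to one (gene,
region), one is kept uniformly at random under a seed. The 201-nt
base-composition profile is centred on the last templated base (not the
first tail base) and strand-oriented; columns are renormalised to sum to
1 and events whose window leaves the chromosome are dropped with a log
message.

## Termination quantification (termination)

The seven primary-TSS criteria, with comparisons exactly as stated
(strict "> two-fold", "at least 1.5×" as ≥): (i) an H3K4me3 peak within
0.5 kb; (ii) ≥ 20 NET-seq counts in the sense PROMPT (raw counts — the
procedure does not specify normalisation); (iii) strictly the strongest
PROMPT among the gene's TSSes; (iv) no other 1-kb window in the gene,
outside annotated PROMPTs, with more than two-fold the PROMPT NET-seq
signal — windows advance in 100-nt steps (granularity was open);
(v) sense RNA-seq over 2 kb downstream ≥ 1.5× antisense RNA-seq over
2 kb upstream; (vi) no snoRNA overlap; (vii) span > 2 kb with ≥ 1 kb
exonic. An optional extra predicate adds a minimum coding-gene distance
for the most stringent gene set.

Regions: sense PROMPT, antisense PROMPT, exons minus the sense PROMPT,
and introns minus the sense PROMPT (the subtraction keeps the region set
disjoint). Reads are counted by midpoint with strand matching; the
antisense PROMPT counts reads antisense to the gene. Ratios use a
pseudocount of 1 by default (the source procedure is silent); with
pseudocount 0 a zero denominator yields a missing ratio rather than
infinity, and simultaneous rescaling of both libraries leaves ratios
unchanged. Class comparisons use the Wilcoxon rank-sum test.

Metaplots bin read midpoints (5-nt bins at exon boundaries, 10-nt bins in
2-kb TSS or nucleosome-dyad windows), divide each transcript's bins by
its maximum bin total, and average across transcripts; all-zero
transcripts are excluded (max-normalisation undefined) and counted in the
log. One representative transcript per gene is used: without external
principal-isoform data, the longest-exonic transcript, random tie-break
under a seed.

## Half-lives (decay)

Size factors are median-of-ratios against a per-feature geometric-mean
reference, computed from spike-in rows with cross-sample mean > 50;
features containing any zero are excluded (undefined log geometric
mean). The median is taken in log space and the factors are rescaled to
unit geometric mean, making normalisation exactly idempotent; the rescale
multiplies all samples by one shared constant and affects no ratio-based
quantity. The half-life is t·log 2 / log(med₀/med_t) with t = 240 min and
medians across replicate libraries; genes with med₂₄₀ ≥ med₀ get an
undefined (flagged) half-life rather than being floored. The 30- and
90-min samples are normalised for QC only; the mock (no-drug, 240 min)
sample yields a drift diagnostic (mock/t₀ ratio) and never enters the
estimator. Expression strata for class comparisons split at 40
normalised counts with strict inequalities — a gene exactly at 40 is in
neither the low nor the high stratum.

## Single-cell analysis (singlecell)

Cell QC: capture annotation "ok", optional external quality flag,
≥ 0.5 M mapped reads, ≤ 10% mitochondrial reads; boundary values pass.
Normalisation shares the median-of-ratios implementation. Variable genes
are the union of the 300 largest-|loading| genes on each of the first 7
PCs of the log2(x+1) cell × gene matrix (≤ 2,100 genes).

DM statistic: CV² = var/mean² of normalised counts per gene; within each
gene-length stratum (terciles; 3 bins, running-median window of 50 genes
— the stratification parameters were open and these follow common
practice for this statistic), genes are ordered by mean expression and
the expected log10 CV² is a centred running median; DM is the residual.
DM is scale-free; bins smaller than the window shrink it with a log
message. Jackpot scores are the per-gene median and 90th percentile
across cells with linear quantile interpolation (so the test oracle is
exact). Cell-cycle stages are assigned by argmax of marker-panel mean
expression; ties and all-zero cells are left unassigned.

The correlation screen uses Spearman by default (robust to jackpot
outliers; the choice of coefficient was open), Pearson by flag; p-values
come from the t transform of the coefficient and Benjamini–Hochberg runs
over all tested lincRNA × mRNA pairs.

Cis co-expression: expression profiles are log2(x+1) then per-gene
centred and scaled; constant genes are dropped. The null is the set of
same-chromosome pairs 20–40 Mb apart on real data; on the synthetic
mini-genome the range scales (the package takes the range as a
parameter), preserving the "distant pairs on the same chromosome"
semantics. The threshold is the 1st percentile of null-pair Euclidean
distances (< 100 null pairs is an error); proximal pairs closer than
20 kb are excluded as possible single transcription units, and
below-threshold fractions are reported in 200-kb genomic-distance bins
(fractions count pairs, not lincRNAs). By construction ~1% of null
proximal pairs fall below the threshold.

## Perturbation tests (perturbation)

Batch centring subtracts the per-gene batch median (or mean) in log
space and adds back the grand statistic, preserving within-batch gene
differences exactly. Neighbour genes lie within 500 kb edge-to-edge of
the locus span by default; genes overlapping the (deleted) span are
flagged and excluded from testing. The Monte-Carlo test statistic is
|median(targeted) − median(control)| — two-sided via the absolute value,
since effects in both directions occur; labels are permuted globally
after batch centring (within-batch permutation available by flag), with
the add-one estimator p = (1 + #{permuted ≥ observed}) / (n_perm + 1),
n_perm = 10,000 by default, so p is never 0. Deletion and ribozyme lines
of a locus are tested as separate groups against all control lines, and
Bonferroni multiplies by the number of (locus, gene, group) tests
performed. With 4 targeted vs 20 control lines the permutation null has
a tail floor near the probability of reassembling the targeted group
(~C(24,4)⁻¹ scale), which bounds attainable p-values in that design.
Gene-set overlap uses a 2×2 chi-squared test without continuity
correction (Yates by flag); up-regulation means a fold change > 1.5
after adding a pseudocount of 8 to both measurements.

## Synthetic data (synthetic)

The generator's defaults define the study conditions for all tests: a
3 × 200 kb genome; 30 mRNA genes (1–3 introns) and 20 lincRNAs (0–1);
80% of genes active (H3K4me3 peak within 0.5 kb of the TSS), half of the
active genes termination-prone with a premature 3′ end planted 300 nt
downstream of the TSS followed by a ~70%-T 25-nt window; AG planted at
every intron 3′ end. CRAC reads are 5-nt UMI + 25–60 nt genomic body +
optional oligo(A) tail (geometric, mean 3, capped at 15 nt) + a 21-nt 3′
adapter, at Q38 with an optional low-quality 3′ decay to exercise
trimming; tail fractions per class default to 10% (sense PROMPT), 8%
(antisense PROMPT), 5% (intron), 1% (exon). When a tail is planted the
3′ end is chosen so the next templated base in sense orientation is not
A, keeping the planted tail length identifiable — real data retain the
±1 ambiguity the aligner documents. Exon- and intron-class read 3′ ends
are placed outside the sense-PROMPT window so truth labels agree with
the positional assignment rules. NET-seq coverage is Poisson with
3× PROMPT density at termination-prone genes; decay counts follow
N₀·2^(−t/t½) × depth factor with constant spike-ins (two planted below
the mean-50 floor); single-cell counts are gamma-Poisson with
subpopulation marker folds, jackpot dispersion inflation, and a shared
log-normal factor for cis pairs; perturbation lines add per-batch scalar
shifts and a −1 log2 effect on the nearest neighbour of each targeted
locus (2× knockdown), −3 log2 on the locus itself.

Everything is deterministic given the config seed (each generator derives
its stream from seed + a fixed offset) and every emitted entity appears
exactly once in the truth tables.

What the generator does **not** emulate: realistic genome composition
(sequence is uniform-random outside planted motifs), base-caller error
models, reads spanning splice junctions, multimapping/repeat-derived
reads, doublets, ambient RNA, or library-specific biases. Passing tests
therefore demonstrate correctness of the implemented rules and
statistical calibration under idealised noise, not robustness to every
artefact of real sequencing data.

## Problem sizes

The default test and demonstration sizes — 50 genes, 5,000 reads, 200
cells, 2,000-gene null matrices, 500-read oracle comparisons on a 60-kb
single-chromosome genome, 2,000 Monte-Carlo calibration replicates —
were chosen so that exhaustive oracles (quadratic alignment enumeration,
all-pairs overlap checks) remain tractable while binomial/Poisson
tolerances stay tight enough to detect real defects.
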