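# Methods

## Scope and model

`mesplice` analyzes *reference* mobile elements (MEs) retained in spliced
transcripts — abnormal splicing that reads through a donor site into
intronic ME sequence — not new germline or somatic ME insertions. Its
inputs are the products of an upstream assembly workflow (de novo assembler
→ RepeatMasker → pblat), consumed as plain files: transcript FASTA,
RepeatMasker `.out`, 21-column PSL, UCSC refGene gene models, raw FASTQ.
The package does not run the assembler, RepeatMasker or the aligner; the
synthetic generator emits their outputs by construction.

All internal coordinates are 0-based, half-open, on the plus strand of the
target sequence. Conversions (1-based inclusive `.out` coordinates,
reversed-query PSL qStarts on minus-strand alignments) happen only at the
I/O boundary, and every writer restores them, so writer→reader round trips
are field-exact. Within a minus-strand PSL block ascending plus-strand
query positions map to descending target offsets; the genomic projection
mirrors block offsets accordingly.

## ME-transcript calling

A call is one (transcript, ME hit) pair that survives, in order:

- transcript length ≥ 300 bp (`min_length`, the assembler's own cutoff for
  retained contigs; the record type itself does not hard-code the
  threshold);
- repeat class ∈ {SINE, LINE, LTR, DNA, SVA}; simple repeats,
  low-complexity, satellites etc. are retained by the parser as class
  "Other" but never called. RepeatMasker writes SVA as `Retroposon/SVA`,
  which is mapped to class SVA;
- fragmented RepeatMasker rows of the same subfamily and orientation
  < 10 bp apart are merged first (length-weighted mean divergence, max
  score), so one shattered element yields one call. The same merge rule is
  applied before the genome-wide census used for TPMPM;
- a genome alignment exists; among multiple hits the one maximizing
  `matches − mismatches − q_gap_count − t_gap_count` wins, ties broken by
  (chromosome, leftmost target start) for determinism;
- the ME interval projects through the alignment blocks with aligned
  fraction ≥ 0.5 (`min_aligned_fraction`, exposed); an ME that mostly falls
  into alignment gaps is not localizable and is dropped;
- a host gene is found: the isoform with maximal exonic-bp overlap with the
  whole transcript's projection, requiring ≥ 1 bp; isoform ties go to the
  longest CDS (the isoform against which a UTR/CDS breakdown is most
  meaningful), then the lexicographically smallest accession.

The gene-region label is single-valued per call: noncoding isoforms give
`noncoding_exonic`; for coding isoforms the ME projection's bp overlap with
the genomic spans `[tx_start, cds_start)`, `[cds_start, cds_end)`,
`[cds_end, tx_end)` is compared (5′/3′ labels swapped on minus strand) and
the majority wins, ties resolved cds > 3′ UTR > 5′ UTR. The suite checks
this against a per-base brute-force vote on randomized gene models, and
checks that mirroring the genome (with all annotations) changes no label.

## Frequency units

- **TPM** (study-specific): calls per million assembled transcripts,
  `count / total_transcripts × 10^6`, where `total_transcripts` counts all
  assembled transcripts, not only ME-transcripts. Counting is per ME hit by
  default; a `per_transcript` mode counts distinct transcript ids instead
  (both interpretations of "number per million transcripts" are defensible;
  per-hit is the default used for class × region tables).
- Region scopes: `all_exons` (every call, including noncoding-exonic),
  plus `cds` / `three_prime_utr` / `five_prime_utr` for coding isoforms.
  Hence per class `all_exons ≥ cds + 3′UTR + 5′UTR`, with equality when no
  noncoding calls exist.
- **TPMPM**: `tpm / (genome_count / 10^6)` per class. The genome census is
  an explicit input — either counted from a genome-wide `.out` with
  `census_genome_mes` or supplied as published copy numbers
  (`HUMAN_GENOME_ME_COUNTS`: SINE 1,779,233; LINE 1,516,226; LTR 720,177;
  DNA 483,994). Taking the census as input keeps the unit well-defined
  regardless of which denominator a study prefers (e.g. class-wide vs
  family-restricted counts).

## Group statistics

`compare_groups` routes on normality: Shapiro–Wilk per group at α = 0.05
(groups of n < 3 cannot be assessed and pass). All normal → one-way ANOVA
with Student–Newman–Keuls; otherwise Kruskal–Wallis with the Nemenyi test,
or pairwise Wilcoxon rank-sum when any group has n < 5. SNK and Nemenyi
are computed on `scipy.stats.studentized_range` directly: SNK orders group
means and tests each pair at its rank span r against the pooled-error df,
with the harmonic-mean n correction for unequal sizes, and propagates
p-values so an inner pair is never more significant than an enclosing range
(stepwise protection); Nemenyi uses mean pooled ranks with k groups and
infinite df, without tie correction. All p-values are two-sided; raw
p-values are reported with stars at 0.05/0.01/0.001; a Benjamini–Hochberg
option exists but defaults off, since the class × region tables are
reported unadjusted. Replicated samples per subject are treated as
independent samples; subsetting to one sample per subject is a caller-side
robustness check, not a model feature (no mixed-effects modelling).

Calibration is part of the test suite: over 1,000 null replicates of four
n = 10 groups, both omnibus routes must reject at α = 0.05 between 3% and
7% of the time.

## Age profiles

Percent divergence from the subfamily consensus is the age proxy (higher =
older). Profiles are histograms over [0, 100] % divergence (default 1%
bins) normalized to sum 1, each ME hit weighted once. Because the source
figures are not reproducible without the original sequence data, profile
comparison is made testable with statistics: a two-sample KS test on the
underlying divergence values (not the binned densities) and a kernel-free
peak shift (difference of highest-density bin centers).

## Junction assays and ORF impact

The divergence junction of two splice forms is the longest common prefix of
the normal mRNA and the ME-transcript (both on the mRNA plus strand); a
common prefix under 20 bp is rejected as probe-ambiguous. Probes are
`flank` bases (default 10) each side of the junction in each form, so the
two 20-mers share their first half and differ at position `flank`.
Counting is exact substring matching of the probe or its reverse complement,
each read counted at most once per probe; a read matching both probes is an
assertion failure rather than a silent double count (the construction
excludes shared 20-mers). No mismatch tolerance is offered: a fixed 20-mer
with one mismatch would need an error-model policy there is no basis to
choose. Paired-end mates are counted independently as reads. Per sample:
`rpm = count / total_reads × 10^6`; `me_rate = me / (me + normal)`,
undefined (and excluded from group tests) when no junction reads occur.
Junction variables are compared by pairwise unpaired two-tailed t-tests.

ORF impact: the normal CDS is spliced from the genome; the ME-form coding
sequence is the shared 5′ CDS portion followed by the ME-transcript's own
continuation, translated in the normal frame to the first stop.
`premature_stop` is true when a stop appears before the normal protein
length; a retained segment of length ≡ 0 (mod 3) without a stop is an
in-frame insertion. A junction upstream of the CDS start is reported as
UTR-only. Nonsense-mediated decay is not modelled; only the premature-stop
flag is reported.

## Synthetic worlds

`build_world` lays genes along one chromosome: exon count 2–20, exon length
50–500 bp, intron length 200–5,000 bp, intergenic gaps 1–5 kb, ~10%
noncoding isoforms, both strands equally. For genes with ≥ 4 exons the CDS
starts inside the second and ends inside the penultimate exon, so first and
last introns fall in UTR spans and every region category exists in the
world. One ME is planted per intron with probability 0.9 (plus intergenic
MEs), classes drawn with weights proportional to the human class copy
numbers (so the synthetic census preserves SINE > LINE > LTR > DNA), and
divergence drawn from class-specific truncated normals (modes: SINE 11%,
DNA 16%, LTR 18%, LINE 26% — youngest-to-oldest ordering as observed for
these classes; parameters are configuration, not claims). No SVA is
planted, so zero downstream SVA calls is a structural property of default
worlds.

Default cohort: control (51 samples), TLE-NC (17), TLE (14), TLE-HS (8),
~10,000 transcripts per sample, all-exon ME-retention rates
0.8/1.4/1.5/2.0% (a gradient rising from control to TLE-HS), retention
class mix SINE 0.49 / LINE 0.25 / DNA 0.16 / LTR 0.10, region mix 3′ UTR
0.70 / CDS 0.20 / 5′ UTR 0.10 with 10% of events in noncoding isoforms,
and read-level junction ME-rates 10.9/3.0/27.0/26.3% with paired-end 150-bp
reads. A retention event fuses the two exons flanking the chosen intron
into one alignment block; PSL, `.out` and truth rows are emitted from the
known coordinates rather than by running an aligner — the alignment step is
deterministic glue, and constructing its output keeps tests hermetic.
Samples also include sub-300-bp ME-bearing decoys and Other-class repeat
rows to exercise the caller's filters.

Two fidelity limits matter for interpreting green tests: sequences are
i.i.d. random (no base composition, no real repeat consensus, no assembly
errors, no alignment ambiguity), and expression is uniform across genes
(retention events are the only structure). Passing tests therefore
demonstrate the correctness of coordinate arithmetic, filtering,
normalization, counting and statistics under known truth — not robustness
to real assembler or aligner artefacts.

The SCN1A-like fixture is a deterministic 26-exon gene with a 1,980-aa
protein; the abnormal form reads through the 17th exon's donor site into an
87-bp LINE (L1PA2) segment whose first two bases complete the boundary
codon to an in-frame TAA. The junction sits after coding base 2,020
(residue 673), so the truncated tail is 1,307 residues. The coding sequence
is synthesized from sense codons only, so the engineered stop is the first
one.

## Problem sizes and numerics

The test suite and acceptance script run the gradient-recovery experiment
at 20 replicate cohorts of 90 samples × 10,000 transcripts (in-memory,
repeat-bearing transcripts materialized individually, background
transcripts as counts — they carry no repeats and cannot produce calls),
junction assays at 1,000 junction-spanning read pairs per sample, the
region-label oracle at 1,000 randomized gene models, and calibration at
1,000 null replicates per route. Histogram densities are exact rational
counts (sum-to-1 within 1e-9); TPM/TPMPM are plain floating-point ratios;
all tie-breaks (alignment selection, isoform choice, region labels) are
documented total orders, so every pipeline stage is deterministic given its
inputs and seed.
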