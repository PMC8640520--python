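# mesplice

Detection and quantification of **mobile-element-containing transcripts**
(ME-transcripts) in de-novo-assembled RNA-seq transcriptomes, built for
case/control comparisons such as temporal-lobe-epilepsy (TLE) cohorts
against healthy controls.

Transposable elements — SINEs, LINEs, LTR elements, DNA transposons and
SVAs — make up roughly half the human genome, mostly in introns. When
splicing misfires, intronic ME sequence is retained in the mature transcript
("exon extension" / intron retention). In coding regions this typically
introduces a premature stop codon and a truncated, loss-of-function protein.
`mesplice` turns the detection of such events into a reproducible pipeline:

1. **Call ME-transcripts** — given assembled transcripts (FASTA), their
   RepeatMasker annotation (`.out`) and transcript→genome alignments (PSL),
   keep transcripts ≥ 300 bp whose repeats belong to the five ME classes,
   project each ME through the alignment to genomic coordinates, assign the
   host gene by maximal exonic overlap against refGene models, and label
   the gene region (5′ UTR / CDS / 3′ UTR, or noncoding-exonic) by
   majority-bp overlap.
2. **Normalize frequencies** — per sample, TPM = ME calls per million
   assembled transcripts (a study-specific unit, *not* expression TPM);
   TPMPM = TPM per million genomic ME copies of the class,
   `tpmpm = tpm / (census / 10^6)`, which compares classes on a per-copy
   basis.
3. **Profile ME ages** — % divergence from the subfamily consensus is the
   age proxy; per-class normalized histograms are compared by two-sample
   Kolmogorov–Smirnov tests and peak (mode) shifts.
4. **Assay splice junctions in raw reads** — for a gene with a known
   ME-retaining form, a 20-bp probe pair (10 bp each side of the divergence
   junction, one probe per splice form) is searched exactly, on both
   strands, in each sample's FASTQ. This yields per-sample counts, RPM, and
   the ME-rate `me / (me + normal)`, plus an ORF-impact prediction
   (premature stop, truncated tail length) for the retained sequence.
5. **Compare groups** — ANOVA with Student–Newman–Keuls post hoc tests when
   every group passes Shapiro–Wilk, otherwise Kruskal–Wallis with Nemenyi
   (or pairwise Wilcoxon rank-sum for very small groups); unpaired
   two-tailed t-tests for junction assays; two-sided p-values starred at
   0.05 / 0.01 / 0.001.
6. **Simulate** — a synthetic-data generator builds a self-consistent world
   (genome, gene models, planted intronic MEs with class-specific divergence
   distributions, four sample groups with a planted retention-rate gradient,
   junction-spanning paired-end reads) with exact truth tables, so the whole
   pipeline is testable without any download.

## Worked example

Generate a small synthetic TLE-HS sample and call its ME-transcripts:

```bash
mesplice call --sample-id TLE_HS_1 \
    --transcripts TLE_HS_1.fa --repeats TLE_HS_1.fa.out \
    --psl TLE_HS_1.psl --refgene refGene.txt --out calls.tsv
# 34 calls from 2003 transcripts (all-exon TPM 16974.5)
```

34 of ~2,000 assembled transcripts carry a retained intronic ME, i.e. an
all-exon frequency of ≈17,000 per million transcripts. The call table has
one row per (transcript, ME) pair:

```
sample     transcript        gene      accession  subfamily class family divergence_pct tx_begin tx_end genome_intervals      region            aligned_fraction
TLE_HS_1   TLE_HS_1.mt00000  GENE0024  NM_100024  MIRb      SINE  MIR    10.6           1274     1400   chr1:891066-891192    cds               1.0
TLE_HS_1   TLE_HS_1.mt00001  GENE0109  NR_100109  L1PA2     LINE  L1     38.7           2180     2284   chr1:3864081-3864185  noncoding_exonic  1.0
```

Quantify the abnormal vs normal splice form of a gene in raw reads (here
the bundled SCN1A-like fixture, whose ME form retains an 87-bp L1PA2
segment after the exon-17 donor site):

```bash
mesplice junction --gene SCN1A_SYN --refgene scn1a.refGene.txt \
    --normal scn1a_normal.fa --me scn1a_me.fa \
    --reads tle_sample.fastq --total-reads 2000
# {"gene": "SCN1A_SYN", "normal_count": 716, "me_count": 284,
#  "normal_rpm": 358000.0, "me_rpm": 142000.0, "me_rate": 0.284}
```

Of the 1,000 junction-spanning read pairs in this sample, 284 reads support
the ME-retaining form — an ME-rate of 28.4%. In the Python API,
`predict_orf_impact` on the same fixture reports a 1,980-aa normal protein,
`premature_stop=True`, and a truncated tail of 1,307 residues.

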