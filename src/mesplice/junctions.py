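"""Splice-junction probe assays for abnormal (ME-retaining) transcripts.

For a gene with a known ME-retaining splice form, the normal mRNA and the
ME-transcript share a 5' block and diverge where the retained intron/ME
sequence begins.  A 20-bp probe pair (10 bp on each side of the junction in
each form) is searched, as exact substrings on either strand, in the raw
reads of every sample; counts yield RPM values and the ME-rate
(ME reads / (ME + normal reads)).  The ORF impact of the retained sequence
is predicted by in-frame translation up to the first stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .io import iter_fastq
from .model import GeneModel, MINUS
from .stats import GroupComparisonResult, compare_groups, ttest_pairwise

_RC = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class SampleAssay:
    group: str
    normal_count: int
    me_count: int
    total_reads: int
    normal_rpm: float
    me_rpm: float
    me_rate: float | None  # None when no junction reads at all

    @property
    def total_rpm(self) -> float:
        return self.normal_rpm + self.me_rpm


@dataclass
class JunctionAssay:
    gene_symbol: str
    junction_chrom_pos: tuple[str, int]
    normal_probe: str
    me_probe: str
    samples: dict[str, SampleAssay] = field(default_factory=dict)


@dataclass
class OrfImpact:
    normal_protein_length: int
    divergence_aa_pos: int
    premature_stop: bool
    truncated_tail_aa: int
    utr_only: bool = False


def find_divergence_junction(
    normal_mrna: str, me_transcript: str
) -> tuple[int, int]:
    """Locate the first position where the two splice forms differ.

    Returns the length of the longest common prefix as (offset_in_normal,
    offset_in_me), anchored on the mRNA plus strand.  Identical sequences
    have no divergence point; a common prefix under 20 bp would make probes
    ambiguous — both are errors.
    """
    a, b = normal_mrna.upper(), me_transcript.upper()
    limit = min(len(a), len(b))
    lcp = 0
    while lcp < limit and a[lcp] == b[lcp]:
        lcp += 1
    if lcp == len(a) and lcp == len(b):
        raise ValueError("sequences are identical: no divergence junction")
    if lcp < 20:
        raise ValueError(
            f"common 5' block is only {lcp} bp (< 20): probes would be ambiguous"
        )
    return lcp, lcp


def build_probes(
    normal_mrna: str,
    me_transcript: str,
    junction: tuple[int, int],
    flank: int = 10,
) -> tuple[str, str]:
    """Extract the probe pair spanning the junction (``flank`` bp each side)."""
    j_normal, j_me = junction
    if j_normal < flank or j_me < flank:
        raise ValueError("insufficient upstream sequence for probe")
    if len(normal_mrna) < j_normal + flank or len(me_transcript) < j_me + flank:
        raise ValueError("insufficient downstream sequence for probe")
    normal_probe = normal_mrna[j_normal - flank : j_normal + flank].upper()
    me_probe = me_transcript[j_me - flank : j_me + flank].upper()
    if normal_probe == me_probe:
        raise ValueError("probes identical: junction does not separate the forms")
    return normal_probe, me_probe


def _reads_iter(reads: str | PathLike | Iterable[str]) -> Iterable[str]:
    if isinstance(reads, (str, PathLike)):
        return iter_fastq(reads)
    return reads


def count_probe_reads(probe: str, reads: str | PathLike | Iterable[str]) -> int:
    """Reads containing the probe or its reverse complement, once per read."""
    probe = probe.upper()
    rc = revcomp(probe)
    n = 0
    for read in _reads_iter(reads):
        r = read.upper()
        if probe in r or rc in r:
            n += 1
    return n


def count_probe_pair(
    normal_probe: str, me_probe: str, reads: str | PathLike | Iterable[str]
) -> tuple[int, int]:
    """Count both probes in one pass.

    A read matching both probes would mean the probes share their informative
    sequence, which the construction excludes — that is an assertion failure,
    never a silent double count.
    """
    np_, mp = normal_probe.upper(), me_probe.upper()
    np_rc, mp_rc = revcomp(np_), revcomp(mp)
    n_normal = n_me = 0
    for read in _reads_iter(reads):
        r = read.upper()
        hit_n = np_ in r or np_rc in r
        hit_m = mp in r or mp_rc in r
        assert not (hit_n and hit_m), "read matches both junction probes"
        if hit_n:
            n_normal += 1
        elif hit_m:
            n_me += 1
    return n_normal, n_me


def spliced_mrna(gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Mature mRNA of the isoform: exons joined, reverse-complemented on minus."""
    chrom = genome[gene.chrom]
    seq = "".join(chrom[s:e] for s, e in gene.exons)
    return revcomp(seq) if gene.strand == MINUS else seq


def mrna_offset_to_genome(gene: GeneModel, offset: int) -> int:
    """Genomic coordinate of an mRNA offset (transcription order)."""
    exons = gene.exons if gene.strand != MINUS else list(reversed(gene.exons))
    pos = offset
    for s, e in exons:
        size = e - s
        if pos < size:
            return s + pos if gene.strand != MINUS else e - 1 - pos
        pos -= size
    raise ValueError(f"offset {offset} beyond mRNA of {gene.accession}")


def cds_offsets_in_mrna(gene: GeneModel) -> tuple[int, int]:
    """(start, end) of the CDS within the mature mRNA, transcription order."""
    if not gene.coding:
        raise ValueError(f"{gene.accession} is noncoding")
    before = 0
    inside = 0
    for s, e in gene.exons:
        before += max(0, min(e, gene.cds_start) - s)
        inside += max(0, min(e, gene.cds_end) - max(s, gene.cds_start))
    if gene.strand == MINUS:
        after = gene.mrna_length - before - inside
        return after, after + inside
    return before, before + inside


def assay_gene(
    gene: GeneModel,
    normal_mrna: str,
    me_transcript: str,
    samples: Mapping[str, tuple[str | PathLike | Iterable[str], int, str]],
    flank: int = 10,
) -> JunctionAssay:
    """Run the junction assay for one gene across samples.

    ``samples`` maps sample_id -> (reads, total_reads, group); reads may be a
    FASTQ path or an iterable of sequences.  Samples with zero junction reads
    carry ``me_rate = None`` and are excluded from group testing.
    """
    junction = find_divergence_junction(normal_mrna, me_transcript)
    normal_probe, me_probe = build_probes(
        normal_mrna, me_transcript, junction, flank=flank
    )
    genome_pos = mrna_offset_to_genome(gene, junction[0] - 1)
    assay = JunctionAssay(
        gene_symbol=gene.gene_symbol,
        junction_chrom_pos=(gene.chrom, genome_pos),
        normal_probe=normal_probe,
        me_probe=me_probe,
    )
    for sample_id, (reads, total_reads, group) in samples.items():
        if total_reads <= 0:
            raise ValueError(f"{sample_id}: total_reads must be positive")
        n_normal, n_me = count_probe_pair(normal_probe, me_probe, reads)
        denom = n_normal + n_me
        assay.samples[sample_id] = SampleAssay(
            group=group,
            normal_count=n_normal,
            me_count=n_me,
            total_reads=total_reads,
            normal_rpm=n_normal / total_reads * 1e6,
            me_rpm=n_me / total_reads * 1e6,
            me_rate=(n_me / denom) if denom > 0 else None,
        )
    return assay


def compare_assay_groups(assay: JunctionAssay) -> dict[str, GroupComparisonResult]:
    """Pairwise unpaired two-tailed t-tests on me_rate, normal RPM, total RPM.

    Samples without a defined me_rate are excluded from the me_rate variable
    (but still contribute RPM values).
    """
    results: dict[str, GroupComparisonResult] = {}
    for variable, getter, defined_only in (
        ("me_rate", lambda s: s.me_rate, True),
        ("normal_rpm", lambda s: s.normal_rpm, False),
        ("total_rpm", lambda s: s.total_rpm, False),
    ):
        groups: dict[str, list[float]] = {}
        for s in assay.samples.values():
            v = getter(s)
            if defined_only and v is None:
                continue
            groups.setdefault(s.group, []).append(float(v))
        groups = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:
            raise ValueError(f"{variable}: need >=2 groups with >=2 values")
        res = compare_groups(groups, force_test="anova", variable=variable)
        res.posthoc_test = "t"
        res.pairwise_p = ttest_pairwise(
            {g: np.asarray(v) for g, v in groups.items()}
        )
        results[variable] = res
    return results


def _translate_to_stop(cds: str) -> tuple[int, bool]:
    """(aa before stop, stop seen) translating in frame from position 0."""
    aa = 0
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3].upper()
        if str(Seq(codon).translate()) == "*":
            return aa, True
        aa += 1
    return aa, False


def predict_orf_impact(
    me_transcript: str,
    gene: GeneModel,
    genome: Mapping[str, str],
) -> OrfImpact:
    """Predict the protein-level consequence of the retained ME sequence.

    The normal CDS is spliced from the genome; the ME-form coding sequence is
    the shared 5' portion followed by the ME-transcript's own continuation,
    translated in the normal frame to the first stop.  A junction upstream of
    the CDS start is reported as UTR-only (no stop-codon impact).  A retained
    segment that re-enters the original frame without a stop is an in-frame
    insertion (``premature_stop`` False).
    """
    if not gene.coding:
        raise ValueError(f"{gene.accession} is noncoding")
    mrna = spliced_mrna(gene, genome)
    cds_start, cds_end = cds_offsets_in_mrna(gene)
    normal_cds = mrna[cds_start:cds_end]
    normal_len, _ = _translate_to_stop(normal_cds)
    junction, _ = find_divergence_junction(mrna, me_transcript)
    if junction <= cds_start:
        return OrfImpact(
            normal_protein_length=normal_len,
            divergence_aa_pos=0,
            premature_stop=False,
            truncated_tail_aa=0,
            utr_only=True,
        )
    divergence_aa = min((junction - cds_start) // 3, normal_len)
    me_cds = me_transcript[cds_start:]
    me_len, stop_seen = _translate_to_stop(me_cds)
    premature = stop_seen and me_len < normal_len
    return OrfImpact(
        normal_protein_length=normal_len,
        divergence_aa_pos=divergence_aa,
        premature_stop=premature,
        truncated_tail_aa=max(0, normal_len - me_len) if premature else 0,
    )


def write_assay_report(assay: JunctionAssay, path: str | PathLike) -> None:
    """Tab-delimited per-sample assay report."""
    with open(path, "w") as fh:
        fh.write(
            "sample\tgroup\tnormal_count\tme_count\tnormal_rpm\tme_rpm\tme_rate\n"
        )
        for sid, s in assay.samples.items():
            rate = "" if s.me_rate is None else f"{s.me_rate:.4f}"
            fh.write(
                f"{sid}\t{s.group}\t{s.normal_count}\t{s.me_count}\t"
                f"{s.normal_rpm:.3f}\t{s.me_rpm:.3f}\t{rate}\n"
            )
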