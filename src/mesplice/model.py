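"""Core domain types shared across the pipeline.

All coordinates are 0-based, half-open, on the plus strand of the target
sequence (transcript or chromosome).  Conversions from the 1-based or
reversed-query conventions of the on-disk formats happen only in
:mod:`mesplice.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

#: The five mobile-element classes tracked by the pipeline.  Everything else
#: (simple repeats, low complexity, satellites, rRNA, ...) is "Other".
ME_CLASSES = ("SINE", "LINE", "LTR", "DNA", "SVA")

#: Gene-region labels for an ME occurrence inside a transcript.
REGIONS = ("five_prime_utr", "cds", "three_prime_utr", "noncoding_exonic")

PLUS = "+"
MINUS = "-"


def repeat_class_of(class_family: str) -> tuple[str, str]:
    """Split a RepeatMasker class/family field into (class, family).

    The class is the token left of "/"; families of the five ME classes map
    directly, SVA (annotated by RepeatMasker as ``Retroposon/SVA``) maps to
    SVA, and anything else (Simple_repeat, Low_complexity, Satellite, ...)
    maps to "Other".
    """
    left, _, family = class_family.partition("/")
    if left in ME_CLASSES:
        return left, family or left
    if left == "Retroposon" and family == "SVA":
        return "SVA", "SVA"
    return "Other", family or left


@dataclass(frozen=True)
class RepeatAnnotation:
    """One RepeatMasker hit on a target sequence (transcript or chromosome)."""

    target_id: str
    target_begin: int
    target_end: int
    repeat_subfamily: str
    repeat_class: str
    repeat_family: str
    divergence_pct: float
    orientation: str = PLUS
    sw_score: int = 0

    def __post_init__(self) -> None:
        if not self.target_begin < self.target_end:
            raise ValueError(
                f"repeat on {self.target_id}: begin {self.target_begin} "
                f">= end {self.target_end}"
            )
        if not 0.0 <= self.divergence_pct <= 100.0:
            raise ValueError(f"divergence {self.divergence_pct} outside [0, 100]")
        if self.orientation not in (PLUS, MINUS):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.sw_score < 0:
            raise ValueError("negative Smith-Waterman score")

    @property
    def length(self) -> int:
        return self.target_end - self.target_begin


@dataclass(frozen=True)
class GeneModel:
    """One gene isoform's genomic structure (refGene.txt semantics)."""

    gene_symbol: str
    accession: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exon_starts", tuple(self.exon_starts))
        object.__setattr__(self, "exon_ends", tuple(self.exon_ends))
        if self.strand not in (PLUS, MINUS):
            raise ValueError(f"{self.accession}: bad strand {self.strand!r}")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.accession}: CDS bounds outside transcript")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(f"{self.accession}: exon list length mismatch")
        prev_end = self.tx_start - 1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.accession}: exon [{s},{e}) outside transcript")
            if s <= prev_end:
                raise ValueError(f"{self.accession}: exons overlap or unsorted")
            prev_end = e

    @property
    def coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def exons(self) -> list[tuple[int, int]]:
        return list(zip(self.exon_starts, self.exon_ends))

    @property
    def cds_length(self) -> int:
        """Total coding bases across exons (0 for noncoding isoforms)."""
        return sum(
            max(0, min(e, self.cds_end) - max(s, self.cds_start))
            for s, e in zip(self.exon_starts, self.exon_ends)
        )

    @property
    def mrna_length(self) -> int:
        return sum(e - s for s, e in zip(self.exon_starts, self.exon_ends))


@dataclass(frozen=True)
class TranscriptAlignment:
    """A blocked transcript-to-genome alignment (PSL semantics).

    ``blocks`` are (q_start, t_start, size) triples with q_start always in
    plus-strand query coordinates, sorted by q_start, non-overlapping in both
    query and target.  ``target_size`` is the chromosome length (PSL tSize).
    """

    query_id: str
    query_length: int
    strand: str
    target_chrom: str
    target_size: int
    matches: int
    mismatches: int
    q_gap_count: int
    t_gap_count: int
    blocks: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "blocks", tuple(tuple(b) for b in self.blocks)
        )
        if self.strand not in (PLUS, MINUS):
            raise ValueError(f"{self.query_id}: bad strand {self.strand!r}")
        if not self.blocks:
            raise ValueError(f"{self.query_id}: alignment has no blocks")
        total = 0
        prev_q = -1
        for q, t, size in self.blocks:
            if size <= 0:
                raise ValueError(f"{self.query_id}: non-positive block size")
            if q < prev_q:
                raise ValueError(f"{self.query_id}: blocks not sorted by q_start")
            if q < 0 or t < 0:
                raise ValueError(f"{self.query_id}: negative block coordinate")
            prev_q = q
            total += size
        if total > self.query_length:
            raise ValueError(f"{self.query_id}: blocks exceed query length")
        for name, key in (("query", 0), ("target", 1)):
            spans = sorted((b[key], b[key] + b[2]) for b in self.blocks)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(f"{self.query_id}: blocks overlap in {name}")

    @property
    def score(self) -> int:
        """Selection score: matches minus mismatches and gap openings."""
        return self.matches - self.mismatches - self.q_gap_count - self.t_gap_count

    @property
    def target_intervals(self) -> list[tuple[str, int, int]]:
        """Genomic footprint of the aligned blocks, merged where adjacent."""
        out: list[tuple[str, int, int]] = []
        for t_start, t_end in sorted((t, t + sz) for _, t, sz in self.blocks):
            if out and t_start <= out[-1][2]:
                out[-1] = (self.target_chrom, out[-1][1], max(out[-1][2], t_end))
            else:
                out.append((self.target_chrom, t_start, t_end))
        return out


@dataclass(frozen=True)
class MeTranscriptCall:
    """One mobile-element occurrence in one assembled transcript.

    The transcript maps to a known gene; the ME's transcript interval is
    projected through the alignment to genomic coordinates and labelled with
    the gene region it falls in.
    """

    sample_id: str
    transcript_id: str
    transcript_length: int
    gene_symbol: str
    gene_accession: str
    me: RepeatAnnotation
    genome_intervals: tuple[tuple[str, int, int], ...]
    region: str
    aligned_fraction: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "genome_intervals", tuple(tuple(i) for i in self.genome_intervals)
        )
        if self.transcript_length <= 0:
            raise ValueError("non-positive transcript length")
        if not self.genome_intervals:
            raise ValueError("call without genomic projection")
        if self.region not in REGIONS:
            raise ValueError(f"bad region label {self.region!r}")
        if not 0.0 <= self.aligned_fraction <= 1.0:
            raise ValueError("aligned_fraction outside [0, 1]")


def merge_intervals(
    intervals: Sequence[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Merge overlapping or book-ended (chrom, start, end) intervals."""
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in sorted(intervals):
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], e))
        else:
            out.append((chrom, s, e))
    return out
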