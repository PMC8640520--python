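"""Identify mobile-element-containing transcripts and localize each ME.

The core procedure: for each assembled transcript with a RepeatMasker ME hit,
pick its best genome alignment, project the whole transcript and the ME
interval to genomic coordinates, find the host gene by exonic overlap, and
label the ME's gene region (5' UTR / CDS / 3' UTR, or noncoding-exonic for
noncoding isoforms).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections import Counter, defaultdict
from os import PathLike
from typing import Iterable, Mapping, Sequence

from .io import fasta_lengths
from .model import (
    GeneModel,
    ME_CLASSES,
    MINUS,
    MeTranscriptCall,
    RepeatAnnotation,
    TranscriptAlignment,
    merge_intervals,
)

log = logging.getLogger(__name__)

Interval = tuple[str, int, int]

#: Tie priority for region labels (applied after majority-bp vote).
REGION_PRIORITY = ("cds", "three_prime_utr", "five_prime_utr")


def select_best_alignment(
    alignments: Sequence[TranscriptAlignment],
) -> TranscriptAlignment:
    """Pick the best of several genome hits for one query.

    Maximizes ``matches - mismatches - q_gap_count - t_gap_count``; ties go
    to the lexicographically smallest (target_chrom, first t_start).
    """
    if not alignments:
        raise ValueError("no alignments supplied")
    return min(
        alignments,
        key=lambda a: (-a.score, a.target_chrom, min(t for _, t, _ in a.blocks)),
    )


def project_to_genome(
    aln: TranscriptAlignment, q_interval: tuple[int, int]
) -> list[Interval]:
    """Project a query (transcript) interval through the alignment blocks.

    Returns the target sub-intervals of every block overlapping the query
    interval, merged where adjacent.  Bases of the query interval falling in
    alignment gaps are simply not projected, so the total projected length is
    at most ``end - start``.  An interval entirely inside gaps projects to [].
    On minus-strand alignments ascending query positions run against the
    target, so block offsets are mirrored.
    """
    q_start, q_end = q_interval
    if q_start >= q_end or q_start < 0 or q_end > aln.query_length:
        raise ValueError(f"bad query interval {q_interval}")
    pieces: list[Interval] = []
    for q, t, size in aln.blocks:
        lo = max(q_start, q)
        hi = min(q_end, q + size)
        if lo < hi:
            if aln.strand == MINUS:
                pieces.append(
                    (aln.target_chrom, t + size - (hi - q), t + size - (lo - q))
                )
            else:
                pieces.append((aln.target_chrom, t + (lo - q), t + (hi - q)))
    return merge_intervals(pieces)


class GeneIndex:
    """Interval lookup over gene isoforms, per chromosome.

    Sorted-by-start lists with a running max of tx_end allow the overlap
    scan to stop early; gene counts here are small enough that this is fast
    without an interval tree.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self._by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
        for g in genes:
            self._by_chrom[g.chrom].append(g)
        self._starts: dict[str, list[int]] = {}
        self._cummax_end: dict[str, list[int]] = {}
        for chrom, gs in self._by_chrom.items():
            gs.sort(key=lambda g: (g.tx_start, g.tx_end))
            self._starts[chrom] = [g.tx_start for g in gs]
            cm, hi = [], 0
            for g in gs:
                hi = max(hi, g.tx_end)
                cm.append(hi)
            self._cummax_end[chrom] = cm

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        gs = self._by_chrom.get(chrom)
        if not gs:
            return []
        hi = bisect_right(self._starts[chrom], end - 1)
        out = []
        for i in range(hi - 1, -1, -1):
            if self._cummax_end[chrom][i] <= start:
                break
            g = gs[i]
            if g.tx_end > start:
                out.append(g)
        out.reverse()
        return out


def _overlap_bp(intervals: Sequence[Interval], chrom: str, start: int, end: int) -> int:
    return sum(
        max(0, min(e, end) - max(s, start))
        for c, s, e in intervals
        if c == chrom and start < end
    )


def exonic_overlap(projection: Sequence[Interval], gene: GeneModel) -> int:
    """Base pairs of the projected intervals overlapping the gene's exons."""
    return sum(
        _overlap_bp(projection, gene.chrom, s, e)
        for s, e in zip(gene.exon_starts, gene.exon_ends)
    )


def assign_gene(
    projection: Sequence[Interval], genes: GeneIndex
) -> GeneModel | None:
    """Find the gene isoform with maximal exonic overlap with the projection.

    Requires at least 1 bp of exonic overlap; returns None otherwise.
    Isoform ties go to the longest CDS, then to the lexicographically
    smallest accession.
    """
    candidates: dict[str, GeneModel] = {}
    for chrom, start, end in projection:
        for g in genes.overlapping(chrom, start, end):
            candidates[g.accession] = g
    scored = [
        (exonic_overlap(projection, g), g) for g in candidates.values()
    ]
    scored = [(ov, g) for ov, g in scored if ov >= 1]
    if not scored:
        return None
    # max overlap; ties by longest CDS, then smallest accession
    return min(scored, key=lambda t: (-t[0], -t[1].cds_length, t[1].accession))[1]


def assign_region(me_projection: Sequence[Interval], gene: GeneModel) -> str:
    """Label the ME's gene region by majority base-pair overlap.

    Noncoding isoforms get ``noncoding_exonic``.  For coding genes the ME
    projection is compared against the three genomic spans
    [tx_start, cds_start), [cds_start, cds_end), [cds_end, tx_end); 5'/3'
    labels are swapped on the minus strand; ties break cds >
    three_prime_utr > five_prime_utr.
    """
    if not gene.coding:
        return "noncoding_exonic"
    left_label = "three_prime_utr" if gene.strand == MINUS else "five_prime_utr"
    right_label = "five_prime_utr" if gene.strand == MINUS else "three_prime_utr"
    overlaps = {
        left_label: _overlap_bp(me_projection, gene.chrom, gene.tx_start, gene.cds_start),
        "cds": _overlap_bp(me_projection, gene.chrom, gene.cds_start, gene.cds_end),
        right_label: _overlap_bp(me_projection, gene.chrom, gene.cds_end, gene.tx_end),
    }
    if sum(overlaps.values()) == 0:
        raise ValueError(
            f"ME projection does not overlap gene span of {gene.accession}"
        )
    best = max(overlaps.values())
    for label in REGION_PRIORITY:
        if overlaps[label] == best:
            return label
    raise AssertionError("unreachable")


def merge_repeat_fragments(
    repeats: Iterable[RepeatAnnotation], max_gap: int = 10
) -> list[RepeatAnnotation]:
    """Merge fragmented RepeatMasker rows of the same element.

    Rows on the same target with identical subfamily and orientation that are
    less than ``max_gap`` bp apart are collapsed into one annotation with a
    length-weighted mean divergence and the maximum score.
    """
    groups: dict[tuple[str, str, str], list[RepeatAnnotation]] = defaultdict(list)
    order: list[RepeatAnnotation] = []
    for r in repeats:
        groups[(r.target_id, r.repeat_subfamily, r.orientation)].append(r)
    out: list[RepeatAnnotation] = []
    for key, rows in groups.items():
        rows.sort(key=lambda r: r.target_begin)
        run = [rows[0]]
        for r in rows[1:]:
            if r.target_begin - run[-1].target_end < max_gap:
                run.append(r)
            else:
                out.append(_collapse(run))
                run = [r]
        out.append(_collapse(run))
    out.sort(key=lambda r: (r.target_id, r.target_begin))
    return out


def _collapse(rows: list[RepeatAnnotation]) -> RepeatAnnotation:
    if len(rows) == 1:
        return rows[0]
    total = sum(r.length for r in rows)
    div = sum(r.divergence_pct * r.length for r in rows) / total
    first = rows[0]
    return RepeatAnnotation(
        target_id=first.target_id,
        target_begin=first.target_begin,
        target_end=max(r.target_end for r in rows),
        repeat_subfamily=first.repeat_subfamily,
        repeat_class=first.repeat_class,
        repeat_family=first.repeat_family,
        divergence_pct=round(div, 4),
        orientation=first.orientation,
        sw_score=max(r.sw_score for r in rows),
    )


def call_me_transcripts(
    sample_id: str,
    transcripts: str | PathLike | Mapping[str, str] | Mapping[str, int] | None,
    repeats: Sequence[RepeatAnnotation],
    alignments: Sequence[TranscriptAlignment],
    genes: GeneIndex,
    min_length: int = 300,
    min_aligned_fraction: float = 0.5,
    merge_gap: int = 10,
) -> list[MeTranscriptCall]:
    """Run the full ME-transcript identification for one sample.

    ``transcripts`` supplies transcript lengths: a FASTA path, a mapping
    id -> sequence, a mapping id -> length, or None to fall back on the
    alignments' query lengths.  One call is produced per (transcript, merged
    ME hit) pair that survives all filters: transcript length >=
    ``min_length``; repeat class one of SINE/LINE/LTR/DNA/SVA; an alignment
    exists; the ME projects to the genome with aligned fraction >=
    ``min_aligned_fraction``; and a host gene is found by exonic overlap.
    Drop reasons are tallied to the module logger.
    """
    if isinstance(transcripts, (str, PathLike)):
        lengths: dict[str, int] = fasta_lengths(transcripts)
    elif transcripts is None:
        lengths = {a.query_id: a.query_length for a in alignments}
    else:
        lengths = {
            k: (len(v) if isinstance(v, str) else int(v))
            for k, v in transcripts.items()
        }

    by_query: dict[str, list[TranscriptAlignment]] = defaultdict(list)
    for a in alignments:
        by_query[a.query_id].append(a)

    dropped: Counter[str] = Counter()
    calls: list[MeTranscriptCall] = []
    for me in merge_repeat_fragments(repeats, max_gap=merge_gap):
        tid = me.target_id
        if me.repeat_class not in ME_CLASSES:
            dropped["repeat_class_other"] += 1
            continue
        length = lengths.get(tid)
        if length is None:
            dropped["no_transcript_record"] += 1
            continue
        if length < min_length:
            dropped["short_transcript"] += 1
            continue
        alns = by_query.get(tid)
        if not alns:
            dropped["no_alignment"] += 1
            continue
        best = select_best_alignment(alns)
        me_proj = project_to_genome(best, (me.target_begin, me.target_end))
        projected = sum(e - s for _, s, e in me_proj)
        frac = projected / me.length
        if not me_proj or frac < min_aligned_fraction:
            dropped["me_not_projected"] += 1
            continue
        tx_proj = best.target_intervals
        gene = assign_gene(tx_proj, genes)
        if gene is None:
            dropped["no_gene"] += 1
            continue
        try:
            region = assign_region(me_proj, gene)
        except ValueError:
            dropped["me_outside_gene_span"] += 1
            continue
        calls.append(
            MeTranscriptCall(
                sample_id=sample_id,
                transcript_id=tid,
                transcript_length=length,
                gene_symbol=gene.gene_symbol,
                gene_accession=gene.accession,
                me=me,
                genome_intervals=tuple(me_proj),
                region=region,
                aligned_fraction=frac,
            )
        )
    if dropped:
        log.info(
            "%s: %d calls; dropped %s",
            sample_id,
            len(calls),
            dict(dropped),
        )
    return calls


def write_call_table(calls: Sequence[MeTranscriptCall], path: str | PathLike) -> None:
    """Tab-delimited call table, one row per (transcript, ME) call."""
    cols = [
        "sample", "transcript", "gene", "accession", "subfamily", "class",
        "family", "divergence_pct", "tx_begin", "tx_end", "genome_intervals",
        "region", "aligned_fraction",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            gi = ";".join(f"{ch}:{s}-{e}" for ch, s, e in c.genome_intervals)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        c.sample_id, c.transcript_id, c.gene_symbol,
                        c.gene_accession, c.me.repeat_subfamily,
                        c.me.repeat_class, c.me.repeat_family,
                        c.me.divergence_pct, c.me.target_begin,
                        c.me.target_end, gi, c.region,
                        round(c.aligned_fraction, 4),
                    )
                )
                + "\n"
            )


def write_bed(calls: Sequence[MeTranscriptCall], path: str | PathLike) -> None:
    """BED export of the ME genome intervals."""
    with open(path, "w") as fh:
        for c in calls:
            for chrom, s, e in c.genome_intervals:
                name = f"{c.transcript_id}|{c.me.repeat_subfamily}|{c.region}"
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t{c.me.orientation}\n")
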