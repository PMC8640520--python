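"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results per base / per element, independent of
the library's interval arithmetic, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

from mesplice.model import GeneModel, MINUS, PLUS, TranscriptAlignment


def random_gene_model(rng: np.random.Generator, chrom: str = "chrT") -> GeneModel:
    """A small random gene isoform (coding ~80% of the time)."""
    n_exons = int(rng.integers(1, 7))
    pos = int(rng.integers(0, 500))
    starts, ends = [], []
    for i in range(n_exons):
        starts.append(pos)
        pos += int(rng.integers(20, 120))
        ends.append(pos)
        pos += int(rng.integers(10, 200))
    tx_start, tx_end = starts[0], ends[-1]
    if rng.random() < 0.8:
        a = int(rng.integers(tx_start, tx_end))
        b = int(rng.integers(tx_start, tx_end))
        cds_start, cds_end = min(a, b), max(a, b)
        if cds_start == cds_end:
            cds_end = min(tx_end, cds_end + 1)
    else:
        cds_start = cds_end = tx_start
    return GeneModel(
        gene_symbol="RND",
        accession=f"NM_{int(rng.integers(0, 10**6)):06d}",
        chrom=chrom,
        strand=PLUS if rng.random() < 0.5 else MINUS,
        tx_start=tx_start,
        tx_end=tx_end,
        cds_start=cds_start,
        cds_end=cds_end,
        exon_starts=tuple(starts),
        exon_ends=tuple(ends),
    )


def random_me_projection(
    rng: np.random.Generator, gene: GeneModel
) -> list[tuple[str, int, int]]:
    """1-3 disjoint intervals overlapping the gene span."""
    n = int(rng.integers(1, 4))
    picks = []
    for _ in range(n):
        s = int(rng.integers(gene.tx_start, gene.tx_end))
        e = s + int(rng.integers(1, 80))
        picks.append((s, min(e, gene.tx_end + 50)))
    picks.sort()
    merged: list[tuple[str, int, int]] = []
    for s, e in picks:
        if merged and s <= merged[-1][2]:
            merged[-1] = (gene.chrom, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append((gene.chrom, s, e))
    return merged


def brute_force_region(
    projection: list[tuple[str, int, int]], gene: GeneModel
) -> tuple[str, bool]:
    """Per-base majority-vote region label.

    Returns (label, was_tie).  Labels the gene region of every projected
    base individually, then takes the majority; ties are resolved by the
    documented priority cds > three_prime_utr > five_prime_utr.
    """
    if not gene.coding:
        return "noncoding_exonic", False
    left = "three_prime_utr" if gene.strand == MINUS else "five_prime_utr"
    right = "five_prime_utr" if gene.strand == MINUS else "three_prime_utr"
    counts = {left: 0, "cds": 0, right: 0}
    for chrom, s, e in projection:
        if chrom != gene.chrom:
            continue
        for g in range(s, e):
            if gene.tx_start <= g < gene.cds_start:
                counts[left] += 1
            elif gene.cds_start <= g < gene.cds_end:
                counts["cds"] += 1
            elif gene.cds_end <= g < gene.tx_end:
                counts[right] += 1
    if sum(counts.values()) == 0:
        raise ValueError("projection outside gene span")
    best = max(counts.values())
    winners = [k for k, v in counts.items() if v == best]
    for label in ("cds", "three_prime_utr", "five_prime_utr"):
        if label in winners:
            return label, len(winners) > 1
    raise AssertionError


def brute_force_projection(
    aln: TranscriptAlignment, q_interval: tuple[int, int]
) -> list[tuple[str, int, int]]:
    """Per-base query->target mapping, merged into intervals."""
    targets = set()
    for q, t, size in aln.blocks:
        for d in range(size):
            qq = q + d
            if q_interval[0] <= qq < q_interval[1]:
                tt = t + (size - 1 - d) if aln.strand == MINUS else t + d
                targets.add(tt)
    out: list[tuple[str, int, int]] = []
    for tt in sorted(targets):
        if out and tt == out[-1][2]:
            out[-1] = (aln.target_chrom, out[-1][1], tt + 1)
        else:
            out.append((aln.target_chrom, tt, tt + 1))
    return out


def random_alignment(rng: np.random.Generator) -> TranscriptAlignment:
    """Random multi-block alignment, either strand, with gaps on both sides."""
    n_blocks = int(rng.integers(1, 5))
    q = int(rng.integers(0, 10))
    t = int(rng.integers(0, 1000))
    blocks = []
    for _ in range(n_blocks):
        size = int(rng.integers(5, 60))
        blocks.append((q, t, size))
        q += size + int(rng.integers(0, 10))
        t += size + int(rng.integers(1, 400))
    q_len = q + int(rng.integers(0, 20))
    total = sum(b[2] for b in blocks)
    return TranscriptAlignment(
        query_id="rnd",
        query_length=q_len,
        strand=PLUS if rng.random() < 0.5 else MINUS,
        target_chrom="chrT",
        target_size=t + 1000,
        matches=total,
        mismatches=0,
        q_gap_count=n_blocks - 1,
        t_gap_count=n_blocks - 1,
        blocks=tuple(blocks),
    )


def flip_alignment(aln: TranscriptAlignment, chrom_len: int) -> TranscriptAlignment:
    """The same molecule aligned to the reverse-complemented genome."""
    blocks = sorted((q, chrom_len - (t + size), size) for q, t, size in aln.blocks)
    return TranscriptAlignment(
        query_id=aln.query_id,
        query_length=aln.query_length,
        strand=MINUS if aln.strand == PLUS else PLUS,
        target_chrom=aln.target_chrom,
        target_size=aln.target_size,
        matches=aln.matches,
        mismatches=aln.mismatches,
        q_gap_count=aln.q_gap_count,
        t_gap_count=aln.t_gap_count,
        blocks=tuple(blocks),
    )


def flip_gene(gene: GeneModel, chrom_len: int) -> GeneModel:
    """The gene's coordinates on the reverse-complemented genome."""
    starts = tuple(sorted(chrom_len - e for e in gene.exon_ends))
    ends = tuple(sorted(chrom_len - s for s in gene.exon_starts))
    return GeneModel(
        gene_symbol=gene.gene_symbol,
        accession=gene.accession,
        chrom=gene.chrom,
        strand=MINUS if gene.strand == PLUS else PLUS,
        tx_start=chrom_len - gene.tx_end,
        tx_end=chrom_len - gene.tx_start,
        cds_start=chrom_len - gene.cds_end,
        cds_end=chrom_len - gene.cds_start,
        exon_starts=starts,
        exon_ends=ends,
    )
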