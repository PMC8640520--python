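"""Readers and writers for the formats the pipeline touches.

RepeatMasker ``.out`` (read + write), PSL 21-column (read + write), UCSC
refGene.txt (read; a writer exists for the synthetic generator), FASTA
(read) and FASTQ (read, plain or gzipped).  Every reader converts to the
internal convention (0-based, half-open, plus-strand target coordinates);
every writer converts back, so reader(writer(x)) == x field for field.
"""

from __future__ import annotations

import gzip
import logging
from os import PathLike
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .model import (
    GeneModel,
    MINUS,
    PLUS,
    RepeatAnnotation,
    TranscriptAlignment,
    repeat_class_of,
)

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# coordinate conventions


def to_zero_half_open(begin_1based: int, end_inclusive: int) -> tuple[int, int]:
    """1-based inclusive (RepeatMasker) -> 0-based half-open."""
    return begin_1based - 1, end_inclusive


def to_one_based_inclusive(begin: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive.  Inverse of the above."""
    return begin + 1, end


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER = """\
   SW   perc perc perc  query      position in query           matching       repeat              position in repeat
score   div. del. ins.  sequence   begin end          (left)   repeat         class/family      begin  end    (left)   ID

"""


def read_repeatmasker_out(path: str | PathLike) -> list[RepeatAnnotation]:
    """Parse a RepeatMasker ``.out`` file.

    The three header lines are skipped; coordinates are converted from
    1-based inclusive to 0-based half-open; the class/family column is split
    on "/"; a "C" in the strand column means minus orientation.  Simple
    repeats, low-complexity, satellite and similar rows are retained with
    ``repeat_class == "Other"``.
    """
    out: list[RepeatAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if not fields[0].lstrip("-").isdigit():
                continue  # header line
            if len(fields) < 14:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=14 whitespace-delimited "
                    f"columns, got {len(fields)}"
                )
            try:
                sw = int(fields[0])
                div = float(fields[1])
                target_id = fields[4]
                begin, end = to_zero_half_open(int(fields[5]), int(fields[6]))
                orientation = MINUS if fields[8] == "C" else PLUS
                subfamily = fields[9]
                cls, family = repeat_class_of(fields[10])
                out.append(
                    RepeatAnnotation(
                        target_id=target_id,
                        target_begin=begin,
                        target_end=end,
                        repeat_subfamily=subfamily,
                        repeat_class=cls,
                        repeat_family=family,
                        divergence_pct=div,
                        orientation=orientation,
                        sw_score=sw,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: malformed row ({exc})") from exc
    return out


def write_repeatmasker_out(
    annotations: Iterable[RepeatAnnotation], path: str | PathLike
) -> None:
    """Write annotations in RepeatMasker ``.out`` layout (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, ann in enumerate(annotations, start=1):
            begin1, end1 = to_one_based_inclusive(ann.target_begin, ann.target_end)
            if ann.repeat_class == "SVA":
                class_family = "Retroposon/SVA"
            elif ann.repeat_class == "Other":
                class_family = ann.repeat_family
            else:
                class_family = f"{ann.repeat_class}/{ann.repeat_family}"
            strand = "C" if ann.orientation == MINUS else "+"
            fh.write(
                f"{ann.sw_score:>5d} {ann.divergence_pct:5.1f}  0.0  0.0  "
                f"{ann.target_id:<20s} {begin1:>8d} {end1:>8d} (0) "
                f"{strand} {ann.repeat_subfamily:<15s} {class_family:<20s} "
                f"1 {end1 - begin1 + 1} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# PSL


def _int_list(field: str) -> list[int]:
    return [int(x) for x in field.rstrip(",").split(",") if x]


def read_psl(path: str | PathLike) -> list[TranscriptAlignment]:
    """Parse a 21-column PSL file (with or without the 5-line header).

    Minus-strand qStarts are stored by blat in reversed-query coordinates;
    they are normalized here to plus-strand query coordinates via
    ``q_plus = qSize - (q_rev + blockSize)`` and blocks re-sorted by q_start.
    """
    out: list[TranscriptAlignment] = []
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    if lines and lines[0].startswith("psLayout"):
        start = 5
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) != 21:
            raise ValueError(
                f"{path}: line {lineno}: PSL requires 21 columns, got {len(fields)}"
            )
        strand = fields[8]
        q_size = int(fields[10])
        sizes = _int_list(fields[18])
        q_starts = _int_list(fields[19])
        t_starts = _int_list(fields[20])
        n = int(fields[17])
        if not (len(sizes) == len(q_starts) == len(t_starts) == n):
            raise ValueError(
                f"{path}: line {lineno}: blockSizes/qStarts/tStarts lengths "
                f"disagree with blockCount={n}"
            )
        blocks = []
        for size, q, t in zip(sizes, q_starts, t_starts):
            if strand == MINUS:
                q = q_size - (q + size)
            blocks.append((q, t, size))
        blocks.sort()
        out.append(
            TranscriptAlignment(
                query_id=fields[9],
                query_length=q_size,
                strand=strand,
                target_chrom=fields[13],
                target_size=int(fields[14]),
                matches=int(fields[0]),
                mismatches=int(fields[1]),
                q_gap_count=int(fields[4]),
                t_gap_count=int(fields[6]),
                blocks=tuple(blocks),
            )
        )
    return out


_PSL_HEADER = (
    "psLayout version 3\n\n"
    "match\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\tQ        "
    "\tQ   \tQ    \tQ  \tT        \tT   \tT    \tT  \tblock\tblockSizes "
    "\tqStarts\t tStarts\n"
    "     \tmatch\tmatch\t   \tcount\tbases\tcount\tbases\t      \tname     "
    "\tsize\tstart\tend\tname     \tsize\tstart\tend\tcount\n"
    "---------------------------------------------------------------------------------------------------------------------------------------------------------------\n"
)


def write_psl(
    alignments: Iterable[TranscriptAlignment],
    path: str | PathLike,
    header: bool = False,
) -> None:
    """Write alignments as 21-column PSL, restoring blat's conventions."""
    with open(path, "w") as fh:
        if header:
            fh.write(_PSL_HEADER)
        for aln in alignments:
            # PSL rows list blocks in target order; minus-strand qStarts are
            # in reversed-query coordinates.
            blocks = sorted(aln.blocks, key=lambda b: b[1])
            sizes = [b[2] for b in blocks]
            if aln.strand == MINUS:
                q_out = [aln.query_length - (q + size) for q, _, size in blocks]
            else:
                q_out = [q for q, _, _ in blocks]
            t_out = [t for _, t, _ in blocks]
            q_start = min(q for q, _, _ in aln.blocks)
            q_end = max(q + s for q, _, s in aln.blocks)
            t_start = t_out[0]
            t_end = t_out[-1] + sizes[-1]
            q_gap_bases = (q_end - q_start) - sum(sizes)
            t_gap_bases = (t_end - t_start) - sum(sizes)
            row = [
                aln.matches,
                aln.mismatches,
                0,
                0,
                aln.q_gap_count,
                max(0, q_gap_bases),
                aln.t_gap_count,
                max(0, t_gap_bases),
                aln.strand,
                aln.query_id,
                aln.query_length,
                q_start,
                q_end,
                aln.target_chrom,
                aln.target_size,
                t_start,
                t_end,
                len(blocks),
                ",".join(map(str, sizes)) + ",",
                ",".join(map(str, q_out)) + ",",
                ",".join(map(str, t_out)) + ",",
            ]
            fh.write("\t".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# refGene.txt


def read_refgene(path: str | PathLike) -> list[GeneModel]:
    """Parse a UCSC refGene.txt table (16 tab-separated columns).

    Starts are 0-based, ends exclusive; exon lists are comma-terminated.
    ``cdsStart == cdsEnd`` (NR_ records) is preserved as the noncoding flag.
    """
    out: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 16:
                raise ValueError(
                    f"{path}: refGene rows need 16 columns, got {len(f)}"
                )
            accession = f[1]
            exon_starts = _int_list(f[9])
            exon_ends = _int_list(f[10])
            if len(exon_starts) != len(exon_ends) or len(exon_starts) != int(f[8]):
                raise ValueError(
                    f"{path}: {accession}: exon list lengths disagree with exonCount"
                )
            out.append(
                GeneModel(
                    gene_symbol=f[12],
                    accession=accession,
                    chrom=f[2],
                    strand=f[3],
                    tx_start=int(f[4]),
                    tx_end=int(f[5]),
                    cds_start=int(f[6]),
                    cds_end=int(f[7]),
                    exon_starts=tuple(exon_starts),
                    exon_ends=tuple(exon_ends),
                )
            )
    return out


def write_refgene(genes: Iterable[GeneModel], path: str | PathLike) -> None:
    """Write gene models in the 16-column refGene.txt dialect."""
    with open(path, "w") as fh:
        for g in genes:
            row = [
                0,
                g.accession,
                g.chrom,
                g.strand,
                g.tx_start,
                g.tx_end,
                g.cds_start,
                g.cds_end,
                len(g.exon_starts),
                ",".join(map(str, g.exon_starts)) + ",",
                ",".join(map(str, g.exon_ends)) + ",",
                0,
                g.gene_symbol,
                "cmpl" if g.coding else "none",
                "cmpl" if g.coding else "none",
                ",".join("0" if g.coding else "-1" for _ in g.exon_starts) + ",",
            ]
            fh.write("\t".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def iter_fasta(path: str | PathLike) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTA file; id is the first header token."""
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            else:
                chunks.append(line.strip())
    if name is not None:
        yield name, "".join(chunks)


def extract_sequences(
    ids: set[str], fasta: str | PathLike
) -> dict[str, str]:
    """Pull the requested records out of a FASTA file.

    Returns exactly the requested ids present in the file (case preserved).
    Duplicate ids: first occurrence wins, with a warning.  Requested ids that
    are absent are reported in a warning, not fatal.
    """
    wanted = set(ids)
    found: dict[str, str] = {}
    for name, seq in iter_fasta(fasta):
        if name in found:
            log.warning("duplicate FASTA id %s: keeping first occurrence", name)
            continue
        if name in wanted:
            found[name] = seq
    missing = wanted - found.keys()
    if missing:
        log.warning(
            "%d requested ids missing from %s: %s",
            len(missing),
            fasta,
            ", ".join(sorted(missing)[:10]) + ("..." if len(missing) > 10 else ""),
        )
    return found


def fasta_lengths(path: str | PathLike) -> dict[str, int]:
    """Sequence lengths by id; duplicates keep the first occurrence."""
    out: dict[str, int] = {}
    for name, seq in iter_fasta(path):
        out.setdefault(name, len(seq))
    return out


def write_fasta(records: Mapping[str, str] | Sequence[tuple[str, str]],
                path: str | PathLike, width: int = 80) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq(path: str | PathLike) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (plain or gzipped).

    Qualities are ignored; only the sequence line is returned.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()  # +
            fh.readline()  # qualities
            yield seq


def write_fastq(reads: Iterable[tuple[str, str]], path: str | PathLike) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
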