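"""Synthetic world generator: genome, gene models, planted mobile elements,
per-group transcript sets with ME-retention events, and junction reads.

The generator builds a self-consistent miniature study: a random genome with
genes laid out along one chromosome, MEs planted in introns (and intergenic
space) with class-specific divergence distributions, and four sample groups
whose transcripts carry retained-intron MEs at group-specific rates.  Every
emitted file (FASTA / .out / PSL / refGene / FASTQ) is written by
construction from known coordinates, so the truth tables are exact and all
downstream modules can be tested hermetically.

Default group structure mirrors the study cohort this pipeline was built
for: control (n=51), TLE-NC (17), TLE (14), TLE-HS (8), paired-end 150-bp
reads, ~10,000 assembled transcripts per sample, with all-exon ME-retention
rates rising from control to TLE-HS and no SVA planted (so SVA absence
downstream is a structural property of the world).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from os import PathLike
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .calling import GeneIndex
from .io import (
    write_fasta,
    write_fastq,
    write_psl,
    write_refgene,
    write_repeatmasker_out,
)
from .junctions import revcomp
from .model import (
    GeneModel,
    MINUS,
    PLUS,
    RepeatAnnotation,
    TranscriptAlignment,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: The 61 sense codons, used to synthesize stop-free coding sequence.
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


# ---------------------------------------------------------------------------
# configuration


#: Per-class ME catalog: subfamily -> family names, divergence distribution
#: (truncated normal on [0, 45] % divergence; SINEs youngest, LINEs oldest),
#: and genome-abundance weights proportional to the human class copy numbers.
DEFAULT_ME_CATALOG: dict[str, dict] = {
    "SINE": {
        "subfamilies": {"AluY": "Alu", "AluSx": "Alu", "AluJb": "Alu",
                        "MIRb": "MIR", "MIR": "MIR"},
        "div_mode": 11.0, "div_sd": 5.0, "genome_weight": 0.395,
    },
    "LINE": {
        "subfamilies": {"L1PA2": "L1", "L1MB5": "L1", "L2a": "L2",
                        "L2": "L2", "CR1_Mam": "CR1"},
        "div_mode": 26.0, "div_sd": 6.0, "genome_weight": 0.337,
    },
    "LTR": {
        "subfamilies": {"MLT1K": "ERVL-MaLR", "MSTA": "ERVL-MaLR",
                        "MER41B": "ERV1", "LTR13": "ERVK"},
        "div_mode": 18.0, "div_sd": 7.0, "genome_weight": 0.160,
    },
    "DNA": {
        "subfamilies": {"MER5A": "hAT-Charlie", "Tigger1": "TcMar-Tigger",
                        "MER20": "hAT-Tip100"},
        "div_mode": 16.0, "div_sd": 5.0, "genome_weight": 0.108,
    },
}

#: Class mix of retention events in transcripts (Table-2-like ordering:
#: SINE > LINE > DNA > LTR; no SVA planted).
DEFAULT_CLASS_MIX = {"SINE": 0.49, "LINE": 0.25, "DNA": 0.16, "LTR": 0.10}

#: Region mix of retention events in coding transcripts.
DEFAULT_REGION_MIX = {"three_prime_utr": 0.70, "cds": 0.20,
                      "five_prime_utr": 0.10}


@dataclass
class GroupParams:
    n_samples: int
    transcripts_per_sample: int = 10_000
    me_retention_rate: float = 0.01
    junction_me_rate: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.me_retention_rate <= 1.0:
            raise ValueError("me_retention_rate outside [0, 1]")
        if not 0.0 <= self.junction_me_rate <= 1.0:
            raise ValueError("junction_me_rate outside [0, 1]")


#: Study-like cohort: sample sizes, all-exon retention gradient
#: control < TLE-NC < TLE < TLE-HS, and the SCN1A-style junction ME-rate
#: pattern with TLE-NC lowest.
DEFAULT_GROUPS = {
    "control": GroupParams(51, me_retention_rate=0.008, junction_me_rate=0.109),
    "TLE_NC": GroupParams(17, me_retention_rate=0.014, junction_me_rate=0.030),
    "TLE": GroupParams(14, me_retention_rate=0.015, junction_me_rate=0.270),
    "TLE_HS": GroupParams(8, me_retention_rate=0.020, junction_me_rate=0.263),
}


@dataclass
class WorldConfig:
    seed: int = 0
    n_genes: int = 300
    exon_count_range: tuple[int, int] = (2, 20)
    exon_length_range: tuple[int, int] = (50, 500)
    intron_length_range: tuple[int, int] = (200, 5000)
    intergenic_gap_range: tuple[int, int] = (1000, 5000)
    noncoding_gene_fraction: float = 0.10
    intron_me_probability: float = 0.90
    intergenic_me_mean: float = 3.0
    me_catalog: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_ME_CATALOG.items()
    })
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    region_mix: dict = field(default_factory=lambda: dict(DEFAULT_REGION_MIX))
    noncoding_event_fraction: float = 0.10
    group_params: dict = field(
        default_factory=lambda: {k: GroupParams(**asdict(v))
                                 for k, v in DEFAULT_GROUPS.items()}
    )
    read_length: int = 150
    paired_end: bool = True
    junction_depth: int = 200
    fragment_gap: int = 50

    @classmethod
    def from_yaml(cls, path: str | PathLike) -> "WorldConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "group_params" in raw:
            raw["group_params"] = {
                g: GroupParams(**p) for g, p in raw["group_params"].items()
            }
        for key in ("exon_count_range", "exon_length_range",
                    "intron_length_range", "intergenic_gap_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# world


@dataclass
class PlantedMe:
    chrom: str
    start: int
    end: int
    me_class: str
    subfamily: str
    family: str
    divergence: float
    orientation: str


@dataclass
class IntronRecord:
    gene: GeneModel
    intron_index: int  # 0-based, in genomic order
    start: int
    end: int
    region_label: str  # five_prime_utr | cds | three_prime_utr | noncoding
    me: PlantedMe | None = None


@dataclass
class World:
    config: WorldConfig
    genes: list[GeneModel]
    gene_index: GeneIndex
    introns: list[IntronRecord]
    catalog: dict[tuple[str, str], list[IntronRecord]]
    genome_repeats: list[RepeatAnnotation]
    chrom_sizes: dict[str, int]
    _genome: dict[str, str] | None = None

    @property
    def genome(self) -> dict[str, str]:
        """Random genome sequence, generated lazily but deterministically."""
        if self._genome is None:
            rng = np.random.default_rng((self.config.seed * 7919 + 13) % 2**31)
            self._genome = {
                chrom: _random_seq(rng, size)
                for chrom, size in sorted(self.chrom_sizes.items())
            }
        return self._genome

    def genome_census(self) -> dict[str, int]:
        """Planted ME count per class (the truth for census recovery)."""
        counts: dict[str, int] = {c: 0 for c in self.config.me_catalog}
        for r in self.genome_repeats:
            counts[r.repeat_class] = counts.get(r.repeat_class, 0) + 1
        return counts

    def digest(self) -> str:
        """Stable hash over gene models and planted repeats (determinism checks)."""
        h = hashlib.sha256()
        for g in self.genes:
            h.update(repr((g.accession, g.chrom, g.strand, g.tx_start, g.tx_end,
                           g.cds_start, g.cds_end, g.exon_starts,
                           g.exon_ends)).encode())
        for r in self.genome_repeats:
            h.update(repr((r.target_id, r.target_begin, r.target_end,
                           r.repeat_subfamily, r.divergence_pct,
                           r.orientation)).encode())
        return h.hexdigest()

    def write(self, outdir: str | PathLike, sequences: bool = False) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_refgene(self.genes, outdir / "refGene.txt")
        write_repeatmasker_out(self.genome_repeats, outdir / "genome.fa.out")
        if sequences:
            write_fasta(self.genome, outdir / "genome.fa")


def _draw_divergence(rng: np.random.Generator, mode: float, sd: float) -> float:
    """Truncated-normal divergence on [0, 45], rounded to RepeatMasker's 0.1."""
    for _ in range(100):
        d = rng.normal(mode, sd)
        if 0.0 <= d <= 45.0:
            return round(float(d), 1)
    return round(float(np.clip(mode, 0.0, 45.0)), 1)


def _plant_me(
    rng: np.random.Generator,
    cfg: WorldConfig,
    chrom: str,
    lo: int,
    hi: int,
    me_class: str,
) -> PlantedMe | None:
    """Place one ME of the class inside [lo, hi) with small margins."""
    space = hi - lo - 10
    if space < 70:
        return None
    length = int(rng.integers(60, min(300, space) + 1))
    start = lo + 5 + int(rng.integers(0, space - length + 1))
    cat = cfg.me_catalog[me_class]
    subfamilies = list(cat["subfamilies"])
    sub = subfamilies[int(rng.integers(0, len(subfamilies)))]
    return PlantedMe(
        chrom=chrom,
        start=start,
        end=start + length,
        me_class=me_class,
        subfamily=sub,
        family=cat["subfamilies"][sub],
        divergence=_draw_divergence(rng, cat["div_mode"], cat["div_sd"]),
        orientation=PLUS if rng.random() < 0.5 else MINUS,
    )


def _gene_structure(
    rng: np.random.Generator, cfg: WorldConfig, tx_start: int
) -> tuple[list[int], list[int], int, int, bool]:
    """Random exon layout + CDS bounds from tx_start; returns
    (exon_starts, exon_ends, cds_start, cds_end, coding)."""
    n_exons = int(rng.integers(cfg.exon_count_range[0],
                               cfg.exon_count_range[1] + 1))
    exon_lens = rng.integers(cfg.exon_length_range[0],
                             cfg.exon_length_range[1] + 1, size=n_exons)
    intron_lens = rng.integers(cfg.intron_length_range[0],
                               cfg.intron_length_range[1] + 1,
                               size=max(0, n_exons - 1))
    starts, ends = [], []
    pos = tx_start
    for i, el in enumerate(exon_lens):
        starts.append(pos)
        pos += int(el)
        ends.append(pos)
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    coding = rng.random() >= cfg.noncoding_gene_fraction
    if not coding:
        return starts, ends, tx_start, tx_start, False
    if n_exons >= 4:
        # CDS starts inside exon 2 and ends inside exon n-1, so the first
        # and last introns fall in the UTR spans.
        cds_start = starts[1] + int(rng.integers(10, ends[1] - starts[1] - 10))
        cds_end = starts[-2] + int(rng.integers(10, ends[-2] - starts[-2] - 10))
    else:
        cds_start = starts[0] + int(rng.integers(5, ends[0] - starts[0] - 5))
        cds_end = starts[-1] + int(rng.integers(5, ends[-1] - starts[-1] - 5))
    if cds_start >= cds_end:
        cds_start, cds_end = cds_end - 1, cds_start + 1
    return starts, ends, cds_start, cds_end, True


def build_world(config: WorldConfig) -> World:
    """Build the synthetic world: genome layout, genes, planted MEs.

    Deterministic under ``config.seed``.  Raises if the configured gene
    structures cannot be packed (only possible with degenerate ranges).
    """
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    genes: list[GeneModel] = []
    introns: list[IntronRecord] = []
    genome_repeats: list[RepeatAnnotation] = []
    class_names = list(config.me_catalog)
    intron_weights = np.array(
        [config.me_catalog[c]["genome_weight"] for c in class_names]
    )
    intron_weights = intron_weights / intron_weights.sum()

    def add_repeat(me: PlantedMe) -> None:
        genome_repeats.append(
            RepeatAnnotation(
                target_id=me.chrom,
                target_begin=me.start,
                target_end=me.end,
                repeat_subfamily=me.subfamily,
                repeat_class=me.me_class,
                repeat_family=me.family,
                divergence_pct=me.divergence,
                orientation=me.orientation,
                sw_score=int(rng.integers(300, 5000)),
            )
        )

    pos = int(rng.integers(*config.intergenic_gap_range))
    for gi in range(config.n_genes):
        starts, ends, cds_start, cds_end, coding = _gene_structure(
            rng, config, pos
        )
        strand = PLUS if rng.random() < 0.5 else MINUS
        gene = GeneModel(
            gene_symbol=f"GENE{gi:04d}",
            accession=(f"NM_{100000 + gi}" if coding else f"NR_{100000 + gi}"),
            chrom=chrom,
            strand=strand,
            tx_start=starts[0],
            tx_end=ends[-1],
            cds_start=cds_start,
            cds_end=cds_end,
            exon_starts=tuple(starts),
            exon_ends=tuple(ends),
        )
        genes.append(gene)
        for k in range(len(starts) - 1):
            i_start, i_end = ends[k], starts[k + 1]
            if not coding:
                label = "noncoding"
            elif i_end <= cds_start:
                label = ("three_prime_utr" if strand == MINUS
                         else "five_prime_utr")
            elif i_start >= cds_end:
                label = ("five_prime_utr" if strand == MINUS
                         else "three_prime_utr")
            else:
                label = "cds"
            rec = IntronRecord(gene=gene, intron_index=k,
                               start=i_start, end=i_end, region_label=label)
            if rng.random() < config.intron_me_probability:
                cls = class_names[int(rng.choice(len(class_names),
                                                 p=intron_weights))]
                me = _plant_me(rng, config, chrom, i_start, i_end, cls)
                if me is not None:
                    rec.me = me
                    add_repeat(me)
            introns.append(rec)
        gap = int(rng.integers(*config.intergenic_gap_range))
        n_inter = int(rng.poisson(config.intergenic_me_mean))
        gap_lo, gap_hi = ends[-1] + 20, ends[-1] + gap - 20
        slot = (gap_hi - gap_lo) // max(1, n_inter) if n_inter else 0
        for j in range(n_inter):
            if slot < 90:
                break
            cls = class_names[int(rng.choice(len(class_names),
                                             p=intron_weights))]
            me = _plant_me(rng, config, chrom,
                           gap_lo + j * slot, gap_lo + (j + 1) * slot, cls)
            if me is not None:
                add_repeat(me)
        pos = ends[-1] + gap

    catalog: dict[tuple[str, str], list[IntronRecord]] = {}
    for rec in introns:
        if rec.me is not None:
            catalog.setdefault((rec.me.me_class, rec.region_label),
                               []).append(rec)
    # strand-aware UTR labels depend on the gene's orientation, so a minus
    # gene's "first" intron is a 3' UTR intron; both cases land in the
    # catalog under their genomic-region label.
    genome_repeats.sort(key=lambda r: (r.target_id, r.target_begin))
    return World(
        config=config,
        genes=genes,
        gene_index=GeneIndex(genes),
        introns=introns,
        catalog=catalog,
        genome_repeats=genome_repeats,
        chrom_sizes={chrom: pos + 100},
    )


# ---------------------------------------------------------------------------
# sample simulation


@dataclass
class TruthRow:
    transcript_id: str
    gene_symbol: str
    accession: str
    me_class: str
    subfamily: str
    region: str  # label as called downstream (noncoding -> noncoding_exonic)
    tx_begin: int
    tx_end: int
    genome_start: int
    genome_end: int
    divergence: float
    intron_index: int


@dataclass
class SimulatedSample:
    sample_id: str
    group: str
    total_transcripts: int
    lengths: dict[str, int]
    repeats: list[RepeatAnnotation]
    alignments: list[TranscriptAlignment]
    truth: list[TruthRow]
    junction_me_rate: float
    sequences: dict[str, str] | None = None
    reads: list[tuple[str, str]] | None = None

    def write(self, outdir: str | PathLike) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prefix = outdir / self.sample_id
        write_repeatmasker_out(self.repeats, f"{prefix}.fa.out")
        write_psl(self.alignments, f"{prefix}.psl")
        if self.sequences is not None:
            write_fasta(self.sequences, f"{prefix}.fa")
        if self.reads is not None:
            write_fastq(self.reads, f"{prefix}.fastq")
        with open(f"{prefix}.truth.tsv", "w") as fh:
            fh.write("transcript\tgene\taccession\tclass\tsubfamily\tregion\t"
                     "tx_begin\ttx_end\tgenome_start\tgenome_end\t"
                     "divergence\tintron_index\n")
            for t in self.truth:
                fh.write("\t".join(str(x) for x in (
                    t.transcript_id, t.gene_symbol, t.accession, t.me_class,
                    t.subfamily, t.region, t.tx_begin, t.tx_end,
                    t.genome_start, t.genome_end, t.divergence,
                    t.intron_index)) + "\n")


def _segments_for_retention(
    gene: GeneModel, intron_index: int
) -> list[tuple[int, int]]:
    """Genomic segments of a transcript retaining one intron: the two exons
    flanking the intron fuse into a single block."""
    exons = gene.exons
    fused = (exons[intron_index][0], exons[intron_index + 1][1])
    return exons[:intron_index] + [fused] + exons[intron_index + 2:]


def _alignment_from_segments(
    tid: str,
    gene: GeneModel,
    segs: Sequence[tuple[int, int]],
    chrom_size: int,
) -> TranscriptAlignment:
    total = sum(e - s for s, e in segs)
    blocks = []
    off = 0
    for s, e in segs:
        size = e - s
        q = off if gene.strand == PLUS else total - (off + size)
        blocks.append((q, s, size))
        off += size
    blocks.sort()
    return TranscriptAlignment(
        query_id=tid,
        query_length=total,
        strand=gene.strand,
        target_chrom=gene.chrom,
        target_size=chrom_size,
        matches=total,
        mismatches=0,
        q_gap_count=0,
        t_gap_count=len(segs) - 1,
        blocks=tuple(blocks),
    )


def _genome_to_query(
    segs: Sequence[tuple[int, int]], strand: str, g_start: int, g_end: int
) -> tuple[int, int]:
    """Map a genomic interval inside one segment to transcript coordinates."""
    total = sum(e - s for s, e in segs)
    off = 0
    for s, e in segs:
        if s <= g_start and g_end <= e:
            o_start = off + (g_start - s)
            o_end = off + (g_end - s)
            if strand == MINUS:
                return total - o_end, total - o_start
            return o_start, o_end
        off += e - s
    raise ValueError("interval not contained in any segment")


def _transcript_sequence(
    genome: Mapping[str, str], gene: GeneModel, segs: Sequence[tuple[int, int]]
) -> str:
    chrom = genome[gene.chrom]
    seq = "".join(chrom[s:e] for s, e in segs)
    return revcomp(seq) if gene.strand == MINUS else seq


def _mrna_junction_offset(gene: GeneModel, intron_index: int) -> int:
    """Transcription-order mRNA offset where the retained intron begins."""
    exons = gene.exons
    if gene.strand == PLUS:
        return sum(e - s for s, e in exons[: intron_index + 1])
    return sum(e - s for s, e in exons[intron_index + 1:])


def simulate_junction_reads(
    normal_seq: str,
    me_seq: str,
    junction_normal: int,
    junction_me: int,
    n_reads: int,
    me_fraction: float,
    rng: np.random.Generator,
    read_length: int = 150,
    paired: bool = True,
    name_prefix: str = "read",
) -> list[tuple[str, str]]:
    """Draw junction-spanning reads from a two-form mixture.

    Each fragment is the ME form with probability ``me_fraction``; the first
    mate is placed to span the junction with at least 15 bp on each side,
    the optional second mate is the reverse complement of a nearby window.
    Read orientation is randomized, so counting must be strand-symmetric.
    """
    out: list[tuple[str, str]] = []
    for i in range(n_reads):
        is_me = rng.random() < me_fraction
        seq, j = (me_seq, junction_me) if is_me else (normal_seq, junction_normal)
        lo = max(0, j - read_length + 15)
        hi = max(lo + 1, j - 15)
        start = int(rng.integers(lo, hi))
        r1 = seq[start : start + read_length]
        if rng.random() < 0.5:
            r1 = revcomp(r1)
        out.append((f"{name_prefix}{i}/1", r1))
        if paired:
            m_start = max(0, start - read_length - 50)
            r2 = seq[m_start : m_start + read_length]
            if rng.random() < 0.5:
                r2 = revcomp(r2)
            out.append((f"{name_prefix}{i}/2", r2))
    return out


def simulate_sample(
    world: World,
    group: str,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
    sequences: bool = False,
    reads: bool = False,
    transcripts_per_sample: int | None = None,
) -> SimulatedSample:
    """Simulate one sample of the group: transcripts, repeats, alignments.

    A ``me_retention_rate`` fraction of the sample's transcripts (binomially
    sampled) carry one retained intronic ME; sub-300-bp decoys and
    Other-class repeat rows are included to exercise the caller's filters.
    With ``sequences=True`` full transcript FASTA records (and normal
    background transcripts) are materialized; ``reads=True`` additionally
    draws junction-spanning paired-end reads at the group's planted
    read-level ME rate.  Without sequences, only repeat-bearing transcripts
    are materialized (as lengths) — background transcripts contribute only
    to ``total_transcripts``, which is all the frequency pipeline uses.
    """
    cfg = world.config
    if group not in cfg.group_params:
        raise ValueError(f"unknown group {group!r}")
    gp = cfg.group_params[group]
    if rng is None:
        rng = np.random.default_rng(seed)
    if reads:
        sequences = True
    total = transcripts_per_sample or gp.transcripts_per_sample
    sid = sample_id or f"{group}_{seed if seed is not None else 'r'}"
    chrom_size = max(world.chrom_sizes.values())

    class_names = list(cfg.class_mix)
    class_p = np.array([cfg.class_mix[c] for c in class_names], dtype=float)
    class_p /= class_p.sum()
    region_names = list(cfg.region_mix)
    region_p = np.array([cfg.region_mix[r] for r in region_names], dtype=float)
    region_p /= region_p.sum()

    n_me = int(rng.binomial(total, gp.me_retention_rate))
    lengths: dict[str, int] = {}
    seqs: dict[str, str] | None = {} if sequences else None
    repeats: list[RepeatAnnotation] = []
    alignments: list[TranscriptAlignment] = []
    truth: list[TruthRow] = []
    read_list: list[tuple[str, str]] = [] if reads else None

    for k in range(n_me):
        cls = class_names[int(rng.choice(len(class_names), p=class_p))]
        if rng.random() < cfg.noncoding_event_fraction:
            bucket = world.catalog.get((cls, "noncoding"))
            region_called = "noncoding_exonic"
        else:
            region = region_names[int(rng.choice(len(region_names),
                                                 p=region_p))]
            bucket = world.catalog.get((cls, region))
            region_called = region
        if not bucket:  # thin world: fall back to any intron of the class
            fallback = [r for (c, _), recs in world.catalog.items()
                        if c == cls for r in recs]
            if not fallback:
                continue
            rec = fallback[int(rng.integers(0, len(fallback)))]
            region_called = ("noncoding_exonic"
                             if rec.region_label == "noncoding"
                             else rec.region_label)
        else:
            rec = bucket[int(rng.integers(0, len(bucket)))]
        gene, me = rec.gene, rec.me
        tid = f"{sid}.mt{k:05d}"
        segs = _segments_for_retention(gene, rec.intron_index)
        aln = _alignment_from_segments(tid, gene, segs, chrom_size)
        lengths[tid] = aln.query_length
        q_start, q_end = _genome_to_query(segs, gene.strand, me.start, me.end)
        orient_tx = me.orientation if gene.strand == PLUS else (
            PLUS if me.orientation == MINUS else MINUS
        )
        repeats.append(
            RepeatAnnotation(
                target_id=tid,
                target_begin=q_start,
                target_end=q_end,
                repeat_subfamily=me.subfamily,
                repeat_class=me.me_class,
                repeat_family=me.family,
                divergence_pct=me.divergence,
                orientation=orient_tx,
                sw_score=int(rng.integers(300, 5000)),
            )
        )
        alignments.append(aln)
        truth.append(
            TruthRow(
                transcript_id=tid,
                gene_symbol=gene.gene_symbol,
                accession=gene.accession,
                me_class=me.me_class,
                subfamily=me.subfamily,
                region=region_called,
                tx_begin=q_start,
                tx_end=q_end,
                genome_start=me.start,
                genome_end=me.end,
                divergence=me.divergence,
                intron_index=rec.intron_index,
            )
        )
        if sequences:
            me_seq = _transcript_sequence(world.genome, gene, segs)
            seqs[tid] = me_seq
            if reads:
                normal_seq = _transcript_sequence(world.genome, gene,
                                                  gene.exons)
                j = _mrna_junction_offset(gene, rec.intron_index)
                read_list.extend(
                    simulate_junction_reads(
                        normal_seq, me_seq, j, j,
                        n_reads=cfg.junction_depth,
                        me_fraction=gp.junction_me_rate,
                        rng=rng,
                        read_length=cfg.read_length,
                        paired=cfg.paired_end,
                        name_prefix=f"{tid}.",
                    )
                )

    # decoys: ME-bearing transcripts under the 300-bp cutoff
    n_decoys = max(2, n_me // 20)
    coding_genes = [g for g in world.genes if g.mrna_length >= 400]
    for d in range(n_decoys):
        gene = coding_genes[int(rng.integers(0, len(coding_genes)))]
        exon = max(gene.exons, key=lambda x: x[1] - x[0])
        dlen = int(rng.integers(150, 300))
        dlen = min(dlen, exon[1] - exon[0])
        tid = f"{sid}.dk{d:03d}"
        lengths[tid] = dlen
        segs = [(exon[0], exon[0] + dlen)]
        alignments.append(
            _alignment_from_segments(tid, gene, segs, chrom_size)
        )
        me_len = min(80, dlen - 20)
        repeats.append(
            RepeatAnnotation(
                target_id=tid, target_begin=10, target_end=10 + me_len,
                repeat_subfamily="AluY", repeat_class="SINE",
                repeat_family="Alu",
                divergence_pct=_draw_divergence(rng, 11.0, 5.0),
                orientation=PLUS, sw_score=500,
            )
        )
        if sequences:
            seqs[tid] = world.genome[gene.chrom][exon[0]: exon[0] + dlen]

    # Other-class repeat rows on normal-length transcripts (class filter)
    for d in range(3):
        gene = coding_genes[int(rng.integers(0, len(coding_genes)))]
        exon = max(gene.exons, key=lambda x: x[1] - x[0])
        if exon[1] - exon[0] < 320:
            continue
        tid = f"{sid}.ot{d:03d}"
        olen = min(500, exon[1] - exon[0])
        lengths[tid] = olen
        segs = [(exon[0], exon[0] + olen)]
        alignments.append(
            _alignment_from_segments(tid, gene, segs, chrom_size)
        )
        repeats.append(
            RepeatAnnotation(
                target_id=tid, target_begin=20, target_end=60,
                repeat_subfamily="(TA)n", repeat_class="Other",
                repeat_family="Simple_repeat", divergence_pct=5.0,
                orientation=PLUS, sw_score=50,
            )
        )
        if sequences:
            seqs[tid] = world.genome[gene.chrom][exon[0]: exon[0] + olen]

    if sequences:
        # background normal transcripts (spliced mRNAs, no repeats)
        n_background = max(0, total - n_me - n_decoys)
        n_emit = min(n_background, 2000)  # cap FASTA size; rest counted only
        for b in range(n_emit):
            gene = world.genes[int(rng.integers(0, len(world.genes)))]
            tid = f"{sid}.nt{b:05d}"
            lengths[tid] = gene.mrna_length
            seqs[tid] = _transcript_sequence(world.genome, gene, gene.exons)
            alignments.append(
                _alignment_from_segments(tid, gene, gene.exons, chrom_size)
            )

    return SimulatedSample(
        sample_id=sid,
        group=group,
        total_transcripts=total,
        lengths=lengths,
        repeats=repeats,
        alignments=alignments,
        truth=truth,
        junction_me_rate=gp.junction_me_rate,
        sequences=seqs,
        reads=read_list,
    )


# ---------------------------------------------------------------------------
# SCN1A-like fixture


@dataclass
class ScnFixture:
    gene: GeneModel
    genome: dict[str, str]
    normal_mrna: str
    me_transcript: str
    junction_offset: int  # mRNA offset where the retained ME segment begins
    me_annotation: RepeatAnnotation  # the retained LINE, transcript coords


def make_scn1a_like_fixture(world: World | None = None,
                            seed: int | None = None) -> ScnFixture:
    """Build a gene modelled on the SCN1A abnormal-splicing case.

    A 26-exon coding gene with a 1,980-aa protein; the abnormal transcript
    reads through the donor site of the exon mimicking exon 17 into an
    87-bp LINE (L1PA2) segment of the intron, which places an in-frame stop
    codon immediately downstream, truncating more than 1,000 C-terminal
    residues.  The layout is deterministic given the world's seed.
    """
    base_seed = (world.config.seed if world is not None else (seed or 0))
    rng = np.random.default_rng((base_seed * 104729 + 7) % 2**31)
    chrom = "chrF"
    utr5, utr3 = 100, 200
    n_exons = 26
    cds_lens = [100] + [120] * 24 + [2963]  # 5,943 bp = 1,980 aa + stop
    exon_lens = [utr5 + cds_lens[0]] + cds_lens[1:-1] + [cds_lens[-1] + utr3]
    intron_len = 500
    retained_len = 87

    # stop-free coding sequence, stop codon appended at the very end
    n_codons = (sum(cds_lens) - 3) // 3
    cds = "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS),
                                               size=n_codons)
    ) + "TAA"
    # The exon 17/18 boundary sits after 2,020 coding bases, one base into
    # codon 674.  Pin that codon to T|CG: in the normal form it reads TCG
    # (Ser); in the ME form the retained segment's leading "AA" completes
    # it to TAA, an immediate in-frame stop.  The 'C' at the boundary also
    # guarantees the divergence junction falls exactly at the exon end.
    cds_to_junction = 100 + 16 * 120  # 2,020
    cds = cds[: cds_to_junction - 1] + "TCG" + cds[cds_to_junction + 2:]

    mrna = _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)
    junction = utr5 + cds_to_junction

    # retained intron head: 'AA' completes the boundary codon to 'TAA'
    retained = "AA" + _random_seq(rng, retained_len - 2)

    # assemble the genome: exons separated by introns; intron 17 starts
    # with the retained segment
    tx_start = 500
    exon_starts, exon_ends = [], []
    pos = tx_start
    mrna_pos = 0
    intron_seqs = []
    for i, el in enumerate(exon_lens):
        exon_starts.append(pos)
        pos += el
        exon_ends.append(pos)
        mrna_pos += el
        if i < n_exons - 1:
            iseq = _random_seq(rng, intron_len)
            if i == 16:  # intron 17 (0-based 16) carries the LINE head
                iseq = retained + iseq[retained_len:]
            intron_seqs.append(iseq)
            pos += intron_len
    genome_seq_parts = [_random_seq(rng, tx_start)]
    m = 0
    for i, el in enumerate(exon_lens):
        genome_seq_parts.append(mrna[m : m + el])
        m += el
        if i < n_exons - 1:
            genome_seq_parts.append(intron_seqs[i])
    genome_seq_parts.append(_random_seq(rng, 500))
    genome = {chrom: "".join(genome_seq_parts)}

    gene = GeneModel(
        gene_symbol="SCN1A_SYN",
        accession="NM_900001",
        chrom=chrom,
        strand=PLUS,
        tx_start=tx_start,
        tx_end=exon_ends[-1],
        cds_start=exon_starts[0] + utr5,
        cds_end=exon_ends[-1] - utr3,
        exon_starts=tuple(exon_starts),
        exon_ends=tuple(exon_ends),
    )
    me_transcript = mrna[:junction] + retained
    me_annotation = RepeatAnnotation(
        target_id="scn1a_like_me_transcript",
        target_begin=junction,
        target_end=junction + retained_len,
        repeat_subfamily="L1PA2",
        repeat_class="LINE",
        repeat_family="L1",
        divergence_pct=2.1,
        orientation=PLUS,
        sw_score=700,
    )
    return ScnFixture(
        gene=gene,
        genome=genome,
        normal_mrna=mrna,
        me_transcript=me_transcript,
        junction_offset=junction,
        me_annotation=me_annotation,
    )
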