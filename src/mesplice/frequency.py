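"""Per-sample ME-transcript frequency tables and TPMPM normalization.

TPM here is the study-specific unit: ME hits (or ME-containing transcripts)
per million assembled transcripts, NOT the expression-level
transcripts-per-million.  TPMPM further divides by the genome-wide copy
number (in millions) of the ME class, giving a per-copy contribution rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calling import merge_repeat_fragments
from .model import ME_CLASSES, MeTranscriptCall, RepeatAnnotation

#: Region scopes of the frequency table.  ``all_exons`` covers every call
#: (noncoding-exonic calls count only here); the other three cover coding
#: isoforms broken down by gene region.
REGION_SCOPES = ("all_exons", "cds", "three_prime_utr", "five_prime_utr")

#: Genome-wide ME copy numbers for the human reference (GRCh38), used as the
#: default TPMPM denominator.
HUMAN_GENOME_ME_COUNTS = {
    "SINE": 1_779_233,
    "LINE": 1_516_226,
    "LTR": 720_177,
    "DNA": 483_994,
}


@dataclass
class Cell:
    count: int = 0
    tpm: float = 0.0


@dataclass
class SampleFrequencyTable:
    """ME frequencies for one sample: counts and TPM per (label, scope).

    ``class_cells`` always holds all five ME classes x four scopes;
    ``subfamily_cells`` holds the subfamilies seen in the calls;
    ``totals`` aggregates over all classes per scope ("All MEs").
    """

    sample_id: str
    group: str
    total_transcripts: int
    counting_mode: str = "per_hit"
    class_cells: dict[tuple[str, str], Cell] = field(default_factory=dict)
    subfamily_cells: dict[tuple[str, str], Cell] = field(default_factory=dict)
    totals: dict[str, Cell] = field(default_factory=dict)

    def cell(self, me_class: str, scope: str) -> Cell:
        return self.class_cells[(me_class, scope)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"label": label, "scope": scope, "count": c.count, "tpm": c.tpm}
            for (label, scope), c in self.class_cells.items()
        ]
        rows += [
            {"label": "ALL", "scope": scope, "count": c.count, "tpm": c.tpm}
            for scope, c in self.totals.items()
        ]
        return pd.DataFrame(rows)


def _scopes_for(region: str) -> tuple[str, ...]:
    if region == "noncoding_exonic":
        return ("all_exons",)
    return ("all_exons", region)


def tabulate_sample(
    calls: Sequence[MeTranscriptCall],
    total_transcripts: int,
    counting_mode: str = "per_hit",
    sample_id: str | None = None,
    group: str = "",
) -> SampleFrequencyTable:
    """Build the per-sample frequency table from a sample's calls.

    ``per_hit`` counts every (transcript, ME) call; ``per_transcript``
    counts distinct transcript ids per cell.  TPM = count / total_transcripts
    x 10^6.  ``total_transcripts`` is the number of all assembled transcripts
    >= 300 bp in the sample, not only ME-transcripts.
    """
    if total_transcripts <= 0:
        raise ValueError("total_transcripts must be positive")
    if counting_mode not in ("per_hit", "per_transcript"):
        raise ValueError(f"unknown counting mode {counting_mode!r}")
    if sample_id is None:
        sample_id = calls[0].sample_id if calls else ""

    table = SampleFrequencyTable(
        sample_id=sample_id,
        group=group,
        total_transcripts=total_transcripts,
        counting_mode=counting_mode,
    )
    for cls in ME_CLASSES:
        for scope in REGION_SCOPES:
            table.class_cells[(cls, scope)] = Cell()
    for scope in REGION_SCOPES:
        table.totals[scope] = Cell()

    members: dict[tuple[str, str, str], set[str] | int] = {}
    class_members: dict[tuple[str, str], set[str]] = {}
    subfam_members: dict[tuple[str, str], set[str]] = {}
    total_members: dict[str, set[str]] = {}

    def bump(cells: dict, key, tid: str, registry: dict) -> None:
        cell = cells.setdefault(key, Cell())
        if counting_mode == "per_hit":
            cell.count += 1
        else:
            seen = registry.setdefault(key, set())
            if tid not in seen:
                seen.add(tid)
                cell.count += 1

    for call in calls:
        for scope in _scopes_for(call.region):
            bump(table.class_cells, (call.me.repeat_class, scope),
                 call.transcript_id, class_members)
            bump(table.subfamily_cells, (call.me.repeat_subfamily, scope),
                 call.transcript_id, subfam_members)
            bump(table.totals, scope, call.transcript_id, total_members)

    scale = 1e6 / total_transcripts
    for cells in (table.class_cells, table.subfamily_cells, table.totals):
        for cell in cells.values():
            cell.tpm = cell.count * scale
    return table


def census_genome_mes(
    genome_rm: Sequence[RepeatAnnotation], merge_gap: int = 10
) -> dict[str, int]:
    """Count MEs per class in a genome-wide RepeatMasker table.

    Fragmented rows are merged with the same rule the caller uses (< merge_gap
    bp apart, same subfamily and orientation).  Non-ME classes are excluded.
    """
    counts = {cls: 0 for cls in ME_CLASSES}
    for r in merge_repeat_fragments(genome_rm, max_gap=merge_gap):
        if r.repeat_class in counts:
            counts[r.repeat_class] += 1
    return counts


def normalize_tpmpm(
    table: SampleFrequencyTable, genome_me_counts: Mapping[str, int]
) -> dict[tuple[str, str], float]:
    """TPM per million genomic MEs of the class: tpm / (genome_count / 10^6)."""
    out: dict[tuple[str, str], float] = {}
    for (cls, scope), cell in table.class_cells.items():
        if cls not in genome_me_counts:
            if cell.count > 0:
                raise ValueError(f"no genome ME count for class {cls}")
            continue
        denom = genome_me_counts[cls]
        if denom <= 0:
            raise ValueError(f"non-positive genome ME count for class {cls}")
        out[(cls, scope)] = cell.tpm / (denom / 1e6)
    return out


def frequency_matrix(tables: Iterable[SampleFrequencyTable]) -> pd.DataFrame:
    """TPM matrix: rows = class x scope, columns = samples."""
    data = {}
    for t in tables:
        col = {f"{cls}|{scope}": t.class_cells[(cls, scope)].tpm
               for cls in ME_CLASSES for scope in REGION_SCOPES}
        col.update({f"ALL|{scope}": t.totals[scope].tpm for scope in REGION_SCOPES})
        data[t.sample_id] = col
    return pd.DataFrame(data)


def group_summary(tables: Sequence[SampleFrequencyTable]) -> pd.DataFrame:
    """Mean +/- SD TPM per (class, scope) per group (Table-2 style layout)."""
    rows = []
    for t in tables:
        for cls in (*ME_CLASSES, "ALL"):
            for scope in REGION_SCOPES:
                tpm = (t.totals[scope].tpm if cls == "ALL"
                       else t.class_cells[(cls, scope)].tpm)
                rows.append({"group": t.group, "class": cls, "scope": scope,
                             "tpm": tpm})
    df = pd.DataFrame(rows)
    out = df.groupby(["scope", "class", "group"])["tpm"].agg(["mean", "std", "count"])
    return out.reset_index()


def group_values(
    tables: Sequence[SampleFrequencyTable], me_class: str, scope: str
) -> dict[str, list[float]]:
    """Per-group TPM vectors for one cell, ready for compare_groups."""
    out: dict[str, list[float]] = {}
    for t in tables:
        tpm = (t.totals[scope].tpm if me_class == "ALL"
               else t.class_cells[(me_class, scope)].tpm)
        out.setdefault(t.group, []).append(tpm)
    return out


def write_group_summary(tables: Sequence[SampleFrequencyTable],
                        path: str | PathLike) -> None:
    group_summary(tables).to_csv(path, sep="\t", index=False)
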