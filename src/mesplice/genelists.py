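"""Cross-mapping of ME-transcript genes against curated gene lists.

Used with epilepsy-associated and neural/neurodevelopment gene lists (plain
text, one symbol per line).  Matching is exact after uppercasing; no alias
or HGNC resolution is attempted, but a mismatch report is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Mapping, Sequence

from .model import MeTranscriptCall

#: Default region restriction for list cross-mapping: only MEs in the CDS
#: and 3' UTR of coding transcripts are counted.
DEFAULT_REGIONS = frozenset({"cds", "three_prime_utr"})


@dataclass(frozen=True)
class GeneList:
    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"gene list {self.name!r} is empty")
        up = frozenset(s.upper() for s in self.symbols)
        object.__setattr__(self, "symbols", up)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols


def load_gene_list(path: str | PathLike, name: str | None = None) -> GeneList:
    """Read a one-symbol-per-line gene list; blank lines and # comments skip."""
    symbols = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                symbols.add(s.upper())
    return GeneList(name=name or str(path), symbols=frozenset(symbols))


def _region_symbols(
    calls: Iterable[MeTranscriptCall], regions: frozenset[str] | set[str]
) -> set[str]:
    if not regions:
        raise ValueError("empty region set")
    return {
        c.gene_symbol.upper() for c in calls if c.region in regions
    }


def count_list_genes(
    calls: Sequence[MeTranscriptCall],
    gene_list: GeneList,
    regions: frozenset[str] | set[str] = DEFAULT_REGIONS,
) -> int:
    """Distinct genes of one sample's calls that are on the list.

    Restricted to the given regions (by default CDS and 3' UTR).
    """
    return len(_region_symbols(calls, regions) & gene_list.symbols)


def nonredundant_group_genes(
    group_calls: Mapping[str, Sequence[MeTranscriptCall]],
    regions: frozenset[str] | set[str] | None = None,
) -> list[str]:
    """Sorted union of ME-transcript gene symbols across a group's samples.

    ``regions=None`` keeps every call regardless of region.  The resulting
    list is what gets exported for external enrichment analysis.
    """
    if not group_calls:
        raise ValueError("no samples in group")
    symbols: set[str] = set()
    for calls in group_calls.values():
        if regions is None:
            symbols |= {c.gene_symbol.upper() for c in calls}
        else:
            symbols |= _region_symbols(calls, regions)
    return sorted(symbols)


def mismatch_report(
    calls: Sequence[MeTranscriptCall], lists: Sequence[GeneList]
) -> list[str]:
    """Call gene symbols found on none of the supplied lists."""
    all_symbols = {c.gene_symbol.upper() for c in calls}
    for gl in lists:
        all_symbols -= gl.symbols
    return sorted(all_symbols)


def write_gene_list(symbols: Iterable[str], path: str | PathLike) -> None:
    """One-symbol-per-line export (e.g. for DAVID submission)."""
    with open(path, "w") as fh:
        for s in symbols:
            fh.write(s + "\n")
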