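"""Per-target read counting, CPM normalization, and abundance filtering."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from smalldisco.discovery import SirnaRegion

AGGREGATIONS = ("region", "gene")
NORMALIZATION_MODES = ("sirna-only", "exon-background")
DEFAULT_CPM_THRESHOLD = 25.0


@dataclass
class CountRow:
    key: str
    raw_count: float
    cpm: float | None = None


@dataclass
class CountTable:
    """Rows keyed by gene id or region name, with CPM against a library size."""

    rows: list[CountRow] = field(default_factory=list)
    library_size: float | None = None

    def keys(self) -> list[str]:
        return [row.key for row in self.rows]

    def raw_total(self) -> float:
        return sum(row.raw_count for row in self.rows)


def count_per_gene(
    regions: Sequence[SirnaRegion], aggregation: str = "gene"
) -> CountTable:
    """Aggregate supporting-read counts per region or per gene.

    Gene-level aggregation sums all regions sharing a gene id; a region
    attributed to several genes contributes its full count to each.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(
            f"unknown aggregation {aggregation!r}; choose from {AGGREGATIONS}"
        )
    ordered = sorted(regions, key=lambda reg: (reg.interval.chrom, reg.interval.start))
    if aggregation == "region":
        rows = []
        for serial, region in enumerate(ordered, start=1):
            genes = ";".join(sorted(region.gene_ids)) or "."
            rows.append(CountRow(key=f"{genes}.sir{serial}", raw_count=region.read_count))
        return CountTable(rows=rows)
    totals: dict[str, float] = {}
    for region in ordered:
        for gene in sorted(region.gene_ids) or ["."]:
            totals[gene] = totals.get(gene, 0.0) + region.read_count
    return CountTable(rows=[CountRow(key=k, raw_count=v) for k, v in sorted(totals.items())])


def cpm_normalize(
    table: CountTable,
    library_size: float | None = None,
    mode: str = "sirna-only",
    background_count: float = 0.0,
) -> CountTable:
    """Populate the CPM column: raw / library_size * 1e6.

    ``sirna-only`` uses the sum of the table's counts as denominator (unless
    an explicit ``library_size`` is given); ``exon-background`` adds
    ``background_count`` exon-mapped reads to that denominator.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}; choose from {NORMALIZATION_MODES}")
    if library_size is None:
        library_size = table.raw_total()
        if mode == "exon-background":
            library_size += background_count
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    rows = [
        CountRow(key=row.key, raw_count=row.raw_count,
                 cpm=row.raw_count / library_size * 1e6)
        for row in table.rows
    ]
    return CountTable(rows=rows, library_size=library_size)


def filter_by_cpm(table: CountTable, threshold: float = DEFAULT_CPM_THRESHOLD) -> CountTable:
    """Retain rows with cpm >= threshold (inclusive), preserving order."""
    for row in table.rows:
        if row.cpm is None:
            raise ValueError("cpm column not populated; run cpm_normalize first")
    return CountTable(
        rows=[row for row in table.rows if row.cpm >= threshold],
        library_size=table.library_size,
    )


def write_count_tsv(table: CountTable, path: str | Path, key_name: str = "gene_id") -> None:
    with open(path, "w") as handle:
        handle.write(f"{key_name}\traw_count\tcpm\n")
        for row in table.rows:
            cpm = "" if row.cpm is None else f"{row.cpm:.6g}"
            raw = int(row.raw_count) if float(row.raw_count).is_integer() else row.raw_count
            handle.write(f"{row.key}\t{raw}\t{cpm}\n")
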