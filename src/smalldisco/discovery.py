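"""Antisense read filtering and r/s-gated merging into putative siRNA regions.

Reads are decomposed into reference-matched blocks (spliced alignments are
split at skipped-region segments, so a junction-spanning read contributes
one block per exon side). Blocks overlapping a candidate region on the
opposite strand are clustered transitively per (chrom, read strand); a
cluster becomes a putative siRNA region if it has at least ``r`` supporting
blocks and spans at least ``s`` base pairs.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from smalldisco.annotation import CandidateRegionSet
from smalldisco.intervals import GenomeInterval, Region

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 17
DEFAULT_MAX_LEN = 35

# CIGAR ops consuming the reference within one block: M, D, =, X
_BLOCK_OPS = {0, 2, 7, 8}
_SKIP_OP = 3  # N: splits blocks


@dataclass
class AlignedRead:
    """One read alignment decomposed into reference-matched blocks."""

    read_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    seq: str
    is_primary: bool = True


@dataclass
class SirnaRegion:
    """A merged antisense read cluster passing the r/s gates."""

    interval: GenomeInterval
    read_count: int
    gene_ids: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class AntisenseHit:
    """One read block paired with the candidate region it maps antisense to."""

    read_id: str
    chrom: str
    strand: str  # read alignment strand
    block: tuple[int, int]
    region: Region


def cigar_blocks(aln: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Reference blocks of an alignment, split at N (skipped) segments."""
    blocks: list[tuple[int, int]] = []
    pos = aln.reference_start
    block_start = pos
    open_block = False
    for op, length in aln.cigartuples or []:
        if op in _BLOCK_OPS:
            if not open_block:
                block_start = pos
                open_block = True
            pos += length
        elif op == _SKIP_OP:
            if open_block:
                blocks.append((block_start, pos))
                open_block = False
            pos += length
        # I/S/H/P do not consume reference
    if open_block:
        blocks.append((block_start, pos))
    return blocks


def load_alignments(
    path: str | Path,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    *,
    keep_secondary: bool = False,
) -> Iterator[AlignedRead]:
    """Stream primary, mapped alignments within a read-length window.

    Secondary, supplementary, and unmapped records are skipped (a flag
    admits secondaries). ``seq`` is reported in original read orientation
    (reverse-complemented back for minus-strand alignments).
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    with pysam.AlignmentFile(str(path), "rb") as bam:
        if bam.header.get("HD", {}).get("SO") not in (None, "coordinate"):
            raise ValueError(f"{path} is not coordinate-sorted (SO tag)")
        for aln in bam:
            if aln.is_unmapped or aln.is_supplementary:
                continue
            if aln.is_secondary and not keep_secondary:
                continue
            seq = aln.query_sequence
            if seq is None:
                continue
            if not (min_len <= len(seq) <= max_len):
                continue
            blocks = cigar_blocks(aln)
            if not blocks:
                continue
            if aln.is_reverse:
                seq = reverse_complement(seq)
            yield AlignedRead(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                strand="-" if aln.is_reverse else "+",
                blocks=blocks,
                seq=seq,
                is_primary=not aln.is_secondary,
            )


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class _RegionIndex:
    """Sorted-start overlap lookup over disjoint regions of one (chrom, strand)."""

    def __init__(self, regions: list[Region]):
        self.regions = regions
        self.starts = [r.interval.start for r in regions]

    def find_all(self, start: int, end: int) -> list[Region]:
        # Regions are disjoint and sorted; a short block usually hits at most
        # one, but a block spanning a gap can touch several.
        idx = max(0, bisect_right(self.starts, start) - 1)
        hits = []
        for cand in self.regions[idx:]:
            if cand.interval.start >= end:
                break
            if start < cand.interval.end:
                hits.append(cand)
        return hits


def filter_antisense(
    reads: Iterable[AlignedRead], regions: CandidateRegionSet
) -> Iterator[AntisenseHit]:
    """Emit read blocks overlapping (>= 1 base) an opposite-strand candidate region."""
    opposite = {"+": "-", "-": "+"}
    indexes: dict[tuple[str, str], _RegionIndex] = {
        key: _RegionIndex(regs) for key, regs in regions.by_chrom_strand().items()
    }
    for read in reads:
        index = indexes.get((read.chrom, opposite[read.strand]))
        if index is None:
            continue
        for block in read.blocks:
            for region in index.find_all(*block):
                yield AntisenseHit(
                    read_id=read.read_id,
                    chrom=read.chrom,
                    strand=read.strand,
                    block=block,
                    region=region,
                )


def merge_into_sirna_regions(
    hits: Iterable[AntisenseHit],
    r: int = 10,
    s: int = 10,
    *,
    strict_greater_r: bool = False,
) -> list[SirnaRegion]:
    """Transitively merge antisense blocks and keep clusters passing r and s.

    A cluster passes with ``count >= r`` (or ``count > r`` under the
    strict-greater reading) and merged span ``>= s``. Blocks joining a
    cluster must share at least one base with it.
    """
    if r < 1 or s < 1:
        raise ValueError("r and s must be >= 1")
    # A block touching two candidate regions (across a gap) counts once but
    # inherits both regions' gene ids.
    grouped: dict[tuple[str, str], dict[tuple[str, tuple[int, int]], set[str]]] = {}
    for hit in hits:
        per_block = grouped.setdefault((hit.chrom, hit.strand), {})
        per_block.setdefault((hit.read_id, hit.block), set()).update(hit.region.gene_ids)

    out: list[SirnaRegion] = []
    for (chrom, strand), per_block in grouped.items():
        items = sorted(
            ((block, genes) for (_, block), genes in per_block.items()),
            key=lambda item: item[0],
        )
        cluster: list[tuple[tuple[int, int], set[str]]] = []
        cluster_end = -1

        def flush() -> None:
            if not cluster:
                return
            count = len(cluster)
            passes_r = count > r if strict_greater_r else count >= r
            start = cluster[0][0][0]
            end = max(block[1] for block, _ in cluster)
            if passes_r and (end - start) >= s:
                genes: set[str] = set()
                for _, block_genes in cluster:
                    genes |= block_genes
                out.append(
                    SirnaRegion(
                        interval=GenomeInterval(chrom, start, end, strand),
                        read_count=count,
                        gene_ids=frozenset(genes),
                    )
                )

        for block, genes in items:
            if cluster and block[0] < cluster_end:
                cluster.append((block, genes))
                cluster_end = max(cluster_end, block[1])
            else:
                flush()
                cluster = [(block, genes)]
                cluster_end = block[1]
        flush()
    out.sort(key=lambda reg: (reg.interval.chrom, reg.interval.start))
    return out


def write_sirna_bed(regions: list[SirnaRegion], path: str | Path) -> None:
    """Write putative siRNA regions as BED6 sorted by (chrom, start).

    Name column is the semicolon-joined gene ids plus a serial ``.sirN``
    suffix; score is the supporting read count; strand is the read strand.
    """
    ordered = sorted(regions, key=lambda reg: (reg.interval.chrom, reg.interval.start))
    with open(path, "w") as handle:
        for serial, region in enumerate(ordered, start=1):
            iv = region.interval
            genes = ";".join(sorted(region.gene_ids)) or "."
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{genes}.sir{serial}\t"
                f"{region.read_count}\t{iv.strand}\n"
            )


def read_sirna_bed(path: str | Path) -> list[SirnaRegion]:
    """Parse a BED6 written by :func:`write_sirna_bed` (round-trip oracle)."""
    regions: list[SirnaRegion] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns")
            name = cols[3].rsplit(".sir", 1)[0]
            gene_ids = frozenset(g for g in name.split(";") if g and g != ".")
            regions.append(
                SirnaRegion(
                    interval=GenomeInterval(cols[0], int(cols[1]), int(cols[2]), cols[5]),
                    read_count=int(float(cols[4])),
                    gene_ids=gene_ids,
                )
            )
    return regions
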