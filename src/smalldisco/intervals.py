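"""Stranded genomic intervals: the unit of all region algebra.

Internal convention is 0-based, half-open ``[start, end)`` throughout the
package. GTF/GFF input (1-based inclusive) is converted at parse time; BED
output shares the internal convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A stranded half-open interval on a named reference sequence."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval", *, ignore_strand: bool = False) -> bool:
        """True if the two intervals share at least one base on the same chrom."""
        if self.chrom != other.chrom:
            return False
        if not ignore_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass
class Region:
    """A candidate-region fragment: interval plus the gene ids merged into it."""

    interval: GenomeInterval
    gene_ids: frozenset[str] = field(default_factory=frozenset)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge half-open intervals that share at least one base.

    Bookended intervals (end of one == start of the next) share no base and
    are kept separate.
    """
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start < out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def subtract_intervals(
    intervals: list[tuple[int, int]], holes: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Remove every base of ``holes`` from ``intervals`` (both half-open).

    Subtraction may split an interval in two. Inputs need not be sorted.
    """
    holes = merge_intervals(list(holes))
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        cur = start
        for hs, he in holes:
            if he <= cur or hs >= end:
                continue
            if hs > cur:
                out.append((cur, hs))
            cur = max(cur, he)
            if cur >= end:
                break
        if cur < end:
            out.append((cur, end))
    return out
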