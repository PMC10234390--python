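"""3' nontemplated tail calling against a reference genome.

Each read is decomposed into a templated 5' prefix — the longest prefix that
matches the genome exactly, with zero mismatches, on either strand — and a
3' nontemplated tail (the remaining suffix, empty if the whole read is
templated). Calls are assigned to stranded regions and tabulated per target
with ``untailed`` and ``all_tails`` totals; the two always sum to the total
reads assigned to the target.
"""

from __future__ import annotations

import csv
import logging
import random
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from smalldisco.discovery import SirnaRegion, read_sirna_bed, reverse_complement
from smalldisco.intervals import GenomeInterval

logger = logging.getLogger(__name__)

DEFAULT_MIN_PREFIX = 18

MULTIMAP_POLICIES = ("fractional", "random", "drop")


@dataclass
class TailCall:
    """One read's templated-prefix match plus its nontemplated 3' suffix."""

    read_id: str
    templated_len: int
    tail_seq: str  # DNA alphabet, read orientation; empty = untailed
    target_interval: GenomeInterval
    weight: float = 1.0


@dataclass
class TailTable:
    """Per-target tail summary: counts per tail type plus totals."""

    rows: dict[str, dict[str, float]] = field(default_factory=dict)
    unassigned: float = 0.0

    def add(self, target: str, tail: str, weight: float = 1.0) -> None:
        self.rows.setdefault(target, defaultdict(float))[tail] += weight

    def untailed(self, target: str) -> float:
        return self.rows.get(target, {}).get("", 0.0)

    def all_tails(self, target: str) -> float:
        return sum(count for tail, count in self.rows.get(target, {}).items() if tail)

    def total(self, target: str) -> float:
        return sum(self.rows.get(target, {}).values())


class Genome:
    """Indexed reference with a k-mer seed table for templated-prefix search."""

    def __init__(self, fasta_path: str | Path, seed_len: int = DEFAULT_MIN_PREFIX):
        self.seed_len = seed_len
        self.seqs: dict[str, str] = {}
        with pysam.FastxFile(str(fasta_path)) as fh:
            for record in fh:
                self.seqs[record.name] = record.sequence.upper()
        self._seed_index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in self.seqs.items():
            for pos in range(len(seq) - seed_len + 1):
                kmer = seq[pos : pos + seed_len]
                if "N" not in kmer:
                    self._seed_index[kmer].append((chrom, pos))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.seqs:
            raise KeyError(f"reference sequence {chrom!r} not in FASTA")
        return self.seqs[chrom][max(0, start) : end]

    def seed_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._seed_index.get(kmer, [])


def call_tail(
    read_seq: str,
    genome: Genome,
    min_prefix: int = DEFAULT_MIN_PREFIX,
    read_id: str = "",
) -> list[TailCall]:
    """Find the maximal exactly-templated prefix of a read on either strand.

    Returns one TailCall per genomic location achieving the maximal
    templated length L >= min_prefix, with ``tail_seq = read_seq[L:]``.
    Minus-strand locations match the reverse complement of the genome; their
    target interval grows leftward as the prefix extends. An ``N`` in the
    read matches nothing. Empty list if no location reaches ``min_prefix``.
    """
    if min_prefix < 1:
        raise ValueError("min_prefix must be >= 1")
    if min_prefix != genome.seed_len:
        raise ValueError(
            f"min_prefix ({min_prefix}) must equal the genome seed length "
            f"({genome.seed_len}); rebuild the Genome with seed_len=min_prefix"
        )
    read_seq = read_seq.upper()
    if len(read_seq) < min_prefix:
        return []
    seed = read_seq[:min_prefix]
    if "N" in seed:
        return []

    best_len = 0
    best: list[tuple[str, int, str]] = []  # (chrom, prefix_start, strand)

    # Plus strand: genome[pos : pos+L] == read[:L]; extend rightward.
    for chrom, pos in genome.seed_hits(seed):
        seq = genome.seqs[chrom]
        length = min_prefix
        while (
            length < len(read_seq)
            and pos + length < len(seq)
            and read_seq[length] != "N"
            and seq[pos + length] == read_seq[length]
        ):
            length += 1
        if length > best_len:
            best_len, best = length, [(chrom, pos, "+")]
        elif length == best_len:
            best.append((chrom, pos, "+"))

    # Minus strand: genome[pos : pos+L] == revcomp(read[:L]); the seed sits at
    # the right edge of the interval and extension moves the left edge down.
    rc_seed = reverse_complement(seed)
    for chrom, pos in genome.seed_hits(rc_seed):
        seq = genome.seqs[chrom]
        length = min_prefix
        while (
            length < len(read_seq)
            and pos - (length - min_prefix) - 1 >= 0
            and read_seq[length] != "N"
            and seq[pos - (length - min_prefix) - 1]
            == reverse_complement(read_seq[length])
        ):
            length += 1
        start = pos - (length - min_prefix)
        if length > best_len:
            best_len, best = length, [(chrom, start, "-")]
        elif length == best_len:
            best.append((chrom, start, "-"))

    calls = []
    for chrom, start, strand in best:
        calls.append(
            TailCall(
                read_id=read_id,
                templated_len=best_len,
                tail_seq=read_seq[best_len:],
                target_interval=GenomeInterval(chrom, start, start + best_len, strand),
            )
        )
    return calls


def resolve_multimappers(
    calls: Sequence[TailCall],
    policy: str = "fractional",
    rng: random.Random | None = None,
) -> list[TailCall]:
    """Weight or select among one read's equal-best locations.

    ``fractional``: each of k locations gets weight 1/k. ``random``: one
    location is chosen with the run's seeded RNG. ``drop``: reads with
    k > 1 are discarded.
    """
    if policy not in MULTIMAP_POLICIES:
        raise ValueError(f"unknown multimap policy {policy!r}; choose from {MULTIMAP_POLICIES}")
    if not calls:
        return []
    if len(calls) == 1:
        return list(calls)
    if policy == "drop":
        return []
    if policy == "random":
        if rng is None:
            rng = random.Random()
        return [rng.choice(list(calls))]
    k = len(calls)
    weighted = []
    for call in calls:
        weighted.append(
            TailCall(
                read_id=call.read_id,
                templated_len=call.templated_len,
                tail_seq=call.tail_seq,
                target_interval=call.target_interval,
                weight=1.0 / k,
            )
        )
    return weighted


def dna_tail_to_rna(tail: str) -> str:
    """Report tails in the RNA alphabet (T -> U); internal work stays in DNA."""
    return tail.replace("T", "U").replace("t", "u")


def assign_to_regions(
    calls: Iterable[TailCall],
    regions: Sequence[SirnaRegion],
    *,
    antisense_assign: bool = False,
) -> TailTable:
    """Assign calls to every same-strand region their templated interval overlaps.

    Region names follow the BED serial convention (``genes.sirN``). With
    ``antisense_assign`` the strand test is inverted, for user BEDs
    annotated on the genomic sense strand. Tails are tabulated in the RNA
    alphabet; calls overlapping no region increment ``unassigned``.
    """
    opposite = {"+": "-", "-": "+"}
    by_chrom_strand: dict[tuple[str, str], list[tuple[int, int, str]]] = defaultdict(list)
    ordered = sorted(regions, key=lambda reg: (reg.interval.chrom, reg.interval.start))
    for serial, region in enumerate(ordered, start=1):
        iv = region.interval
        genes = ";".join(sorted(region.gene_ids)) or "."
        name = f"{genes}.sir{serial}"
        key_strand = opposite[iv.strand] if antisense_assign else iv.strand
        by_chrom_strand[(iv.chrom, key_strand)].append((iv.start, iv.end, name))
    for lst in by_chrom_strand.values():
        lst.sort()

    table = TailTable()
    for call in calls:
        iv = call.target_interval
        assigned = False
        for start, end, name in by_chrom_strand.get((iv.chrom, iv.strand), []):
            if start >= iv.end:
                break
            if iv.start < end:
                table.add(name, dna_tail_to_rna(call.tail_seq), call.weight)
                assigned = True
        if not assigned:
            table.unassigned += call.weight
    return table


def write_tail_csv(table: TailTable, path: str | Path) -> None:
    """Write the long-format tail table: target,tail,count.

    Observed tail strings (U alphabet) plus the reserved ``untailed`` and
    ``all_tails`` rows, one of each per target, stable-sorted by
    (target, tail).
    """
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["target", "tail", "count"])
        for target in sorted(table.rows):
            counts = table.rows[target]
            entries: list[tuple[str, float]] = [("untailed", counts.get("", 0.0))]
            entries.extend(
                (tail, count) for tail, count in counts.items() if tail
            )
            entries.append(("all_tails", table.all_tails(target)))
            for tail, count in sorted(entries, key=lambda e: e[0]):
                writer.writerow([target, tail, _fmt_count(count)])


def _fmt_count(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(value)


def read_tail_csv(path: str | Path) -> TailTable:
    """Re-parse a written tail CSV into a TailTable (round-trip oracle)."""
    table = TailTable()
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        for row in reader:
            tail = row["tail"]
            count = float(row["count"])
            if tail == "all_tails":
                continue
            if tail == "untailed":
                tail = ""
            table.add(row["target"], tail, count)
    return table


def extract_read_sequences(path: str | Path) -> Iterable[tuple[str, str]]:
    """Yield (read_id, sequence in read orientation) from BAM/SAM or FASTQ/FASTA."""
    suffix = Path(path).suffix.lower()
    if suffix in (".bam", ".sam", ".cram"):
        mode = {"": "r", ".bam": "rb", ".sam": "r", ".cram": "rc"}[suffix]
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
            for aln in bam:
                if aln.is_secondary or aln.is_supplementary:
                    continue
                seq = aln.query_sequence
                if seq is None:
                    continue
                if aln.is_reverse:
                    seq = reverse_complement(seq)
                yield aln.query_name, seq
    else:
        with pysam.FastxFile(str(path)) as fh:
            for record in fh:
                yield record.name, record.sequence


def run_tail_pipeline(
    reads_path: str | Path,
    genome_fasta: str | Path,
    regions_bed: str | Path,
    *,
    min_prefix: int = DEFAULT_MIN_PREFIX,
    multimap: str = "fractional",
    seed: int | None = None,
    antisense_assign: bool = False,
) -> tuple[TailTable, dict[str, int]]:
    """End-to-end tail mode: call tails, resolve multimappers, tabulate.

    Returns the table and a stage-count report (reads seen, called,
    multimapped, dropped, unassigned weight).
    """
    genome = Genome(genome_fasta, seed_len=min_prefix)
    regions = read_sirna_bed(regions_bed)
    rng = random.Random(seed)
    stats = {"reads": 0, "called": 0, "uncallable": 0, "multimapped": 0, "dropped": 0}
    resolved: list[TailCall] = []
    for read_id, seq in extract_read_sequences(reads_path):
        stats["reads"] += 1
        calls = call_tail(seq, genome, min_prefix=min_prefix, read_id=read_id)
        if not calls:
            stats["uncallable"] += 1
            continue
        stats["called"] += 1
        if len(calls) > 1:
            stats["multimapped"] += 1
        kept = resolve_multimappers(calls, policy=multimap, rng=rng)
        if not kept:
            stats["dropped"] += 1
        resolved.extend(kept)
    table = assign_to_regions(resolved, regions, antisense_assign=antisense_assign)
    stats["unassigned_weight"] = table.unassigned
    return table, stats
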