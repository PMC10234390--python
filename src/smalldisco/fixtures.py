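"""Self-contained synthetic inputs: toy genome, annotation, and reads with
planted antisense siRNA clusters and known 3' tails, plus ground-truth
manifests.

Everything is deterministic under a fixed seed. Planted clusters are built
so that their read-coverage footprint equals the recorded window exactly:
every read in a cluster covers the window's center base (guaranteed for
spans up to ``2*read_len - 1``), the first read starts at the window start,
and the last read ends at the window end. Noise reads (sense-strand decoys
and intergenic reads) are placed so they can never enter an antisense
cluster.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from smalldisco.discovery import reverse_complement
from smalldisco.tailing import dna_tail_to_rna

DEFAULT_READ_LEN = 22
BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class ClusterSpec:
    """One planted antisense cluster inside an exon.

    ``span`` defaults to ``read_len`` (all reads identical). ``junction``
    plants reads at the 3' edge of exon ``exon_index`` and the 5' edge of
    the next exon, plus ``junction_reads`` spliced reads bridging them.
    """

    gene_index: int
    exon_index: int = 0
    n_reads: int = 10
    span: int | None = None
    junction: bool = False
    junction_reads: int = 0


@dataclass
class PlantedRegion:
    chrom: str
    start: int
    end: int
    strand: str  # read strand
    read_count: int
    gene_id: str
    passes: bool


@dataclass
class TruthManifest:
    seed: int
    read_len: int
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    planted_tails: dict[str, dict[str, int]] = field(default_factory=dict)
    planted_gene_counts: dict[str, int] = field(default_factory=dict)
    n_sense_noise: int = 0
    n_intergenic_noise: int = 0

    def region_key(self, region: PlantedRegion) -> str:
        return f"{region.chrom}:{region.start}-{region.end}({region.strand})"

    def passing_regions(self) -> list[PlantedRegion]:
        return [r for r in self.planted_regions if r.passes]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "read_len": self.read_len,
            "planted_regions": [vars(r) for r in self.planted_regions],
            "planted_tails": self.planted_tails,
            "planted_gene_counts": self.planted_gene_counts,
            "n_sense_noise": self.n_sense_noise,
            "n_intergenic_noise": self.n_intergenic_noise,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        manifest = cls(seed=payload["seed"], read_len=payload["read_len"])
        manifest.planted_regions = [PlantedRegion(**r) for r in payload["planted_regions"]]
        manifest.planted_tails = payload["planted_tails"]
        manifest.planted_gene_counts = payload["planted_gene_counts"]
        manifest.n_sense_noise = payload["n_sense_noise"]
        manifest.n_intergenic_noise = payload["n_intergenic_noise"]
        return manifest


def make_genome(
    path: str | Path, n_chroms: int = 1, length: int = 10_000, seed: int = 0
) -> dict[str, str]:
    """Write a random FASTA (60-column wrapped) plus .fai index; return the sequences."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    rng = random.Random(seed)
    seqs: dict[str, str] = {}
    with open(path, "w") as handle:
        for i in range(n_chroms):
            name = f"chr{'I' * (i + 1)}" if n_chroms <= 3 else f"chr{i + 1}"
            seq = "".join(rng.choice(BASES) for _ in range(length))
            seqs[name] = seq
            handle.write(f">{name}\n")
            for off in range(0, length, 60):
                handle.write(seq[off : off + 60] + "\n")
    pysam.faidx(str(path))
    return seqs


class PlacementError(ValueError):
    """Requested genes cannot be placed within the genome."""


def make_annotation(
    path: str | Path,
    chrom_lengths: dict[str, int],
    n_genes: int = 10,
    exons_per_gene: int = 1,
    seed: int = 0,
    exon_len: int = 150,
    intron_len: int = 60,
    gap: int = 100,
    strand_mix: float = 0.5,
    cross_strand_overlap_pairs: int = 0,
) -> list[GeneModel]:
    """Write a GTF of exon features; return the gene layout.

    Genes are laid out left to right with ``gap`` bp between them, so they
    never overlap by default. ``cross_strand_overlap_pairs`` extra gene
    pairs are appended with exons overlapping across strands, recorded in
    the layout for region-algebra tests. Introns are at least 50 bp.
    """
    if intron_len < 50:
        raise ValueError("introns must be >= 50 bp")
    rng = random.Random(seed)
    genes: list[GeneModel] = []
    chroms = sorted(chrom_lengths)
    gene_width = exons_per_gene * exon_len + (exons_per_gene - 1) * intron_len

    cursor = {chrom: gap for chrom in chroms}
    chrom_cycle = 0
    for g in range(n_genes):
        placed = False
        for _ in range(len(chroms)):
            chrom = chroms[chrom_cycle % len(chroms)]
            chrom_cycle += 1
            start = cursor[chrom]
            if start + gene_width + gap <= chrom_lengths[chrom]:
                strand = "+" if rng.random() < strand_mix else "-"
                exons = [
                    (start + k * (exon_len + intron_len),
                     start + k * (exon_len + intron_len) + exon_len)
                    for k in range(exons_per_gene)
                ]
                genes.append(GeneModel(f"g{g + 1}", chrom, strand, exons))
                cursor[chrom] = start + gene_width + gap
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"cannot place gene {g + 1} of {n_genes} (width {gene_width} bp)"
            )

    for p in range(cross_strand_overlap_pairs):
        chrom = chroms[0]
        start = cursor[chrom]
        if start + 2 * exon_len + gap > chrom_lengths[chrom]:
            raise PlacementError("no room for cross-strand overlap pair")
        shift = exon_len // 2
        idx = len(genes)
        genes.append(GeneModel(f"g{idx + 1}", chrom, "+", [(start, start + exon_len)]))
        genes.append(
            GeneModel(f"g{idx + 2}", chrom, "-", [(start + shift, start + shift + exon_len)])
        )
        cursor[chrom] = start + shift + exon_len + gap

    with open(path, "w") as handle:
        for gene in genes:
            for exon_start, exon_end in gene.exons:
                handle.write(
                    f"{gene.chrom}\ttoy\texon\t{exon_start + 1}\t{exon_end}\t.\t"
                    f'{gene.strand}\t.\tgene_id "{gene.gene_id}"; '
                    f'transcript_id "{gene.gene_id}.t1";\n'
                )
    return genes


@dataclass
class _Read:
    read_id: str
    chrom: str
    strand: str  # alignment strand
    pos: int
    cigar: list[tuple[int, int]]
    stored_seq: str  # forward-reference orientation, as stored in BAM
    read_seq: str  # original read orientation


def _draw_tail(rng: random.Random, tail_spec: dict[str, float], forbidden_first: str) -> str:
    """Draw a tail from the spec, rejecting tails the genome would template."""
    tails = sorted(tail_spec)
    weights = [tail_spec[t] for t in tails]
    for _ in range(100):
        tail = rng.choices(tails, weights=weights)[0]
        if not tail or tail[0] != forbidden_first:
            return tail
    return ""


def _antisense_read(
    rng: random.Random,
    seqs: dict[str, str],
    gene: GeneModel,
    block: tuple[int, int],
    tail_spec: dict[str, float] | None,
    read_id: str,
) -> tuple[_Read, str]:
    """Build one antisense read over a genomic block, with an optional tail.

    Returns the read and the planted tail (DNA alphabet). The tail's first
    base is constrained not to extend the templated prefix at this location.
    """
    chrom_seq = seqs[gene.chrom]
    start, end = block
    template = chrom_seq[start:end]
    read_strand = "-" if gene.strand == "+" else "+"
    tail = ""
    if tail_spec:
        if read_strand == "-":
            # 3' extension walks leftward on the reference.
            next_templated = _COMPLEMENT[chrom_seq[start - 1]] if start > 0 else ""
        else:
            next_templated = chrom_seq[end] if end < len(chrom_seq) else ""
        tail = _draw_tail(rng, tail_spec, next_templated)
    if read_strand == "-":
        read_seq = reverse_complement(template) + tail
        stored_seq = reverse_complement(tail) + template
        cigar = ([(4, len(tail))] if tail else []) + [(0, len(template))]
    else:
        read_seq = template + tail
        stored_seq = template + tail
        cigar = [(0, len(template))] + ([(4, len(tail))] if tail else [])
    return (
        _Read(read_id, gene.chrom, read_strand, start, cigar, stored_seq, read_seq),
        tail,
    )


def make_reads(
    out_prefix: str | Path,
    seqs: dict[str, str],
    genes: list[GeneModel],
    clusters: list[ClusterSpec],
    read_len: int = DEFAULT_READ_LEN,
    tail_spec: dict[str, float] | None = None,
    noise_rate: float = 0.1,
    seed: int = 0,
    r: int = 10,
    s: int = 10,
) -> TruthManifest:
    """Plant antisense read clusters, write BAM (+index), FASTQ, and manifest.

    Each cluster's ``passes`` label is computed against the ``r``/``s``
    gates the fixture was built for. Tails are drawn per read from
    ``tail_spec`` (a distribution over DNA tail strings; probabilities must
    sum to 1) and recorded per region in the manifest, keyed by
    ``chrom:start-end(strand)`` in the RNA alphabet.
    """
    if tail_spec is not None:
        total_p = sum(tail_spec.values())
        if abs(total_p - 1.0) > 1e-9:
            raise ValueError(f"tail_spec probabilities sum to {total_p}, expected 1")
    rng = random.Random(seed)
    out_prefix = Path(out_prefix)
    manifest = TruthManifest(seed=seed, read_len=read_len)
    reads: list[_Read] = []
    serial = 0

    def next_id(kind: str) -> str:
        nonlocal serial
        serial += 1
        return f"{kind}{serial}"

    placed_windows: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for spec in clusters:
        gene = genes[spec.gene_index]
        if spec.junction:
            _plant_junction(
                rng, seqs, gene, spec, read_len, tail_spec, manifest, reads, next_id
            )
        else:
            _plant_cluster(
                rng, seqs, gene, spec, read_len, tail_spec, manifest, reads,
                next_id, r, s, placed_windows.setdefault(
                    (spec.gene_index, spec.exon_index), []
                ),
            )

    n_planted = len(reads)
    n_noise = int(round(noise_rate * n_planted))
    n_sense = n_noise // 2
    n_intergenic = n_noise - n_sense
    _plant_sense_decoys(rng, seqs, genes, n_sense, read_len, reads, next_id)
    _plant_intergenic(rng, seqs, genes, n_intergenic, read_len, reads, next_id)
    manifest.n_sense_noise = n_sense
    manifest.n_intergenic_noise = n_intergenic

    for region in manifest.planted_regions:
        if region.passes:
            manifest.planted_gene_counts[region.gene_id] = (
                manifest.planted_gene_counts.get(region.gene_id, 0) + region.read_count
            )

    _write_bam(out_prefix.with_suffix(".bam"), seqs, reads)
    _write_fastq(out_prefix.with_suffix(".fastq"), reads)
    manifest.to_json(out_prefix.with_suffix(".manifest.json"))
    return manifest


def _plant_cluster(
    rng, seqs, gene, spec, read_len, tail_spec, manifest, reads, next_id, r, s,
    placed: list[tuple[int, int]],
):
    exon_start, exon_end = gene.exons[spec.exon_index]
    span = spec.span if spec.span is not None else read_len
    if span < read_len or span > 2 * read_len - 1:
        raise ValueError(
            f"cluster span must be in [read_len, 2*read_len-1] = "
            f"[{read_len}, {2 * read_len - 1}], got {span}"
        )
    if exon_end - exon_start < span:
        raise PlacementError(f"cluster span {span} exceeds exon length")
    # Windows sharing an exon must stay >= 2 bp apart so footprints never touch.
    for _ in range(500):
        w_start = exon_start + rng.randrange(exon_end - exon_start - span + 1)
        w_end = w_start + span
        if all(w_start > pe + 1 or w_end < ps - 1 for ps, pe in placed):
            break
    else:
        raise PlacementError("could not place cluster window apart from existing ones")
    placed.append((w_start, w_end))
    starts = [w_start, w_end - read_len]
    for _ in range(max(0, spec.n_reads - 2)):
        starts.append(w_start + rng.randrange(span - read_len + 1))
    starts = starts[: spec.n_reads]
    tail_counts: dict[str, int] = {}
    for start in starts:
        read, tail = _antisense_read(
            rng, seqs, gene, (start, start + read_len), tail_spec, next_id("cl")
        )
        reads.append(read)
        rna = dna_tail_to_rna(tail)
        tail_counts[rna] = tail_counts.get(rna, 0) + 1
    footprint_start = min(starts)
    footprint_end = max(st + read_len for st in starts)
    read_strand = "-" if gene.strand == "+" else "+"
    region = PlantedRegion(
        chrom=gene.chrom,
        start=footprint_start,
        end=footprint_end,
        strand=read_strand,
        read_count=spec.n_reads,
        gene_id=gene.gene_id,
        passes=spec.n_reads >= r and (footprint_end - footprint_start) >= s,
    )
    manifest.planted_regions.append(region)
    manifest.planted_tails[manifest.region_key(region)] = tail_counts


def _plant_junction(rng, seqs, gene, spec, read_len, tail_spec, manifest, reads, next_id):
    """Reads hugging an exon-exon boundary plus spliced reads bridging it."""
    if spec.exon_index + 1 >= len(gene.exons):
        raise ValueError("junction cluster needs a following exon")
    e1_start, e1_end = gene.exons[spec.exon_index]
    e2_start, e2_end = gene.exons[spec.exon_index + 1]
    read_strand = "-" if gene.strand == "+" else "+"
    chrom_seq = seqs[gene.chrom]

    windows = [(e1_end - read_len, e1_end), (e2_start, e2_start + read_len)]
    counts = [0, 0]
    for side, (w_start, w_end) in enumerate(windows):
        if spec.n_reads <= 0:
            continue
        for _ in range(spec.n_reads):
            read, _ = _antisense_read(
                rng, seqs, gene, (w_start, w_end), None, next_id("jx")
            )
            reads.append(read)
            counts[side] += 1

    half = read_len // 2
    intron = e2_start - e1_end
    for _ in range(spec.junction_reads):
        b1 = (e1_end - half, e1_end)
        b2 = (e2_start, e2_start + (read_len - half))
        template = chrom_seq[b1[0] : b1[1]] + chrom_seq[b2[0] : b2[1]]
        if read_strand == "-":
            stored_seq, read_seq = template, reverse_complement(template)
        else:
            stored_seq, read_seq = template, template
        cigar = [(0, half), (3, intron), (0, read_len - half)]
        reads.append(
            _Read(next_id("jx"), gene.chrom, read_strand, b1[0], cigar, stored_seq, read_seq)
        )
        counts[0] += 1
        counts[1] += 1

    for side, (w_start, w_end) in enumerate(windows):
        if counts[side] == 0:
            continue
        region = PlantedRegion(
            chrom=gene.chrom,
            start=w_start,
            end=w_end,
            strand=read_strand,
            read_count=counts[side],
            gene_id=gene.gene_id,
            passes=True,
        )
        manifest.planted_regions.append(region)
        manifest.planted_tails[manifest.region_key(region)] = {"": counts[side]}


def _plant_sense_decoys(rng, seqs, genes, n, read_len, reads, next_id):
    """Reads on the SAME strand as their gene: dropped by the antisense filter."""
    if not genes or n <= 0:
        return
    for _ in range(n):
        gene = rng.choice(genes)
        exon_start, exon_end = rng.choice(gene.exons)
        if exon_end - exon_start < read_len:
            continue
        start = exon_start + rng.randrange(exon_end - exon_start - read_len + 1)
        template = seqs[gene.chrom][start : start + read_len]
        if gene.strand == "+":
            reads.append(
                _Read(next_id("ns"), gene.chrom, "+", start, [(0, read_len)], template, template)
            )
        else:
            reads.append(
                _Read(
                    next_id("ns"), gene.chrom, "-", start, [(0, read_len)],
                    template, reverse_complement(template),
                )
            )


def _plant_intergenic(rng, seqs, genes, n, read_len, reads, next_id):
    """Reads placed entirely between genes: overlap no candidate region."""
    if n <= 0:
        return
    gaps: list[tuple[str, int, int]] = []
    for chrom, seq in seqs.items():
        spans = sorted(g.span for g in genes if g.chrom == chrom)
        cursor = 0
        for start, end in spans:
            if start - cursor >= read_len + 2:
                gaps.append((chrom, cursor + 1, start - 1))
            cursor = max(cursor, end)
        if len(seq) - cursor >= read_len + 2:
            gaps.append((chrom, cursor + 1, len(seq) - 1))
    if not gaps:
        return
    for _ in range(n):
        chrom, gap_start, gap_end = rng.choice(gaps)
        start = gap_start + rng.randrange(gap_end - gap_start - read_len + 1)
        template = seqs[chrom][start : start + read_len]
        if rng.random() < 0.5:
            reads.append(
                _Read(next_id("ni"), chrom, "+", start, [(0, read_len)], template, template)
            )
        else:
            reads.append(
                _Read(
                    next_id("ni"), chrom, "-", start, [(0, read_len)],
                    template, reverse_complement(template),
                )
            )


def _write_bam(path: Path, seqs: dict[str, str], reads: list[_Read]) -> None:
    chroms = sorted(seqs)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": len(seqs[chrom])} for chrom in chroms],
    }
    ref_ids = {chrom: i for i, chrom in enumerate(chroms)}
    ordered = sorted(reads, key=lambda rd: (ref_ids[rd.chrom], rd.pos, rd.read_id))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for read in ordered:
            aln = pysam.AlignedSegment(bam.header)
            aln.query_name = read.read_id
            aln.query_sequence = read.stored_seq
            aln.flag = 16 if read.strand == "-" else 0
            aln.reference_id = ref_ids[read.chrom]
            aln.reference_start = read.pos
            aln.mapping_quality = 60
            aln.cigartuples = read.cigar
            aln.query_qualities = pysam.qualitystring_to_array("I" * len(read.stored_seq))
            bam.write(aln)
    pysam.index(str(path))


def _write_fastq(path: Path, reads: list[_Read]) -> None:
    with open(path, "w") as handle:
        for read in sorted(reads, key=lambda rd: rd.read_id):
            handle.write(f"@{read.read_id}\n{read.read_seq}\n+\n{'I' * len(read.read_seq)}\n")


@dataclass
class PlantedTailRead:
    read_id: str
    seq: str  # read orientation: templated prefix + tail
    templated_len: int
    tail: str  # DNA alphabet
    chrom: str
    start: int  # templated-prefix interval, half-open
    end: int
    strand: str


def _count_occurrences(seqs: dict[str, str], pattern: str) -> int:
    total = 0
    rc = reverse_complement(pattern)
    for seq in seqs.values():
        for pat in {pattern, rc}:
            pos = seq.find(pat)
            while pos != -1:
                total += 1
                pos = seq.find(pat, pos + 1)
    return total


def make_tail_reads(
    seqs: dict[str, str],
    n_reads: int,
    seed: int = 0,
    prefix_len_range: tuple[int, int] = (18, 25),
    max_tail_len: int = 4,
) -> list[PlantedTailRead]:
    """Reads built as genome-unique templated prefixes plus non-extendable tails.

    Each read's prefix occurs exactly once in the genome (either strand) and
    its tail, if any, starts with a base the genome would not template, so
    an exact-prefix caller must recover exactly the planted decomposition.
    """
    rng = random.Random(seed)
    chroms = sorted(seqs)
    out: list[PlantedTailRead] = []
    attempts = 0
    while len(out) < n_reads:
        attempts += 1
        if attempts > 100 * n_reads:
            raise PlacementError("could not place genome-unique tail reads")
        chrom = rng.choice(chroms)
        seq = seqs[chrom]
        prefix_len = rng.randrange(prefix_len_range[0], prefix_len_range[1] + 1)
        if len(seq) < prefix_len + 2:
            continue
        pos = rng.randrange(1, len(seq) - prefix_len - 1)
        template = seq[pos : pos + prefix_len]
        if "N" in template or _count_occurrences(seqs, template) != 1:
            continue
        strand = rng.choice("+-")
        prefix = template if strand == "+" else reverse_complement(template)
        next_templated = (
            seq[pos + prefix_len] if strand == "+" else _COMPLEMENT[seq[pos - 1]]
        )
        tail_len = rng.randrange(0, max_tail_len + 1)
        tail = ""
        if tail_len:
            first = rng.choice([b for b in BASES if b != next_templated])
            tail = first + "".join(rng.choice(BASES) for _ in range(tail_len - 1))
        out.append(
            PlantedTailRead(
                read_id=f"tr{len(out) + 1}",
                seq=prefix + tail,
                templated_len=prefix_len,
                tail=tail,
                chrom=chrom,
                start=pos,
                end=pos + prefix_len,
                strand=strand,
            )
        )
    return out


def make_fixture(
    outdir: str | Path,
    n_chroms: int = 1,
    genome_length: int = 20_000,
    n_genes: int = 6,
    exons_per_gene: int = 1,
    clusters: list[ClusterSpec] | None = None,
    read_len: int = DEFAULT_READ_LEN,
    tail_spec: dict[str, float] | None = None,
    noise_rate: float = 0.1,
    seed: int = 0,
    r: int = 10,
    s: int = 10,
) -> dict[str, object]:
    """Generate a complete fixture tree (FASTA, GTF, BAM, FASTQ, manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fa"
    gtf = outdir / "annotation.gtf"
    seqs = make_genome(fasta, n_chroms=n_chroms, length=genome_length, seed=seed)
    genes = make_annotation(
        gtf,
        {chrom: len(seq) for chrom, seq in seqs.items()},
        n_genes=n_genes,
        exons_per_gene=exons_per_gene,
        seed=seed + 1,
    )
    if clusters is None:
        clusters = [
            ClusterSpec(gene_index=i % len(genes), n_reads=12) for i in range(3)
        ]
    manifest = make_reads(
        outdir / "reads",
        seqs,
        genes,
        clusters,
        read_len=read_len,
        tail_spec=tail_spec,
        noise_rate=noise_rate,
        seed=seed + 2,
        r=r,
        s=s,
    )
    return {
        "fasta": fasta,
        "gtf": gtf,
        "bam": outdir / "reads.bam",
        "fastq": outdir / "reads.fastq",
        "manifest": manifest,
        "manifest_path": outdir / "reads.manifest.json",
        "seqs": seqs,
        "genes": genes,
    }
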