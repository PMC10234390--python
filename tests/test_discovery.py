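import random

import pysam
import pytest

from smalldisco.annotation import Feature, build_candidate_regions
from smalldisco.discovery import (
    AlignedRead,
    AntisenseHit,
    SirnaRegion,
    filter_antisense,
    load_alignments,
    merge_into_sirna_regions,
    read_sirna_bed,
    reverse_complement,
    write_sirna_bed,
)
from smalldisco.intervals import GenomeInterval, Region


def _feat(chrom, start, end, strand, gene="g"):
    return Feature(
        interval=GenomeInterval(chrom, start, end, strand),
        feature_kind="exon",
        attributes={},
        gene_id=gene,
    )


def write_bam(path, records, ref_len=10_000):
    """records: (name, flag, pos, cigar, seq)"""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "chrI", "LN": ref_len}],
    }
    records = sorted(records, key=lambda r: (bool(r[1] & 0x4), r[2]))  # unmapped last
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for name, flag, pos, cigar, seq in records:
            aln = pysam.AlignedSegment(bam.header)
            aln.query_name = name
            aln.flag = flag
            aln.reference_id = 0 if not flag & 0x4 else -1
            aln.reference_start = pos if not flag & 0x4 else -1
            aln.mapping_quality = 60
            aln.cigarstring = cigar if not flag & 0x4 else None
            aln.query_sequence = seq
            bam.write(aln)
    pysam.index(str(path))
    return path


class TestLoadAlignments:
    def test_flag_filtering(self, tmp_path):
        seq = "A" * 22
        records = [(f"p{i}", 0, 100 + i * 50, "22M", seq) for i in range(5)]
        records += [(f"s{i}", 0x100, 400 + i * 10, "22M", seq) for i in range(2)]
        records += [("u1", 0x4, 0, None, seq)]
        bam = write_bam(tmp_path / "a.bam", records)
        reads = list(load_alignments(bam, min_len=0, max_len=10**9))
        assert len(reads) == 5
        assert all(r.is_primary for r in reads)
        # --keep-secondary admits the two secondaries
        assert len(list(load_alignments(bam, 0, 10**9, keep_secondary=True))) == 7

    def test_spliced_read_yields_two_blocks(self, tmp_path):
        bam = write_bam(tmp_path / "s.bam", [("j1", 16, 100, "11M100N11M", "C" * 22)])
        (read,) = load_alignments(bam)
        assert read.blocks == [(100, 111), (211, 222)]
        assert read.strand == "-"

    def test_length_filter(self, tmp_path):
        records = [(f"in{i}", 0, 100 + i, "22M", "A" * 22) for i in range(20)]
        records += [(f"out{i}", 0, 500 + i, "40M", "A" * 40) for i in range(5)]
        bam = write_bam(tmp_path / "l.bam", records)
        assert len(list(load_alignments(bam, min_len=18, max_len=30))) == 20

    def test_min_gt_max_rejected(self, tmp_path):
        bam = write_bam(tmp_path / "m.bam", [("x", 0, 10, "22M", "A" * 22)])
        with pytest.raises(ValueError, match="min_len"):
            list(load_alignments(bam, min_len=30, max_len=20))

    def test_seq_reported_in_read_orientation(self, tmp_path):
        stored = "ACGTACGTACGTACGTACGTAC"
        bam = write_bam(tmp_path / "o.bam", [("r1", 16, 100, "22M", stored)])
        (read,) = load_alignments(bam)
        assert read.seq == reverse_complement(stored)


def _read(read_id, chrom, strand, blocks):
    return AlignedRead(read_id=read_id, chrom=chrom, strand=strand, blocks=blocks, seq="")


class TestFilterAntisense:
    def test_antisense_emitted(self):
        regions = build_candidate_regions([_feat("chrI", 100, 200, "+", "g1")])
        hits = list(filter_antisense([_read("r", "chrI", "-", [(120, 142)])], regions))
        assert len(hits) == 1
        assert hits[0].region.gene_ids == {"g1"}

    def test_sense_dropped(self):
        regions = build_candidate_regions([_feat("chrI", 100, 200, "+")])
        assert list(filter_antisense([_read("r", "chrI", "+", [(120, 142)])], regions)) == []

    def test_no_overlap_dropped(self):
        regions = build_candidate_regions([_feat("chrI", 100, 200, "+")])
        assert list(filter_antisense([_read("r", "chrI", "-", [(200, 222)])], regions)) == []
        assert list(filter_antisense([_read("r", "chrII", "-", [(120, 142)])], regions)) == []

    def test_brute_force_oracle(self):
        rng = random.Random(99)
        feats = [
            _feat("chrI", s, s + ln, strand, f"g{i}")
            for i, (s, ln, strand) in enumerate(
                (rng.randrange(0, 900), rng.randrange(20, 150), rng.choice("+-"))
                for _ in range(12)
            )
        ]
        region_set = build_candidate_regions(feats)
        reads = [
            _read(f"r{i}", "chrI", rng.choice("+-"), [(start, start + 22)])
            for i, start in enumerate(rng.randrange(0, 978) for _ in range(100))
        ]
        got = {
            (h.read_id, h.block, h.region.interval.start, h.region.interval.end)
            for h in filter_antisense(reads, region_set)
        }
        expected = set()
        for read in reads:
            for block in read.blocks:
                for region in region_set:
                    iv = region.interval
                    if (
                        iv.strand != read.strand
                        and block[0] < iv.end
                        and iv.start < block[1]
                    ):
                        expected.add((read.read_id, block, iv.start, iv.end))
        assert got == expected


def _hit(read_id, block, chrom="chrI", strand="-", genes=("g1",)):
    return AntisenseHit(
        read_id=read_id,
        chrom=chrom,
        strand=strand,
        block=block,
        region=Region(
            interval=GenomeInterval(chrom, 0, 1000, "+"), gene_ids=frozenset(genes)
        ),
    )


class TestMergeIntoSirnaRegions:
    def test_default_gates_pass_at_exactly_r_and_s(self):
        hits = [_hit(f"r{i}", (100, 122)) for i in range(10)]
        regions = merge_into_sirna_regions(hits, r=10, s=10)
        assert len(regions) == 1
        region = regions[0]
        assert region.interval == GenomeInterval("chrI", 100, 122, "-")
        assert region.read_count == 10

    def test_below_r_empty(self):
        hits = [_hit(f"r{i}", (100, 122)) for i in range(9)]
        assert merge_into_sirna_regions(hits, r=10, s=10) == []

    def test_strict_greater_flag(self):
        hits = [_hit(f"r{i}", (100, 122)) for i in range(10)]
        assert merge_into_sirna_regions(hits, r=10, s=10, strict_greater_r=True) == []
        hits.append(_hit("r10", (100, 122)))
        assert len(merge_into_sirna_regions(hits, r=10, s=10, strict_greater_r=True)) == 1

    def test_transitive_chaining(self):
        blocks = [(0, 12), (10, 22), (20, 32)]
        hits = [
            _hit(f"r{b}{i}", block)
            for b, block in enumerate(blocks)
            for i in range(4)
        ]
        regions = merge_into_sirna_regions(hits, r=10, s=10)
        assert len(regions) == 1
        assert regions[0].interval == GenomeInterval("chrI", 0, 32, "-")
        assert regions[0].read_count == 12

    def test_span_gate(self):
        hits = [_hit(f"r{i}", (100, 109)) for i in range(20)]
        assert merge_into_sirna_regions(hits, r=10, s=10) == []
        assert len(merge_into_sirna_regions(hits, r=10, s=9)) == 1

    def test_bookended_blocks_not_chained(self):
        hits = [_hit(f"a{i}", (0, 20)) for i in range(10)]
        hits += [_hit(f"b{i}", (20, 40)) for i in range(10)]
        regions = merge_into_sirna_regions(hits, r=10, s=10)
        assert [(r.interval.start, r.interval.end) for r in regions] == [(0, 20), (20, 40)]

    def test_strand_and_chrom_grouping(self):
        hits = [_hit(f"r{i}", (100, 122), strand="-") for i in range(10)]
        hits += [_hit(f"q{i}", (100, 122), strand="+") for i in range(10)]
        regions = merge_into_sirna_regions(hits, r=10, s=10)
        assert {r.interval.strand for r in regions} == {"+", "-"}

    def test_invalid_r_s(self):
        with pytest.raises(ValueError):
            merge_into_sirna_regions([], r=0, s=10)

    def test_monotonicity_in_r_and_s(self):
        rng = random.Random(5)
        hits = [
            _hit(f"r{i}", (start, start + 22))
            for i, start in enumerate(rng.randrange(0, 500) for _ in range(120))
        ]

        def keys(r, s):
            return {
                (reg.interval.start, reg.interval.end)
                for reg in merge_into_sirna_regions(hits, r=r, s=s)
            }

        base = keys(3, 10)
        for delta in (1, 5, 50):
            assert keys(3 + delta, 10) <= base
            assert keys(3, 10 + delta) <= base

    def test_brute_force_transitive_closure_oracle(self):
        rng = random.Random(17)
        hits = [
            _hit(f"r{i}", (start, start + rng.randrange(15, 30)))
            for i, start in enumerate(rng.randrange(0, 400) for _ in range(60))
        ]
        regions = merge_into_sirna_regions(hits, r=1, s=1)
        # oracle: per-base coverage connectivity over the block multiset
        covered = sorted({p for h in hits for p in range(h.block[0], h.block[1])})
        runs = []
        for pos in covered:
            if runs and pos == runs[-1][1]:
                runs[-1] = (runs[-1][0], pos + 1)
            else:
                runs.append((pos, pos + 1))
        assert {(r.interval.start, r.interval.end) for r in regions} == set(runs)
        for start, end in runs:
            n = sum(1 for h in hits if h.block[0] < end and start < h.block[1])
            (match,) = [r for r in regions if r.interval.start == start]
            assert match.read_count == n


class TestBedIO:
    def test_serialization(self, tmp_path):
        region = SirnaRegion(
            interval=GenomeInterval("chrI", 100, 122, "-"),
            read_count=15,
            gene_ids=frozenset({"g1"}),
        )
        path = tmp_path / "out.bed"
        write_sirna_bed([region], path)
        assert path.read_text() == "chrI\t100\t122\tg1.sir1\t15\t-\n"

    def test_empty_regions_empty_file(self, tmp_path):
        path = tmp_path / "empty.bed"
        write_sirna_bed([], path)
        assert path.read_text() == ""

    def test_round_trip(self, tmp_path):
        rng = random.Random(3)
        regions = [
            SirnaRegion(
                interval=GenomeInterval("chrI", start, start + rng.randrange(10, 200), rng.choice("+-")),
                read_count=rng.randrange(1, 500),
                gene_ids=frozenset({f"g{i}", f"h{i}"}),
            )
            for i, start in enumerate(range(0, 5000, 250))
        ]
        path = tmp_path / "rt.bed"
        write_sirna_bed(regions, path)
        reparsed = read_sirna_bed(path)
        orig = sorted(regions, key=lambda r: (r.interval.chrom, r.interval.start))
        assert [(r.interval, r.read_count, r.gene_ids) for r in reparsed] == [
            (r.interval, r.read_count, r.gene_ids) for r in orig
        ]

    def test_sorted_output(self, tmp_path):
        regions = [
            SirnaRegion(GenomeInterval("chrI", 500, 600, "+"), 10, frozenset({"b"})),
            SirnaRegion(GenomeInterval("chrI", 100, 200, "-"), 12, frozenset({"a"})),
        ]
        path = tmp_path / "sorted.bed"
        write_sirna_bed(regions, path)
        starts = [int(line.split("\t")[1]) for line in path.read_text().splitlines()]
        assert starts == sorted(starts)


class TestEndToEnd:
    def test_planted_recovery(self, basic_fixture):
        from smalldisco.annotation import parse_annotation

        manifest = basic_fixture["manifest"]
        feats = parse_annotation(basic_fixture["gtf"], "exon")
        region_set = build_candidate_regions(feats)
        reads = list(load_alignments(basic_fixture["bam"]))
        hits = filter_antisense(reads, region_set)
        regions = merge_into_sirna_regions(hits, r=10, s=10)
        got = {
            (r.interval.chrom, r.interval.start, r.interval.end, r.interval.strand, r.read_count)
            for r in regions
        }
        expected = {
            (p.chrom, p.start, p.end, p.strand, p.read_count)
            for p in manifest.passing_regions()
        }
        assert got == expected

    def test_junction_two_regions(self, junction_fixture):
        from smalldisco.annotation import parse_annotation

        feats = parse_annotation(junction_fixture["gtf"], "exon")
        region_set = build_candidate_regions(feats)
        reads = list(load_alignments(junction_fixture["bam"]))
        hits = filter_antisense(reads, region_set)
        regions = merge_into_sirna_regions(hits, r=10, s=10)
        assert len(regions) == 2
        manifest = junction_fixture["manifest"]
        got = {
            (r.interval.start, r.interval.end, r.read_count) for r in regions
        }
        expected = {(p.start, p.end, p.read_count) for p in manifest.passing_regions()}
        assert got == expected
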