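"""GTF/GFF parsing and strand-resolved candidate-region construction.

Candidate regions are the search space for antisense reads: per strand,
overlapping features of the requested kind are merged; afterwards every base
covered on both strands is excised from both strands' regions. Excision may
split a region in two, and each surviving fragment keeps the gene-id set of
its parent cluster.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from smalldisco.intervals import (
    GenomeInterval,
    Region,
    merge_intervals,
    subtract_intervals,
)

logger = logging.getLogger(__name__)

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


class AnnotationParseError(ValueError):
    """Raised for a malformed annotation line; message names the line number."""


class AnnotationFormatError(ValueError):
    """Raised when the dialect cannot be inferred from the file extension."""


@dataclass
class Feature:
    """One annotation record of the requested feature kind."""

    interval: GenomeInterval
    feature_kind: str
    attributes: dict[str, str]
    gene_id: str


@dataclass
class CandidateRegionSet:
    """Disjoint (within and across strands) candidate regions."""

    regions: list[Region] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def by_chrom_strand(self) -> dict[tuple[str, str], list[Region]]:
        """Regions grouped by (chrom, strand), sorted by start."""
        grouped: dict[tuple[str, str], list[Region]] = {}
        for region in self.regions:
            key = (region.interval.chrom, region.interval.strand)
            grouped.setdefault(key, []).append(region)
        for regs in grouped.values():
            regs.sort(key=lambda r: r.interval.start)
        return grouped


def _detect_dialect(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".gtf":
        return "gtf"
    if suffix in (".gff", ".gff3"):
        return "gff"
    raise AnnotationFormatError(
        f"cannot infer annotation dialect from extension {suffix!r} of {path}; "
        "pass dialect='gtf' or dialect='gff' explicitly"
    )


def parse_attributes(raw: str, dialect: str) -> dict[str, str]:
    """Parse the ninth column in either GTF (key "value";) or GFF3 (key=value) style."""
    attrs: dict[str, str] = {}
    if dialect == "gtf":
        for key, value in _GTF_ATTR.findall(raw):
            attrs.setdefault(key, value)
    else:
        for part in raw.strip().split(";"):
            part = part.strip()
            if not part or "=" not in part:
                continue
            key, _, value = part.partition("=")
            attrs.setdefault(key.strip(), value.strip())
    return attrs


def extract_gene_id(attrs: dict[str, str], dialect: str, gene_key: str | None = None) -> str:
    """Gene identifier from attributes: ``gene_id`` (GTF) or Parent/ID chain (GFF)."""
    if gene_key is not None:
        return attrs.get(gene_key, "")
    if dialect == "gtf":
        return attrs.get("gene_id", "")
    for key in ("Parent", "ID", "gene_id"):
        if key in attrs:
            return attrs[key]
    return ""


def parse_annotation(
    path: str | Path,
    feature_kind: str,
    *,
    dialect: str | None = None,
    gene_key: str | None = None,
) -> list[Feature]:
    """Parse an annotation file and return the records of one feature kind.

    Coordinates are converted from the annotation's 1-based inclusive
    convention to the internal 0-based half-open convention. Unstranded
    ('.') records are excluded and counted in a warning. Records without an
    extractable gene id are kept and flagged with gene_id ``"."``.

    Raises
    ------
    AnnotationParseError
        If a non-comment line does not have nine tab-separated columns.
    AnnotationFormatError
        If ``dialect`` is None and the extension is not .gtf/.gff/.gff3.
    """
    if dialect is None:
        dialect = _detect_dialect(path)
    if dialect not in ("gtf", "gff"):
        raise AnnotationFormatError(f"unknown dialect {dialect!r}; use 'gtf' or 'gff'")

    features: list[Feature] = []
    n_unstranded = 0
    n_missing_gene = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            if cols[2] != feature_kind:
                continue
            strand = cols[6]
            if strand not in ("+", "-"):
                n_unstranded += 1
                continue
            try:
                start_1b, end_1b = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer coordinates {cols[3]!r}/{cols[4]!r}"
                ) from exc
            attrs = parse_attributes(cols[8], dialect)
            gene_id = extract_gene_id(attrs, dialect, gene_key)
            if not gene_id:
                n_missing_gene += 1
                gene_id = "."
            features.append(
                Feature(
                    interval=GenomeInterval(cols[0], start_1b - 1, end_1b, strand),
                    feature_kind=feature_kind,
                    attributes=attrs,
                    gene_id=gene_id,
                )
            )
    if n_unstranded:
        logger.warning(
            "excluded %d unstranded ('.') %s record(s)", n_unstranded, feature_kind
        )
    if n_missing_gene:
        logger.warning(
            "%d %s record(s) had no extractable gene id", n_missing_gene, feature_kind
        )
    return features


def feature_to_gtf_line(feature: Feature, source: str = "smalldisco") -> str:
    """Serialize a Feature back to a GTF line (coordinates 1-based inclusive)."""
    iv = feature.interval
    attrs = "".join(f'{k} "{v}"; ' for k, v in feature.attributes.items()).strip()
    if not attrs:
        attrs = f'gene_id "{feature.gene_id}";'
    return "\t".join(
        [
            iv.chrom,
            source,
            feature.feature_kind,
            str(iv.start + 1),
            str(iv.end),
            ".",
            iv.strand,
            ".",
            attrs,
        ]
    )


def build_candidate_regions(features: list[Feature]) -> CandidateRegionSet:
    """Merge same-strand features, then excise bases covered on both strands.

    Merging is transitive and requires at least one shared base (bookended
    features stay separate). Gene-id sets propagate from each merged cluster
    to every fragment that survives cross-strand excision.
    """
    # Same-strand transitive merge, tracking gene ids per cluster.
    clusters: dict[tuple[str, str], list[tuple[int, int, set[str]]]] = {}
    by_key: dict[tuple[str, str], list[Feature]] = {}
    for feat in features:
        by_key.setdefault((feat.interval.chrom, feat.interval.strand), []).append(feat)
    for key, feats in by_key.items():
        feats.sort(key=lambda f: (f.interval.start, f.interval.end))
        merged: list[tuple[int, int, set[str]]] = []
        for feat in feats:
            iv = feat.interval
            if merged and iv.start < merged[-1][1]:
                start, end, genes = merged[-1]
                merged[-1] = (start, max(end, iv.end), genes | {feat.gene_id})
            else:
                merged.append((iv.start, iv.end, {feat.gene_id}))
        clusters[key] = merged

    # Per chrom: bases covered on both strands are removed from both.
    chroms = {chrom for chrom, _ in clusters}
    regions: list[Region] = []
    for chrom in sorted(chroms):
        plus = clusters.get((chrom, "+"), [])
        minus = clusters.get((chrom, "-"), [])
        plus_cov = merge_intervals([(s, e) for s, e, _ in plus])
        minus_cov = merge_intervals([(s, e) for s, e, _ in minus])
        overlap = _intersect(plus_cov, minus_cov)
        for strand, strand_clusters in (("+", plus), ("-", minus)):
            for start, end, genes in strand_clusters:
                for frag_start, frag_end in subtract_intervals([(start, end)], overlap):
                    regions.append(
                        Region(
                            interval=GenomeInterval(chrom, frag_start, frag_end, strand),
                            gene_ids=frozenset(genes),
                        )
                    )
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.strand))
    return CandidateRegionSet(regions=regions)


def _intersect(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two sorted disjoint half-open interval lists."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        start = max(a[i][0], b[j][0])
        end = min(a[i][1], b[j][1])
        if start < end:
            out.append((start, end))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def write_regions_bed(region_set: CandidateRegionSet, path: str | Path) -> None:
    """Dump candidate regions as 6-column BED (debug hand-off)."""
    with open(path, "w") as handle:
        for region in sorted(
            region_set.regions,
            key=lambda r: (r.interval.chrom, r.interval.start, r.interval.strand),
        ):
            iv = region.interval
            name = ";".join(sorted(region.gene_ids)) or "."
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
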