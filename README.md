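# smalldisco

A command-line tool and Python library for **s**mall interfering RNA
**disco**very and 3' nontemplated tail quantification from small RNA-seq
data.

siRNAs are identified by pattern, not biogenesis: reads that map *antisense*
to an annotated genomic feature (exons, 3' UTRs, ...) are clustered into
putative siRNA regions. Two analysis modes:

* **sirna** — build strand-resolved candidate regions from a GTF/GFF
  (same-strand features merged, cross-strand overlaps excised), keep reads
  mapping antisense to them, and merge overlapping reads into regions gated
  by a minimum read support `r` and minimum span `s` (defaults: 10 and 10).
  Output: BED6 of putative siRNA regions (score = supporting reads, strand =
  read strand).
* **tail** — re-derive each read's templated genomic prefix (exact match,
  zero mismatches, either strand), call the 3' nontemplated suffix, assign
  reads to sRNA regions (the sirna-mode BED or any user list), and emit a
  CSV of per-target tail counts. Each target gets `untailed` and
  `all_tails` rows; their sum equals the total reads assigned to it.

A `quantify` subcommand counts reads per siRNA gene/region, normalizes to
CPM (siRNA-only or exon-background denominators), and applies an inclusive
CPM threshold (default ≥ 25).

## Usage

```sh
# discover siRNA regions from one or more coordinate-sorted, indexed BAMs
smalldisco sirna -b sample_dir/ -g genes.gtf -f exon -r 10 -s 10 -o sirna.bed

# quantify 3' tails over the discovered regions
smalldisco tail -b reads.bam -G genome.fa -B sirna.bed -o tails.csv

# per-gene counts, CPM normalization, abundance filter
smalldisco quantify -i sirna.bed -o counts.tsv --cpm-threshold 25
```

Useful flags: `--len-min/--len-max` (read-length window, default 17–35 nt),
`--strict-greater-r`, `--keep-secondary`, `--dialect {gtf,gff}`,
`--min-prefix` (templated-prefix minimum, default 18 nt),
`--multimap {fractional,random,drop}`, `--seed`, `--antisense-assign`
(for region BEDs annotated on the genomic sense strand), and `--config`
(TOML defaults file; CLI flags win). Every run writes a JSON run report
(`<output>.report.json`) with the resolved config and stage counts.

Synthetic test data (toy genome, annotation, reads with planted antisense
clusters and known tails, plus a ground-truth manifest):

```sh
smalldisco-fixtures -o fixture_dir --seed 1 --n-clusters 5
```

## Tests and acceptance

```sh
python -m pytest -q tests/            # unit + property + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script regenerates fixtures from scratch, runs both modes
plus quantification, and verifies planted-region recovery, tail round-trip,
the untailed/all_tails conservation contract, and CPM arithmetic; it exits
non-zero if anything fails.

## Layout

| module | role |
| --- | --- |
| `smalldisco.intervals` | stranded half-open intervals, union/subtraction algebra |
| `smalldisco.annotation` | GTF/GFF parsing, candidate-region construction |
| `smalldisco.discovery` | BAM loading, antisense filtering, r/s cluster merging, BED I/O |
| `smalldisco.tailing` | exact templated-prefix search, tail calling, tail tables, CSV I/O |
| `smalldisco.quantify` | per-gene/region counting, CPM normalization, filtering |
| `smalldisco.fixtures` | deterministic synthetic genomes/annotations/reads + truth manifests |
| `smalldisco.cli` | `sirna` / `tail` / `quantify` / `fixtures` subcommands |
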