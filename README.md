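# looptopo

Topology classification of regulatory chromatin interactions relative to
structural (CTCF) loops, with the surrounding integrative machinery —
interaction QC, anchor annotation, differential strength analysis,
accessibility and expression integration — exercised end to end on fully
synthetic studies with planted, machine-readable ground truth.

Each regulatory (H3K27ac) interaction is related to every structural loop
through one of five geometric relations — **contain** (subtypes I/II/III by
shared-anchor count), **cross**, **neighbor**, **inside**, **outside** —
and aggregated into a per-interaction category including the composite
**contain & cross**. Every geometric knob (slack, span mode, strictness)
is an explicit, recorded parameter.

## Layout

| module | what it does |
| --- | --- |
| `looptopo.core` | intervals, paired-anchor loops, genomes, union coverage, interval index |
| `looptopo.io` | BEDPE / BED / TSV / JSON readers & writers with provenance headers |
| `looptopo.simulate` | synthetic study generator: convergent-CTCF loop slots, planted topology classes, condition effects, ATAC and expression counts, ground truth |
| `looptopo.qc` | short-range / low-count filters, identical-element loop merging |
| `looptopo.annotation` | anchor typing (C/E/P composites), interaction classes (PP/EE/EP), promoter windows, looping fraction, nearest-neighbor spacing |
| `looptopo.topology` | the pairwise relation, aggregation, category distribution, solo-anchor report |
| `looptopo.differential` | CPM + exact binomial caller, BH-FDR, Mann–Whitney U (exact + asymptotic), strength stratification, per-class response |
| `looptopo.atac` | differential accessibility, CTCF-overlap partition, site-centered windows, motif→TSS signed distances |
| `looptopo.expression` | DEG calling, set intersections, promoter-CTCF flags, wt/mut rescue typing, mechanism partition, percentage reporting |
| `looptopo.pipeline` / `looptopo.cli` | validated-config orchestration and the `looptopo` command |

## CLI

```sh
looptopo run --config configs/demo.yaml --outdir out/   # full pipeline
looptopo simulate --seed 7 --outdir sim/                # synthetic study only
looptopo qc --loops sim/h3k27ac_interactions.bedpe \
    --min-distance 10000 --min-count 4 --out qc.bedpe
looptopo classify --h3k27ac qc.bedpe --ctcf-loops sim/ctcf_loops.bedpe \
    --out topology.tsv --distribution dist.tsv
looptopo diff --loops qc.bedpe --pre untreated --post IAA \
    --alpha 0.05 --min-lfc 1 --out diff.tsv
```

`looptopo run` writes every stage output (qc.bedpe, topology.tsv,
category_distribution.tsv, diff.tsv, class_response.tsv, atac_diff.tsv,
deg.tsv, mechanism_partition.tsv, …) plus `summary.json`; re-running with
the same config and seed reproduces every file byte for byte.

## Notes

- Coordinates are 0-based half-open everywhere (BED convention).
- Trans (inter-chromosomal) loops are rejected, not dropped.
- All simulator output is a deterministic function of one integer seed.
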