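# episcreen

A tested pipeline for finding genes preferentially expressed in two
dissimilar cell populations and characterizing their differential DNA
methylation. It has three analysis stages plus a simulator:

- **Expression screen** (`episcreen.screen`) — filters a gene universe
  (protein-coding, non-mitochondrial, expression floor in at least one
  tissue and one culture), then calls preferential expression by inclusive
  ratio thresholds: a target culture against the mean of the five other
  cultures, and cerebellum against the median of 10 other brain regions and
  the mean of 41 non-brain tissues, with a rescue rule for zero
  denominators (cerebellum must be the strict tissue-wide maximum). Also
  builds the per-culture x cerebellum overlap matrix.
- **DMR/LMR caller** (`episcreen.dmr`) — aggregates replicated target
  methylomes against a reference panel into a per-CpG delta series
  (intersection of CpGs, optional coverage floor), segments maximal
  sign-consistent runs of candidate CpGs (|delta| >= 0.35 standard,
  0.20 relaxed; >= 3 CpGs; gaps <= 250 bp), and calls low-methylated
  regions against the genome-wide mean of a single track.
- **Integration** (`episcreen.integrate`) — assigns DMRs to nearest genes
  by TSS distance, classifies them into strand-aware TSS-relative location
  classes (promoter upstream/downstream within a configurable window,
  intragenic, near-intergenic within 25 kb), and produces per-gene
  epigenetic summaries.
- **Simulator** (`episcreen.synthetic`) — expression matrices with planted
  gene classes (log-normal noise), methylomes with planted hypo/hyper DMRs
  and LMRs (Beta noise), and non-overlapping gene annotations, all with a
  ground-truth manifest for recovery testing.
- **Reporting** (`episcreen.report`) — headline counts and round-half-up
  percentages, written as TSV and markdown.

All genomic coordinates are 0-based half-open; GTF input is converted at
the reader. Formats: TSV expression matrices, 4-5 column bedGraph
methylomes, BED12/GTF annotation, BED6+ DMR/LMR output.

## CLI

```sh
episcreen simulate --out-dir sim --n-genes 200 --seed 1
episcreen screen --tissue sim/tissue_tpm.tsv --tissue-groups sim/tissue_groups.tsv \
    --culture sim/culture_fpkm.tsv --culture-groups sim/culture_groups.tsv \
    --annotation sim/annotation.gtf --out-dir screen_out
episcreen dmr --target sim/target_rep1.bedgraph --target sim/target_rep2.bedgraph \
    --target sim/target_rep3.bedgraph \
    --panel sim/panel_01.bedgraph --panel sim/panel_02.bedgraph \
    --panel sim/panel_03.bedgraph --panel sim/panel_04.bedgraph \
    --panel sim/panel_05.bedgraph --panel sim/panel_06.bedgraph \
    --lmr-track sim/target_rep1.bedgraph --out-dir dmr_out
episcreen annotate --dmrs dmr_out/dmrs.bed --annotation sim/annotation.gtf \
    --out-dir annotate_out
episcreen report --summaries annotate_out/gene_summaries.tsv --out-dir report_out
```

Every threshold (`--ratio-threshold`, `--delta`/`--relaxed`, `--min-cpgs`,
`--max-gap`, `--window`, central tendencies, ...) can also come from a YAML
config file (`--config`); CLI flags override it.

## Notes

- The brain-regions denominator uses the median by default
  (`brain_central_tendency`); set it to `mean` to reproduce the
  alternative reading.
- The LMR caller is a deterministic threshold proxy (member CpGs <= 0.5,
  run mean at least 0.3 below the genome-wide mean, >= 5 CpGs), not a
  statistical segmentation.
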