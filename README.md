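# oncomark

Comparative chromatin-mark analysis toolkit: bin-level ChIP-seq
quantitation and normalization, percentile-based enrichment-region calling,
factor-occupancy stratification, fold-change classification against a
knockout reference cohort, RPKM expression comparison over gene sets,
allele-informative RNA-seq read classification, and MALDI
methylation-state quantitation — together with seeded synthetic-data
generators so the whole pipeline runs and is verified at desk scale
without any external download.

## Package layout

| module | contents |
|---|---|
| `oncomark.coverage` | genome binning, 5'-start read counting with PCR-duplicate removal, per-million scaling, distribution matching |
| `oncomark.region_calling` | percentile selection over genic bins, gap-merging with length/extreme filters, factor enriched/depleted/neither classification, overlap counts, scaled-region profile matrices, quantile summaries |
| `oncomark.differential` | cross-cohort harmonization, gained/unchanged/other fold-change labels, mirror ("genocopy") log2-ratio comparison |
| `oncomark.transcriptome` | strand-specific RPKM over union exons, gene-set log2 ratios vs seeded random controls, three-allele codon-spanning read classification |
| `oncomark.methylspec` | me0..me3 mass ladders (14.01565 Da per methyl), peak matching and abundance profiles from spectra |
| `oncomark.synthetic_data` | seeded generators with planted truth for all of the above |
| `oncomark.pipeline` / `oncomark.cli` | end-to-end orchestration and the `oncomark` command |

## CLI

```bash
# generate a synthetic two-condition ChIP dataset with planted truth
oncomark simulate chipseq --seed 1 --out sim/

# quantitate, normalize, call regions, stratify, profile
oncomark bin --reads sim/wt.reads.bed --chrom-sizes sim/chrom.sizes --bin-width 200 --dedup --out wt.bedgraph
oncomark normalize --method match --reads sim/wt.reads.bed --reads-b sim/mutant.reads.bed \
    --chrom-sizes sim/chrom.sizes --out wt.m.bedgraph --out-b mut.m.bedgraph
oncomark call-regions --reads-wt sim/wt.reads.bed --reads-mut sim/mutant.reads.bed \
    --chrom-sizes sim/chrom.sizes --genes sim/genes.bed --out-prefix regions
oncomark classify --regions regions.tsv --factor-reads sim/factor.reads.bed \
    --chrom-sizes sim/chrom.sizes --out classes.tsv
oncomark profile --regions regions.tsv --reads sim/mutant.reads.bed \
    --chrom-sizes sim/chrom.sizes --blacklist sim/blacklist.bed --out profile.tsv

# knockout-cohort comparison on a region score table
oncomark diffmark --mark H3K9me3 --table cohort.tsv --out labelled.tsv

# expression and alleles
oncomark simulate rnaseq --seed 1 --out rna/
oncomark rpkm --reads WT=rna/WT.reads.bed --reads G34R=rna/G34R.reads.bed \
    --genes rna/genes.bed12 --out rpkm.tsv
oncomark geneset --rpkm rpkm.tsv --gene-list set.txt --wt-sample WT --mut-sample G34R \
    --seed 1 --out-prefix geneset
oncomark alleles --reads rna/G34R.allele_reads.fasta --library rna/alleles.fasta \
    --codon-offset 99 --out calls.json

# methylation-state readout
oncomark simulate spectrum --seed 1 --out spec/
oncomark methylspec --spectrum spec/spectrum.csv --base-mz 2000 --tolerance-ppm 200 --out profile.tsv

# everything at once, with a machine-readable run report
oncomark run --seed 1 --out pipeline_out/
```

All analysis thresholds (bin width 200, selection percentile 95, merge
distance 100 bp, max region length 500 bp, extreme top fraction 0.01%,
factor percentiles 90/75/25, gain threshold 1.5, unchanged interval
[0.8, 1]) are exposed as flags and YAML config keys with those defaults.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(oracle equivalence against brute-force references, normalization
contracts, planted-region recovery, genocopy and fold-change recovery,
allele-classification accuracy, RPKM closed forms, methyl-ladder
recovery, determinism).

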