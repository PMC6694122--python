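# scsomatic

Detection and analysis of **expressed somatic mutations in droplet
single-cell RNA-seq**.

Droplet platforms (10x Chromium 3'/5') tag every read with a cell barcode
(`CB`) and a unique molecular identifier (`UB`). Although these libraries
are end-biased, residual coverage extends many kilobases into transcript
bodies — enough to observe somatic variants, discovered by DNA sequencing
of the same sample, directly in the expression data of thousands of single
cells. `scsomatic` implements that workflow end to end:

* **Allele pileup** (`scsomatic.pileup`) — barcode/UMI-aware allele counting
  at known variant sites. Reads must carry both `CB` and `UB` tags and have
  base and mapping quality ≥ 1; mates are deduplicated by query name; reads
  sharing a `(CB, UB)` pair are PCR copies of one molecule and are collapsed
  to a consensus call: if duplicate reads disagree at the site, the modal
  base is accepted only when it reaches **≥ 75%** of the reads, otherwise the
  whole molecule is discarded. Small indels are recognized from cigar
  `I`/`D` operations of the expected length within a ±10 bp window of the
  site (indels in repetitive regions are frequently misaligned by a few
  bases).
* **Genotyping and sensitivity metrics** (`scsomatic.genotyping`) — under
  allelic dropout a heterozygous site gives the mutant allele in only half
  of the sampled molecules, so a cell with only reference molecules is
  *unknown*, never wild-type. A cell is `mutant` (≥ 1 consensus mutant
  molecule), `ref_only`, or `no_coverage`. Per variant:
  `scVAF` = alt molecules / all molecules; `MCF` = M/T (mutant cells over
  covered cells); `MCDR` = M / (2 · VAF_DNA · T), the fraction of expected
  mutant cells actually observed. Multi-mutation tallies, clone-tree
  consistency of per-cell mutation sets, and control-sample false-positive
  rates round out the module.
* **Detection model** (`scsomatic.detection`) — the expected number of
  detected mutant cells when sequencing *n* cells:

  `E = n·a·( f·[1 − (1 − c·t)^r] + (1 − f)·e ) ≈ n·a·f·r·c·t + n·a·(1 − f)·e`

  with *a* the tumor fraction, *f* twice the bulk-DNA VAF, *t* the gene's
  expression as a fraction (CPM/10⁶), *r* UMIs per cell, *c* the fraction of
  the gene's molecules covering the site, and *e* the site-specific error
  rate. Exact and first-order forms, `P(≥ 1 mutant cell)`, the design
  inverse (cells required to expect a target yield) and a Monte-Carlo
  validator are provided.
* **Coverage profiling** (`scsomatic.coverage`) — fraction of a transcript's
  unique `(CB, UB)` pairs covering each spliced-transcript position,
  averaged by distance from the TSS (5' kits) or TTS (3' kits) over
  single-isoform genes of 250–11,000 bp, truncated at 10 kb.
* **Integration statistics** (`scsomatic.stats`) — QC + depth normalization
  (scale 10,000, log1p), Spearman nearest-neighbor lineage inference against
  reference profiles, one-sided Fisher exact tests for mutant-cell
  enrichment/depletion per expression cluster, the mutant-density regression
  `E_i = x_i + y_i·m + z_i·g` (per-gene cluster-mean expression on mutant
  fraction *m*, controlling for the mutated gene's expression *g*; partial
  F-test + Benjamini-Hochberg, selecting q ≤ 0.05 with y > 0), Wilcoxon
  signatures of mutant-rich (> 10%) vs mutant-poor clusters, Pearson
  correlation screens, and hypergeometric gene-set overlap.
* **Simulator** (`scsomatic.simulate`) — tagged reads, VCF, barcode lists
  and cluster-structured expression matrices with known ground truth: clone
  trees, heterozygous allele sampling, Poisson UMI counts, site coverage,
  PCR duplicates, per-read errors, and planted expression signatures. Every
  module is testable end to end without external data.

## Worked example

Simulate an AML-like sample (18k cells, 50% tumor, founding clone with a
`DNMT3A` SNV and an `NPM1` 4 bp insertion, a nested subclone carrying a
`GATA2` SNV), then genotype it:

```bash
scsomatic simulate --seed 7 --out-dir sim
scsomatic genotype --bam sim/alignments.sam --vcf sim/variants.vcf \
    --barcodes sim/barcodes.txt --out calls.tsv
# wrote 3399 UMI calls at 3 sites to calls.tsv
scsomatic metrics --calls calls.tsv --barcodes sim/barcodes.txt \
    --vcf sim/variants.vcf --out-prefix demo
# 742 mutant (cell, site) pairs across 3 sites
```

`demo.variant_metrics.tsv`:

```
site              M    T     scvaf   mcf     mcdr    total_alt_umis  total_umis
DNMT3A:1501:A:C   63   277   0.227   0.227   0.457   63              278
NPM1:701:A:ACGAG  648  2479  0.250   0.261   0.525   671             2688
GATA2:1201:T:A    31   426   0.072   0.073   0.486   31              432
```

Reading the founding-clone rows: half the cells are tumor, so the true DNA
VAF is 0.25 and scVAF ≈ 0.25 as expected. The MCF says ~26% of covered
cells show the `NPM1` mutation; MCDR ≈ 0.5 because most covered cells
sample a single molecule, which under heterozygous dropout carries the
mutant allele only half the time. The subclonal `GATA2` row is lower in
proportion to its carrier fraction.

The detection model answers design questions — e.g. the expected yield of
mutant cells for a gene at 100 CPM, a clonal heterozygous variant
(VAF 0.25) in a 50%-tumor sample, with 2,000 UMIs/cell and 2.5% of the
gene's molecules covering the site:

```bash
scsomatic power --n 10000 --tumor-frac 0.5 --vaf 0.25 --cpm 100 \
    --umis-per-cell 2000 --site-coverage-frac 0.025 --invert --target-cells 1
```

```json
{
  "expected_mutant_cells": 12.468817565390067,
  "approx_mutant_cells": 12.5,
  "prob_at_least_one": 0.9999961851057145,
  "cells_required": 803
}
```

So ~12.5 mutant cells are expected from 10,000 sequenced cells, and 803
cells suffice to expect at least one.

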