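# snpdesert

Detection and characterization of **common-variant-free regions** of a
genome — the "holes" in the common-SNP map that genome-wide association
studies silently skip.

Genotyping arrays and GWAS designs tag the genome through common SNPs
(minor allele frequency, MAF ≥ 1%). Wherever a long stretch of sequence
contains *no* common SNP, association studies are blind, even though such
stretches can carry genes (on the human Y chromosome, many of them
fertility-related). `snpdesert` implements the full screening pipeline for
such regions:

1. **CSFR calling** (common SNP-free regions). From a sorted common-SNP
   table, compute the gaps between adjacent SNPs, subtract assembly gaps
   (centromeres, telomeres, clone gaps), and keep every residual interval
   with length ≥ *L* (default *L* = 100 kb, the scale of strong linkage
   disequilibrium blocks). All coordinates are 0-based half-open, so
   length ≡ end − start.
2. **CVFR calling** (common variant-free regions). Subtract copy-number
   variant (CNV) intervals from the CSFRs and re-apply the length filter.
3. **Residual filtering.** Subtract variants from personal-genome
   sequencing tracks and newly catalogued SNPs; report per-source hit
   counts and the regions left untouched.
4. **Gene annotation.** Map refGene models onto regions using the longest
   splicing form per gene symbol and a ≥ 1 bp overlap criterion; count
   distinct genes.
5. **Isochore classification.** Compare each region's GC content with its
   two 100 kb flanks: a region ≥ 2 percentage points above or below *both*
   flanks is an *isochore*; a region whose flanks differ by more than 2
   points and by more than both region-to-flank contrasts is an *isochore
   border*; anything else is *unknown*.
6. **Verification reports.** Genotyping-array probe coverage (which probes
   fall inside regions, and whether any population shows a nonzero MAF)
   and segmental-duplication overlap.

Inputs are UCSC Table Browser-style tab-separated dumps (common-SNP table,
gap table, refGene, DGV CNV table, personal-genome variant tracks,
segmental-duplication pairs; gzip sniffed automatically), genome sequence
as FASTA, and BED for region I/O. A synthetic-data generator
(`snpdesert.simulate`) produces complete format-faithful bundles with
known planted deserts, so the whole pipeline is testable without any
multi-hundred-MB downloads.

## Worked example

The package ships the published hg19 catalog of 50 common-SNP-free
regions and 20 common-variant-free regions as small TSV fixtures, plus
builders that reconstruct pipeline inputs from them
(`snpdesert.catalog`). Running

```sh
python examples/02_catalog_reproduction.py
```

prints:

```
common SNP-free regions: 50 across 8 chromosomes
  on chrY: 33   largest: 3,540,431 bp
common variant-free regions after CNV subtraction: 19
  on chrY: 17, on chrX: 2
distinct genes overlapping SNP-free regions: 97
```

That is: the SNP-gap stage recovers all 50 catalogued regions with exact
coordinates, 33 of them on the Y chromosome, the largest spanning 3.54 Mb;
CNV subtraction leaves variant-free regions only on the sex chromosomes;
and 97 distinct genes overlap the SNP-free set. (The published
variant-free table lists 20 rows, but two of them are not nested inside
any published SNP-free region, so strict CNV subtraction can reproduce at
most 19 — see `docs/methods.md` for the analysis.)

Other examples: `01_simulate_and_call.py` (planted-desert simulation and
recovery), `03_isochore_classification.py` (GC-block classification),
`04_variant_filtering_reports.py` (the final 105 kb residual and its
segdup overlap).

## Library and command line

The primary interface is the Python API (`snpdesert.call_csfrs`,
`call_cvfrs`, `subtract_point_variants`, `annotate_regions`,
`classify_all`, `run_pipeline`, ...). A thin CLI mirrors the stages for
shell use:

```sh
snpdesert simulate --seed 4 --outdir bundle --desert chrS1:800000-840000
snpdesert call-csfr --snps bundle/snp_common.txt --gaps bundle/gap.txt \
    --min-len 10000 > csfr.bed
snpdesert run-all --snps ... --cnvs ... --refgene ... --outdir out/
```

Subcommands: `call-csfr`, `call-cvfr`, `filter-variants`,
`annotate-genes`, `isochore`, `probe-check`, `segdup-check`, `simulate`,
`run-all`. BED goes to standard output; diagnostics to standard error.

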