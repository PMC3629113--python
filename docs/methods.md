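# Methods

## Model and procedure

The pipeline treats the genome as a set of named chromosomes with 0-based
half-open intervals (the UCSC `chromStart`/`chromEnd` convention; length =
end − start). A *common SNP* is a catalogued variant with minor allele
frequency ≥ 1%. The object of interest is the set of maximal intervals of
length ≥ *L* that contain no common SNP and survive successive subtraction
of confounders:

```
gaps between adjacent common SNPs
  − assembly gaps          → filter ≥ L  → CSFR  (common SNP-free regions)
  − CNV intervals          → filter ≥ L  → CVFR  (common variant-free regions)
  − personal-genome / newly catalogued variants
                           → filter ≥ L  → residual
```

Each stage re-applies the length threshold, so the stages are nested:
every CVFR is a sub-interval of a CSFR, every residual of a CVFR. The
inter-SNP gap between two adjacent SNP records is `(prev.end, next.start)`
after sweeping the merged SNP spans of a chromosome in coordinate order;
the segments before the first and after the last SNP of a chromosome are
never candidates (chromosome ends are dominated by assembly gaps, and the
"distance between adjacent SNPs" definition does not cover them).

Two representational choices matter:

* **Half-open exactness.** Interval merge fuses abutting intervals
  (`a.end == b.start`), so subtraction chains never produce zero-length
  artifacts, and every reported size equals end − start exactly.
* **Zero-length SNP records.** dbSNP insertion records have
  `chromStart == chromEnd`. They occupy no base but still split an
  inter-SNP gap at their coordinate. Supporting them is not cosmetic: the
  hg19 catalog contains two *abutting* SNP-free regions
  (chrY 24500602–24620459 and 24620459–28160890) which can only be
  produced by a zero-length record at the shared boundary — a 1 bp SNP
  there would either overlap one region or merge the pair. CSFR calling
  therefore subtracts assembly gaps per candidate gap rather than over the
  merged candidate set, so abutting candidates stay distinct.

**Gene annotation.** A gene symbol's span is its longest splicing form per
(symbol, chromosome); ties break to the smaller start, then the
lexicographically smaller transcript id. A gene is assigned to a region
when the spans share ≥ 1 bp (half-open intersection). Symbols are
whitespace-normalized ("LIMS3 L" → "LIMS3L") because published tables
carry whitespace artifacts that would otherwise split one gene into two.
Gene identity is the normalized refGene `name2` string only; no external
alias resolution. Unique-gene counts deduplicate symbols across all
regions genome-wide.

**Isochore classification.** For a region *R* with GC percentage
*g*, left flank *gₗ* and right flank *gᵣ* (flanks nominally `flank_len` =
100 kb, truncated at chromosome ends):

* *isochore* if (*g* − *gₗ* ≥ t and *g* − *gᵣ* ≥ t) or
  (*g* − *gₗ* ≤ −t and *g* − *gᵣ* ≤ −t), with t = 2 percentage points;
* else *isochore border* if |*gₗ* − *gᵣ*| > t and |*gₗ* − *gᵣ*| exceeds
  both |*g* − *gₗ*| and |*g* − *gᵣ*|;
* else *unknown*.

The isochore rule is tested first so the categories are exclusive. The
border rule's "exceeds both contrasts" reading is the stricter of the two
possible readings of the verbal definition; `border_rule="either"`
switches to the permissive one. GC is counted case-insensitively over
A/C/G/T only; N and other symbols are excluded from numerator and
denominator, and an all-ambiguous window is *undefined*, never 0%.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_len` | 100 000 bp | minimum region length; ≥ comparison (inclusive). 100 kb is the scale of strong linkage-disequilibrium blocks. The smallest catalogued region (100 403 bp) passes under either the inclusive or strict reading. |
| `maf_min` | 0.01 | MAF threshold for "common". The MAF of a table row is the smallest nonzero listed allele frequency; rows without parseable frequencies pass through, because common-SNP tables are already MAF-filtered upstream. |
| `flank_len` | 100 000 bp | nominal flank window for GC classification |
| `threshold_pp` | 2.0 | GC contrast threshold, percentage points |
| `min_usable_fraction` | 0.5 | minimum usable (A/C/G/T) bases per window, as a fraction of the window's *nominal* length — so a flank truncated below half the nominal flank at a chromosome end degrades the call to *unknown* (conservative: the published rule is silent on edges) |
| `border_rule` | `"both"` | strict vs permissive border test |

## Numerical choices

GC threshold comparisons use exact rational arithmetic
(`fractions.Fraction` over the raw G+C and usable-base counts), so a
contrast of exactly 2.00 points is classified identically on every
platform — no float-epsilon flakiness at the boundary. All stage outputs
are sorted by (chromosome, start, end) and region ids are deterministic
functions of (stage, chromosome, start), so identical inputs give
byte-identical BED and report files.

## Synthetic data: what it does and does not emulate

`snpdesert.simulate` generates bundles in the exact table dialects the
readers parse: common SNPs as a homogeneous Poisson process (default rate
10⁻³/bp, about the genome-wide common-SNP density) with planted SNP-free
deserts excised; assembly gaps, CNVs and segmental duplications as planted
intervals; multi-isoform gene models; personal-genome variants placed
Poisson everywhere (rare variation persists inside common-SNP deserts —
that is the phenomenon the screen probes); and FASTA sequence drawn i.i.d.
per GC block with P(G)+P(C) equal to the block target. One global seed
expands into fixed per-component substreams (sequence = seed+1,
SNPs = +2, personal variants = +3, MAFs = +4), so regenerating one table
never perturbs another.

The generator does **not** model linkage disequilibrium, realistic allele
frequency spectra, mutation-rate heterogeneity, or sequence composition
beyond block-wise GC. Passing tests on synthetic bundles therefore
demonstrate the correctness of the interval logic, parsing and
classification rules — not that the statistical model of real variant
density is right.

Tests and examples run the pipeline at desk scale (2 Mb chromosomes,
10 kb threshold, 1 kb GC flanks); the algebra is scale-free and the
genome-scale defaults are plain configuration.

## The packaged catalog and its reconstruction

The published hg19 screen (50 SNP-free regions with genes and isochore
labels; 20 variant-free regions) ships as two small TSV fixtures. Rather
than shipping hundreds of MB of dbSNP/DGV dumps, `snpdesert.catalog`
*inverts* the catalog into minimal inputs: SNP records bracketing each
region (insertion records at shared boundaries), a CNV set defined as the
SNP-free cover minus the variant-free cover, one transcript per symbol
spanning the regions that list it, a GC-block genome realizing each
region's label, and a synthetic array-probe fixture (probe positions were
never published; only the counts — 25 probes, 4 polymorphic — and the four
polymorphic rsids are, so the fixture constructs positions at region
midpoints and carries the published rsids).

Running the pipeline on this reconstruction reproduces the published
numbers exactly where the publication is self-consistent: 50 SNP-free
regions (coordinate-exact), 33 on chrY across 8 chromosomes, largest
3 540 431 bp, 97 distinct genes, isochore label counts 7/25/18
(isochore/border/unknown), and the final 105 216 bp chrX residual.

Known divergences, all traceable to internal inconsistencies of the
published tables rather than to the method:

* The variant-free table has 20 rows, but one (chrY 17559652–17661377)
  lies inside no published SNP-free region and another
  (chrY 4935714–5205540) extends beyond its nearest one. Since CNV
  subtraction can only shrink regions, the reconstruction yields **19**
  variant-free regions (17 chrY + 2 chrX), 18 of them coordinate-exact.
* The published text says 24 border regions, but its own label column
  tallies 25 (and the text's three label counts sum to 49, not 50). The
  classifier reports the tally of the table it was given: 25.
* The published text says 97 genes across 28 regions; the table's gene
  column is non-empty in 29 rows. The unique-gene count (97) is exact;
  the gene-bearing-region count is reported as computed, not forced.

## Known limitations

* No liftOver between assemblies; coordinates are taken as given.
* No VCF input (the supported sources predate routine VCF distribution of
  these tracks; UCSC tables + BED cover every input).
* CNV record types (gain/loss/inversion) are not distinguished; the DGV
  reader ingests all rows, and any filtering is the caller's
  configuration.
* No strandedness, no overlap-fraction thresholds (the assignment
  criterion is ≥ 1 bp), no genome-wide isochore segmentation, and no
  GO/pathway enrichment (the published enrichment depended on an external
  web service's annotation database).
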