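# rnaimap

Quantitative genetics of germline RNAi sensitivity variation in
*Caenorhabditis elegans*, built around the N2 × CB4856 cross.

The laboratory strain N2 is fully sensitive to feeding RNAi against the
essential germline gene *par-1* — treated mothers lay broods that are
100% embryonic-lethal — while the Hawaiian wild isolate CB4856 is almost
completely insensitive. Dissecting that difference runs into two
complications that this package models explicitly:

1. **Background-corrected phenotype.** The assay readout is embryonic
   lethality, which has a nonzero baseline. From plate counts of dead
   embryos (*DE*) and hatched larvae (*HL*) on treated and empty-vector
   control plates, the induced lethality is

   ```
   L = DE/(DE+HL)            (embryonic lethality per plate)
   induced = (L_t − L_c) / (1 − L_c)
   ```

2. **Linked incompatibility.** The major insensitivity gene *ppw-1*
   lies 7.47 cM from the *zeel-1/peel-1* element, which CB4856 lacks.
   Sperm from *peel-1* carriers deposit a toxin that kills zygotes
   homozygous for the deletion with penetrance *p*. In an F2 panel this
   viability selection distorts segregation away from the naive 3:1, so
   the expected phenotype-class frequencies must be computed under the
   joint two-locus model: gamete haplotype frequencies at recombination
   fraction r = cM/100, F2 as products of independent gametes, removal
   of susceptible zygotes with probability *p*, renormalization, and
   classification of survivors by genotype.

On top of these the package provides seeded forward simulators
(meiosis, F2 panels under viability selection, recombinant inbred
advanced intercross line (RIAIL) genomes, binomial plate counts) and
interval mapping re-implemented from first principles: genotype
posteriors on a cM grid under a Haldane two-point model, a
nonparametric scan (posterior-weighted Kruskal–Wallis,
lod = H / (2 ln 10)), a Haley–Knott normal-model scan with covariates,
permutation thresholds, and lod-drop support intervals.

## Worked example

Expected F2 class frequencies under the linked incompatibility model,
and the additive extension with one unlinked recessive
intermediate-loss locus:

```python
>>> from rnaimap import F2SegregationModel
>>> print(F2SegregationModel(distance_cM=7.47, penetrance=0.26).summary())
F2 segregation model (linked incompatibility)
  distance: 7.47 cM  (r = 0.0747, linear)
  toxin penetrance: 0.26
  expected surviving-F2 classes:
     total_lethality:  79.2%
        no_lethality:  17.1%
       low_lethality:   3.7%
  with unlinked recessive intermediate-loss modifier:
                high:  59.4%
        intermediate:  19.8%
                 low:  20.8%
```

Reading: with 26% toxin penetrance, 79.2% of surviving F2 are expected
to carry at least one N2 *ppw-1* allele and show fully lethal broods;
17.1% are insensitive with clean broods; 3.7% are insensitive but
heterozygous at the incompatibility locus, so their self-broods lose
p/4 = 6.5% of offspring ("low lethality"). Adding the unlinked modifier
splits the sensitive class 3:1 into high and intermediate sensitivity.

Testing observed F2 counts against the additive model, and the same
from the shell:

```sh
$ rnaimap segregation --model additive \
    --observed "full=109,high=22,intermediate=12,low=38"
            high:  59.4%
    intermediate:  19.8%
             low:  20.8%
chi-square goodness of fit
              high: observed   109.00  expected   107.53
      intermediate: observed    34.00  expected    35.84
               low: observed    38.00  expected    37.62
  chi2 = 0.1187, df = 2, P = 0.942
```

The observed counts are statistically indistinguishable from the
additive two-locus expectation (P = 0.94).

Simulate a 150-line RIAIL panel with a single recessive major-effect
locus at 20 cM on chromosome I, then map it:

```sh
$ rnaimap simulate --preset ppw1_only --n-lines 150 --seed 7 --out-prefix demo
$ rnaimap scan demo.cross.csv --n-perm 1000 --seed 7
interval mapping scan (np)
  306 positions, 6 chromosomes
  permutation threshold: 2.605
  per-chromosome maxima:
       I     20.0 cM  lod  27.41  *
      II      8.0 cM  lod   0.64
     III     30.0 cM  lod   1.25
      IV      9.0 cM  lod   0.47
       V      1.0 cM  lod   0.38
       X     18.0 cM  lod   0.96
  peak: I @ 20.0 cM, lod 27.41
  1.5-lod support interval: I [19.0, 21.0] cM
```

The scan recovers the simulated locus exactly: the only position above
the 1000-permutation 5% threshold (2.605) is the causal marker, and the
1.5-lod support interval brackets it. The same analysis is available as
library calls via `IntervalMapping(panel, phenotype).fit("np")`, which
returns a `ScanResult` with `summary()`, `support_interval()` and
`plot()`.

File formats: genotype panels use the conventional cross CSV dialect
(header row of phenotype + marker names, then chromosome and cM rows,
then one row per line with alleles coded A = N2, B = CB4856,
"-" = missing); plate counts are tidy CSVs with columns
strain, condition, dead_embryos, hatched_larvae, replicate.

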