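# snp-ploidy

SNP-based triploidy screening and uniparental-disomy (UPD) scanning for
low-coverage whole-genome sequencing (LC-WGS), aimed at miscarriage-tissue
(products-of-conception) diagnostics where triploidy is one of the most
common chromosomal causes of pregnancy loss but is invisible to read-depth
CNV callers.

## The statistic

At a heterozygous biallelic SNP, define the **mutation ratio** (MR) — the
B-allele fraction — as the share of reads supporting the alternate allele:

```
MR = alt_depth / (ref_depth + alt_depth)
```

A diploid heterozygote (AB) centres at MR ≈ 1/2; a triploid heterozygote
carries the alternate allele on one (AAB) or two (ABB) of three
homologues, so its MR centres at 1/3 or 2/3.  Candidate SNPs (present in
a common-SNP panel with minor-allele frequency > 5%, total depth ≥ 10,
both alleles observed) are counted into three closed MR intervals:

| interval | range        |
|----------|--------------|
| "1/3"    | [0.28, 0.38] |
| "1/2"    | [0.45, 0.55] |
| "2/3"    | [0.62, 0.72] |

The three counts, normalised to sum to one, give points (1/3, y₁),
(1/2, y₂), (2/3, y₃), through which the unique parabola
y = ax² + bx + c is fitted in closed form:

```
a = 18(y₁ − 2y₂ + y₃),   b = 3(y₃ − y₁) − a,   c = y₂ − a/4 − b/2
```

**Triploid**: the parabola opens upward (a > 0) with symmetry axis
−b/2a in [0.45, 0.55].  **Diploid**: it opens downward (a < 0).  Under
the sum-to-one normalisation, a > 0 is algebraically equivalent to the
side-to-centre count ratio (n₁/₃ + n₂/₃)/n₁/₂ exceeding **2**, so the
ratio cutoff and the parabola rule are the same classifier.  A Z-test of
each sample's ratio against its sequencing batch is attached as
auxiliary evidence only.

The same candidate sites, binned per megabase, give the heterozygous-SNP
frequency (HSF) used to flag whole-chromosome or segmental runs of
depressed heterozygosity (HSF ≤ 5%) consistent with isodisomic UPD, and
the X:autosome depth dosage provides a maternal-cell-contamination guard.
A generative simulator (Hardy–Weinberg genotypes, Poisson depth, binomial
reads, maternal admixture, mosaicism, UPD regions) makes every stage
testable without sequencing data.

## Worked example

Simulate a small batch (3 diploids, 1 triploid; two 20-Mb chromosomes,
1500 panel SNPs each), classify it, and score against the simulation truth:

```
$ snp-ploidy simulate --config sim.yml --n-diploid 3 --n-triploid 1 --seed 7 --out demo
$ snp-ploidy batch --manifest demo/manifest.tsv --panel demo/panel.tsv --out demo/out
$ cat demo/out/calls.tsv
sample_id  verdict   ratio  a       axis   z      n_candidate_sites  flags
DIP_001    diploid   0.81   -11.81  0.495  -0.65  1054
DIP_002    diploid   0.82   -11.68  0.499  -0.50  1063
DIP_003    diploid   0.90   -10.41  0.502   1.15  1081
TRI_001    triploid  2.28     1.54  0.458  29.10  1549  z_outlier
$ snp-ploidy evaluate --calls demo/out/calls.tsv --truth demo/truth.tsv
tp=1 fp=0 fn=0 tn=3 inconclusive=0
sensitivity=100% specificity=100% accuracy=100%
```

(Numeric columns abbreviated to 2–3 decimals for display.)  The triploid
sample sits far above the ratio cutoff of 2 with an upward-opening
parabola (a = +1.54) and a centred axis; the diploids open downward.
`snp-ploidy call` reports one sample, `snp-ploidy upd` emits the per-bin
HSF table and UPD BED track, and `snp-ploidy titrate` generates the
depth-requirement curve.

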