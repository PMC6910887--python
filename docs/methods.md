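# Methods

## Problem and model

Triploidy (69,XXX / 69,XXY / 69,XYY) leaves genome-wide read depth
essentially flat, so depth-based CNV analysis of low-coverage WGS cannot
see it.  What does change is the allele balance at heterozygous sites:
with three homologues, a heterozygous SNP carries the alternate allele
in one or two copies, so its read-level alternate fraction (mutation
ratio, MR) concentrates near 1/3 or 2/3 instead of 1/2.  The classifier
turns this distributional shift into a single, nearly assumption-free
statistic.

Per sample:

1. **Candidate selection.** Keep biallelic SNPs that match a common-SNP
   panel on position and alleles, have panel minor-allele frequency
   > `min_panel_af`, and total depth ≥ `min_total_depth`.  Heterozygosity
   is decided observationally (≥ `het_min_minor_reads` reads on each
   allele) — genotype callers assume diploidy, which is exactly what is
   in question here, so the VCF GT field is ignored.  INDELs and
   multi-allelic records are excluded at parse time: the MR model is
   defined for one alternate allele, and panel matching makes only SNPs
   usable.
2. **Interval counting.** Count candidate het MRs in the closed
   intervals [0.28, 0.38], [0.45, 0.55], [0.62, 0.72].  The ±0.05 bands
   absorb binomial read-sampling noise at 10–20 reads per site; MRs
   outside all three bands contribute nothing.
3. **Exact quadratic fit.** Normalise the three counts to sum to one and
   interpolate the unique parabola through (1/3, y₁), (1/2, y₂),
   (2/3, y₃).  With abscissa spacing h = 1/6 the closed forms are
   a = 18(y₁ − 2y₂ + y₃), b = 3(y₃ − y₁) − a, c = y₂ − a/4 − b/2.  Three
   points determine a quadratic uniquely, so there are no fitting
   tolerances; a 3-point least squares is identical and serves as an
   independent oracle in the tests.
4. **Verdict.** a > 0 (centre-depleted, upward-opening) with symmetry
   axis −b/2a near 1/2 ⇒ triploid; a < 0 ⇒ diploid.  Under sum-to-one
   normalisation, a = 18(1 − 3y₂), so a > 0 ⇔ y₂ < 1/3 ⇔
   (n₁/₃ + n₂/₃)/n₁/₂ > 2: the ratio cutoff of 2 is the same decision
   boundary, exactly.
5. **Batch Z-test (auxiliary).** Each sample's ratio is Z-scored against
   the mean/SD of its batch's presumed diploids (ratio ≤ 2; this robust
   reference prevents triploids from masking themselves).  |Z| ≥ 3 adds
   a flag; the Z never overrides the parabola verdict.

### Decision thresholds

| parameter | default | rationale |
|---|---|---|
| `min_panel_af` | 0.05 | common SNPs only; rare alleles carry no het signal and are artifact-enriched.  Applied to the minor-allele frequency min(af, 1−af) — whichever allele is rare makes the site uninformative |
| `min_total_depth` | 10 reads | below ~10 reads the three MR intervals are barely resolvable (at depth 9 no attainable fraction falls in [0.28, 0.38]) |
| axis range | [0.45, 0.55], inclusive | the vertex of a genuine triploid fit sits at 1/2 ± counting noise |
| `axis_round_dp` / `axis_slack` | 2 d.p. / 0.01 | confirmed triploids occur with axes that print at 0.56; such samples are still called triploid but flagged `axis_out_of_range`.  `strict_axis` demotes them to `triploid_low_confidence` instead |
| `min_candidate_sites` | 1000 | below this the interval counts are too noisy for a verdict; the sample is `inconclusive` (`low_sites`), never silently called |
| `z_flag_threshold` | 3.0 | conventional outlier bound; auxiliary only |
| `mosaic_band` | ratio ∈ [1.9, 2.1] | intermediate counts (diluted triploid signal) raise `possible_mosaic`; no mosaic-fraction estimate is attempted |
| a = 0 exactly | — | degenerate; `inconclusive`, never diploid |

## UPD / LOH scan

The genome is tiled in 1-Mb bins (0-based half-open, last bin
truncated).  Per bin, the heterozygous-SNP frequency (HSF) is
n_het / n_informative, where informative sites are covered panel SNPs
passing the same depth filter as the ploidy analysis — using all panel
sites as denominator would make low-coverage bins masquerade as LOH.
Bin colours: **gap** when ≥ 50% of the bin lies in a declared assembly
gap; **yellow** (no HSF reported) when n_informative < 20, the point at
which a normal ~30% het rate stops being distinguishable from 5% at
binomial resolution; **pink** when HSF ≤ 5% (the boundary value 5% and
HSF = 0 both count as pink); **green** otherwise.

For the scan, a site counts as heterozygous only with ≥ 2 reads per
allele (stricter than candidate selection): one discordant read in ~15
is overwhelmingly a sequencing error, and counting such sites pushes the
apparent HSF of a truly isodisomic region (~3% at error rate 0.002)
against the 5% boundary.

Whole-chromosome UPD is called when ≥ 90% of a chromosome's informative
(green/pink) bins are pink; otherwise maximal runs of ≥ 5 consecutive
pink bins, tolerating ≤ 1 yellow/gap bin strictly inside the run, are
emitted as segmental calls.  All three knobs are configurable and
logged.  Without parental genotypes, isodisomy cannot be distinguished
from other LOH mechanisms, so reports say "consistent with UPD"; calls
span bin boundaries, not base-precise breakpoints.

## Contamination guard and depth titration

Maternal cells admixed into fetal tissue are 46,XX, so in a male fetus
they raise the X:autosome per-site depth dosage above the hemizygous
expectation of 0.5 (e.g. to 0.7·0.5 + 0.3 = 0.65 at 30% admixture).
The guard infers apparent sex from the X heterozygosity rate relative to
autosomes (override with `known_sex`), then flags a sample whose dosage
exceeds the sex expectation by > 25% relative — or, for an XX-looking
sample, falls > 25% below the XX expectation, the same admixture seen
from the other side: heavy contamination of a male fetus fakes X
heterozygosity before it restores the full XX depth dose.  The dosage
scale is used for the flag (the X *fraction* of total depth, also
reported, compresses the excess nonlinearly with the panel's X share).
Sex-chromosome dosage abnormalities (69,XXY) can legitimately trip this
flag; it marks samples for scrutiny.

`depth_titration` simulates one configuration across a ladder of mean
depths and reports, per depth, the mean and SD of the ratio statistic
and an **instability** column: the RMS deviation of that depth's
replicate ratios from the deepest depth's mean.  Instability — spread
about the converged value — is the quantity that shrinks monotonically
with depth and stabilises by roughly 3×; the plain replicate SD does not
decrease monotonically at the bottom of the ladder because the
statistic's own mean is still drifting there (few attainable MR values
exist at 1–2 reads).  The titration filter defaults to
`min_total_depth = 2`, since the production cutoff of 10 would discard
nearly every site at 1–3× coverage.

## Simulator

`simulate_sample` draws, per panel site: genotypes under Hardy–Weinberg
at the configured ploidy (Binomial(copies, af)); an independent maternal
diploid genotype; depth ~ Poisson(mean_depth × dosage weight); and alt
reads ~ Binomial(depth, p), where p mixes the fetal allele dose with the
maternal one at weight `maternal_fraction` and applies a symmetric
per-read error ε.  X-chromosome copy number follows the sex karyotype
(XX/XY and XXX/XXY/XYY) and scales both depth and allele dose; UPD
regions force fetal homozygosity; mosaicism mixes the allele dose with a
concordant second cell line (one homologue lost or duplicated) at weight
`mosaic_fraction`, autosomes only.

Defaults are the intended operating conditions: 700 panel sites per
chromosome over the GRCh37 autosomes + X (≈16,000 sites, yielding
≈5,000–8,000 candidate het SNPs per sample), mean depth 15 — the read
count available per site after the site filter, comfortably above the
≥ 10-read cutoff — ε = 0.002, and panel alternate-allele frequencies
uniform on [0.05, 0.95].  The frequency symmetry matters: it represents
a panel thresholded at 5% *minor*-allele frequency, where the reference
allele is the major one only about half the time, and it keeps the AAB
and ABB heterozygote classes of a triploid balanced so the parabola axis
centres near 1/2 — which is how confirmed triploid fits behave.  A
one-sided frequency range (alt ≤ 0.5) would skew AAB:ABB ≈ 3:1 and push
the axis to ~0.64, a geometry the axis criterion would reject.

What the simulator does **not** model: GC/mappability depth bias,
alignment artifacts, linkage between neighbouring sites, reference-allele
read bias, or mother–fetus inheritance (the maternal genotype is drawn
independently from the same allele frequency — adequate for
contamination dosage arithmetic, wrong for identity-by-descent
questions).  Consequently, simulated diploids show side-to-centre ratios
around 0.8–0.9, lower than the ~1.8 typical of real LC-WGS batches,
whose MR distributions are broadened by the artifacts above.  Both sit
on the correct side of the cutoff at 2; passing tests demonstrate the
classifier's behaviour under its stated noise model, not robustness to
every artifact of real data.

## Problem sizes used in the test suite

Stochastic checks run at deliberately compact scales chosen so each
check still has clear resolution: the simulated cohort experiment uses
50 diploids + 8 triploids at full per-sample scale; parameter recovery
uses 200 samples at ≥ 5000 candidate sites; contamination monotonicity
uses 50 replicates at each admixture fraction {0, 0.1, 0.2, 0.3} on a
3 × 20-Mb genome; UPD recovery uses 100 replicates; the depth ladder
{1, 2, 3, 5, 10}× uses 50 replicates per depth.  All seeds are fixed;
every simulation is reproducible bit-for-bit.

## Numerical and degenerate-case conventions

Interval membership uses closed bounds with plain floating-point
comparison (the intervals are disjoint, so no MR can be double-counted).
The parabola fit is exact interpolation; the only degeneracies are all
three counts zero (no fit; `degenerate_fit`) and a = 0 (axis undefined;
`inconclusive`).  A zero centre count makes the ratio statistic
undefined (`ratio_undefined`, `inconclusive`) rather than infinite.
Batch Z-scores are NaN when the reference SD is 0 (`z_undefined`), and
the batch test requires ≥ 3 samples with ≥ 2 in the diploid reference.
Site tables and VCFs are 1-based; bins and BED output are 0-based
half-open.  Reports serialise deterministically (byte-identical for
identical input and config).

## Known limitations

Near-triploid karyotypes (68,XX; 68,XXY,−21) are indistinguishable from
full triploidy by this statistic and are reported as triploid.  Mosaic
samples yield intermediate interval counts; the method only flags them.
Heterodisomic UPD (heterozygosity preserved) is invisible without
parental genotypes.  The contamination guard is qualitative and blind in
female fetuses with female contaminant.  Published per-batch reference
values (e.g. a batch ratio mean near 1.77) are properties of a
laboratory's data distribution and are not reproduced by the idealised
noise model here.
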