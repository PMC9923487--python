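# Methods

## The problem and the model

Pool-seq experiments sequence one library per *pool* of individuals, so
individual genotypes are unobservable; the data at a locus are the per-pool
read depths supporting the reference and alternative alleles.  This package
scans such data for loci whose alternative-allele frequency tracks a
phenotype label (inner-shell color in the pearl oyster design it was built
around: red, yellow, green) while controlling for the pools' geographical
site of origin (three wild lagoon sites plus one hatchery cohort).

At each locus the pool allele frequencies `AF = AD_alt / (AD_ref + AD_alt)`
are modelled by ordinary least squares on a treatment-coded two-factor
design,

    AF_j = mu + color(j) + site(j) + e_j ,   j = 1..12 pools,

i.e. a Gaussian identity-link GLM.  AF is bounded on [0, 1] but is treated
as a continuous response; with only one pool per (site, color) cell no
interaction is estimable, and the additive model is exactly what isolates a
"universal" color signal that is shared across sites.

All pairwise level differences of each factor (Tukey all-pairs contrasts;
K1 for the 3 color pairs, K2 for the 6 site pairs) are tested
simultaneously on the fitted coefficients: for each row k of
K = rbind(K1, K2),

    est = k'beta,  se = sqrt(k' Cov(beta) k),  t = est / se ,

with a two-sided Student-t p-value on the residual degrees of freedom
(12 − 6 = 6 for the full design) and a Bonferroni factor of 9 (the stacked
family) applied per locus.

A locus is then classified:

* **geography-associated** — any site pair significant at the threshold;
* **color-associated** — at least one color pair significant *and* no site
  pair significant (the exclusion rule removes loci confounded with
  geography);
* **color-specific** to color *c* — color-associated and every pair
  involving *c* significant.  If all three color pairs are significant, two
  colors qualify simultaneously; no specific color is assigned and the
  locus carries an `all_color_pairs` flag (the rule set does not define
  this case).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_dp` | 20 | depth floor; a record is dropped unless every pool reports DP ≥ 20 (`depth_scope="total"` instead sums DP across pools) |
| `min_maf` | 0.01 | folded minor-allele floor on the unweighted across-pool mean AF |
| `alpha` | 1e-9 | classification threshold on the Bonferroni-adjusted p |
| `correction` | bonferroni | per-locus family correction (or `none`) |
| `family_scope` | snp | Bonferroni family: the 9 contrasts within a locus, or `genome` = 9 × loci |
| `flank` | 2000 bp | strand-aware up/downstream window around genes |
| `window_bp` | 10 000 | pi window span |

Notable conventions:

* **AF denominator.** DP can exceed AD_ref + AD_alt (uninformative reads).
  AF is always the allele-count fraction AD_alt/(AD_ref+AD_alt); the depth
  filter is the only consumer of the raw DP field.
* **Depth filter scope.** The per-pool reading is the strict one — it
  guarantees every AF entering the model meets the floor — and is the
  default; the site-level (summed) reading is available as a switch.
* **MAF for pools.** A cohort MAF is not defined for pooled data; the
  folded frequency of the across-pool mean AF is the simplest pool-level
  analogue and is what the filter folds.
* **Bonferroni family scope.** The default family is the 9 contrasts
  within one SNP, not contrasts × loci: at the 1e-9 threshold a genome-wide
  family over tens of millions of loci would make the test unpassable, and
  the extreme threshold itself plays the genome-wide-stringency role.  The
  genome-wide family is available as `family_scope="genome"`.
* **Block substitutions.** Equal-length multi-base REF/ALT records are
  decomposed into one SNP per mismatching base, each child inheriting the
  parent's per-pool depths verbatim (the depths were counted for the whole
  haplotype block; re-counting per base is not possible from a VCF).
  Unequal-length records (indels) are dropped with a counter — the
  retained universe is biallelic SNPs.
* **Filter bookkeeping.** The kept set is order-independent; rejection
  *attribution* follows the fixed order biallelic → depth → missing → MAF
  (first failing rule).

## Statistical power at extreme thresholds

With 12 pools and 6 residual degrees of freedom, the Student-t null has
heavy tails: a Bonferroni-adjusted p below 1e-6 requires |t| ≈ 29, and
below 1e-9 requires |t| ≈ 92.  A planted AF shift of 0.4 under the
generator's two-stage noise (15 diploids/pool, 80× depth) produces |t|
around 5–10.  Consequently, at thresholds like 1e-6 or 1e-9 the scan does
not detect moderate planted shifts at all — the acceptance script reports
the measured sensitivity at 1e-6 (≈ 0.001), and the corresponding
acceptance check is expected to fail under these conditions.  p-values
this small arise only from (near-)degenerate fits, i.e. loci approaching
fixed differences between groups, where the residual variance collapses.
This is a property of the 12-observation design, not of the
implementation: practitioners applying the 1e-9 rule are, in effect,
selecting near-fixed differences.  At conventional levels the machinery is
well calibrated (measured family-wise error ≈ 0.035 at α = 0.05 over 2 000
null families) and powerful (≈ 0.92 of strong planted shifts recovered as
color-specific at α = 0.05).

## Degenerate fits

Zero-residual fits are routine in noise-free tests and in saturated real
data, and must not crash a genome-scale scan.  When se = 0: estimate = 0
gives p = 1 (no evidence); estimate ≠ 0 gives p = 0 with a `degenerate`
flag carried into the per-locus table.  Because AF inputs reproduced
exactly by the design leave only floating-point residue, variances below
1e-20 and contrast estimates below 1e-10 (AF units) are snapped to zero
before this rule is applied.

## The synthetic generator

The generator emulates the 12-pool design: 4 sites × 3 colors, 172 diploid
individuals (wild pools of 12–13, hatchery pools of 20).  Loci are
neutral / color-shifted / site-shifted / jointly shifted in configurable
fractions (default 0.90/0.04/0.04/0.02); a color shift adds `color_effect`
(default 0.4) to one color's pools at *all* sites.  Baseline frequencies
are uniform on [0.05, 0.95] — wide enough to exercise the MAF filter's
neighbourhood while avoiding loci that are monomorphic in expectation —
and shifted frequencies are clamped to [0.01, 0.99] so planted loci pass
the MAF filter by construction.  Default depth is 80×, a realistic
per-pool figure for a whole-genome pool-seq budget.

Noise is two-stage: the realised pool frequency is Binomial(2N, p)/2N
(which individuals' chromosomes went into the pool), then reads are
Binomial(dp, q) at dp ~ Poisson(depth), floored at 1.  The first stage is
what distinguishes pool-seq from individual sequencing; its extra variance
(≈ p(1−p)/2N) dominates at realistic pool sizes and is the binding
constraint on power above.  Randomness is counter-based — truth uses the
stream (seed, 0) and locus i's reads use (seed, 1, i) — so outputs are
byte-reproducible and per-locus draws never depend on locus order.

What the generator does **not** emulate: linkage disequilibrium between
loci (draws are independent), sequencing-error base miscalls, mapping or
reference bias, coalescent site-frequency spectra, and family structure
within pools.  Passing tests therefore demonstrate the statistical
machinery's correctness and calibration under the assumed noise model, not
robustness to those real-data artefacts.

## Effect annotation

Only the effect vocabulary needed downstream is implemented: strand-aware
upstream/downstream within a 2 000 bp flank (the conventional default),
intron, intergenic, and the coding consequences obtained by splicing the
CDS, substituting the base (reverse-complemented for − strand genes) and
translating with the standard code (stops as `*`, internal stops
retained).  Impact classes are fixed: stop/start gain/loss → HIGH,
amino-acid change → MODERATE, synonymous → LOW, the non-coding classes →
MODIFIER.  UTR, splice-site and frameshift classes are out of scope;
positions inside a gene but outside every CDS interval — introns *and* any
non-coding exon parts — are reported as `intron_variant`.  A SNP in the
flank of several genes gets one annotation per gene; `most_severe` reduces
for summaries.  Intergenic records carry no gene id by default.

## Descriptive summaries

* **Windowed pi** — per variant site, the finite-sample heterozygosity
  (n/(n−1))·2p(1−p) with n the pool's haploid sample size; summed per
  window and divided by the window span in bp (10 kb default).  The
  alternative reading of a "10 000 sites" window — dividing by the number
  of variant sites — is exposed as `denominator="sites"`.  Pi is invariant
  to ref/alt relabelling, and fixed sites contribute nothing.
* **PCA** — SVD of the column-centered pools × loci matrix; at most
  `n_pools − 1` components.  Sign is fixed deterministically (the
  largest-magnitude loading of each axis is made positive) so runs are
  reproducible.
* **Rank tests** — Kruskal–Wallis (tie-corrected, chi-squared reference;
  all-identical input returns H = 0, p = 1) and all-pairs Wilcoxon
  rank-sum with Bonferroni adjustment.  The rank-sum p is exact by full
  enumeration of rank assignments when the combined sample is ≤ 20
  (mid-ranks handle ties correctly), otherwise the normal approximation
  with tie and continuity correction.  The compact letter display uses the
  greedy insert–absorb algorithm with ties broken by group order.
* **AF histograms** — 30 equal-width bins on [0, 1] with a right-closed
  last bin so AF = 1 is counted; out-of-range values are an error, never
  silently truncated.

## Problem sizes used by the test and acceptance runs

Simulated checks run at desk scale: 2 000 null replicates for family-wise
error, 10 000 neutral loci for the stringent-threshold null, 5 × 5 000
loci for planted-effect recovery, 1 000 random REF/ALT pairs for the
decomposition oracle, and a 12 kb single-gene genome swept base by base
for annotation breakpoints.  These sizes give stable Monte-Carlo estimates
(binomial SE < 0.01 on the reported rates) while keeping a full run in
seconds.

## Known limitations

* AF is modelled as unbounded Gaussian; near-fixed loci violate
  homoscedasticity and are exactly the loci an extreme threshold selects.
* One pool per (site, color) cell means color-by-site interactions are
  confounded with residual noise and cannot be tested.
* The within-SNP Bonferroni family does not control the genome-wide error
  rate; the extreme default threshold is the (blunt) instrument for that.
* The annotator handles one transcript per gene and ignores phase
  attributes in GFF3 input; CDS lengths must be multiples of 3.
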