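# Methods

## The calibration problem

Microsatellite diversity statistics printed in different studies cannot be
compared at face value. Marker panels rarely coincide, and allelic
diversity *A* (the number of distinct alleles at a locus) grows with the
number of individuals genotyped, so a 20-sample study and a 200-sample
study of the same population will print different numbers for the same
quantity. The yardstick approach resolves this by fixing one well-sampled
**reference population** and expressing every other population's indices
relative to it, using only the loci the two datasets share and equalising
sample sizes by resampling.

## Indices

For a locus with `n_typed` complete diploid genotypes and allele
frequencies `p_i` estimated from the `2·n_typed` gene copies:

- `Ho` — fraction of typed individuals that are heterozygous;
- `He` — `1 − Σ p_i²` ("biased"), or with Nei's small-sample correction
  `2n/(2n−1) · (1 − Σ p_i²)` ("unbiased", the default);
- `A` — count of distinct observed alleles. No rarefaction is applied at
  this level; sample-size correction is handled exclusively by the
  resampling engine so that the calibrated and uncalibrated views stay
  comparable.

Both He estimators are exposed because published tables do not always say
which convention their toolchain used; reproducing a specific printed table
may require `he_estimator="biased"`.

Population-level values are unweighted across-locus means; their standard
error is the sample (n−1) standard deviation across loci divided by `√L`.
With one locus the s.e. is undefined and reported as absent. The
inbreeding summary is `Fis = 1 − Ho_mean/He_mean`.

## Comparison procedure

Given a reference `R` (sample size `N_R`) and a target `T` (size `N_T`),
restricted to the `k` shared loci:

1. **Sample-size equalisation.** The larger side is resampled *with
   replacement* down to the smaller side's size, 1000 replicates by
   default; each replicate yields across-locus means of `A`, `He`, `Ho`,
   and the replicate means/sds summarise the indices at the equalised
   size. When the target is known only through published indices and
   `N_T ≥ N_R`, both samples are large and similar, so the published
   values are compared directly without resampling; equal genotype sample
   sizes are also compared directly.
2. **Ratio indices.** `Her = He_T(shared) / He_R(shared baseline)` and
   `Art = A_T(shared) / A_R(shared baseline)`, reference in the
   denominator.
3. **Calibrated indices.** `Hec = Her · He_R(full panel)` and
   `Ac = Art · A_R(full panel)` put the ratios back on the familiar scale
   of the reference's complete marker panel. The calibrated observed
   heterozygosity is `Hoc = Hec · (Ho/He)`, where the `Ho/He` ratio comes
   from the target's *original full data* (more loci, no resampling — the
   relationship between the two heterozygosities is better estimated
   there), never from the shared subset.

`Hec/He_R = Her` and `Ac/A_R = Art` hold exactly for every emitted result,
by construction.

### Uncertainty

The variance of a ratio is propagated by the first-order delta method for
`R = x_T/x_R` with independent numerator and denominator:
`se_R² = se_T²/x_R² + x_T²·se_R²/x_R⁴`. The resampled side contributes its
Monte-Carlo sd over replicate means; a fixed genotype side contributes its
across-locus s.e.; a published per-locus side contributes the across-locus
s.e. of the printed values; a mean-only published value enters as a point
value with zero s.e. Calibrated values inherit the ratio s.e. scaled by
the (fixed) full-panel reference value. Confidence intervals are normal:
`estimate ± 1.96 × s.e.`.

Because both sides of a comparison are evaluated on the *same* loci, the
locus-to-locus component of variance is shared and partially cancels in
the ratio; the independence assumption therefore errs on the conservative
side, which the recovery experiments confirm (3·s.e. coverage ≥ 95%,
empirically ~100%).

Note one deliberate reading: "the resampled mean agrees with the point
estimate at full sample size" is checked against the Monte-Carlo sd of a
*single* resampled estimate, not sd/√n_rep. Resampling individuals with
replacement carries the standard O(1/n) downward bias in He (≈0.004 at
n≈100 on an He of 0.8); it is negligible on the He scale and well inside
one replicate sd, but no correct bootstrap implementation could pass a
test at sd/√1000.

## Reference construction

The reference builder pools a random without-replacement subsample of one
area with the complete sample of a second area (e.g. 76 of 145 from one
region plus all 58 from another, giving 134), to balance sampling
intensity between areas with comparable population sizes. This
*constructs* a real reference set and is deliberately distinct from the
with-replacement resampling used for sample-size equalisation. The
reference's full-panel summary is computed once, over all its loci, and
recorded with the loci used.

## Hardy–Weinberg testing and locus screening

The exact test conditions on the observed allele counts. For ≤2 alleles
the heterozygote count h follows Levene's conditional distribution

    P(h) = n!·n_a!·n_b!·2^h / ((2n)!·n_aa!·h!·n_bb!),

enumerated in full; the p-value sums the probabilities of all outcomes no
more probable than the observed one (conditional-probability ordering).
For >2 alleles a seeded Monte-Carlo permutation of the pooled gene copies
is used with the conditional table probability as the ordering statistic
and the add-one estimator `(1 + #{perm ≤ obs})/(n_perm + 1)`; the two
routes use the same ordering and agree within Monte-Carlo error on
biallelic data. A monomorphic locus returns p = 1 with a flag. Per
population, p-values are corrected jointly with Holm–Bonferroni at
alpha = 0.05 (via statsmodels).

Null-allele screening estimates the frequency of non-amplifying alleles
from the heterozygote deficit: Brookfield's `r = (He−Ho)/(1+He)` (default)
or Chakraborty's `r = (He−Ho)/(He+Ho)`, clamped at 0. Loci are flagged,
never auto-excluded — exclusion is an explicit user decision
(`--exclude` in the CLI).

## Synthetic data

The generator emulates the statistical structure the method must cope
with, not the mutational process: per locus, ancestral allele frequencies
are explicit or symmetric-Dirichlet(concentration); subpopulation
frequencies follow the Balding–Nichols draw `Dirichlet(p·(1−Fst)/Fst)`
(chosen for its single interpretable parameter and analytic tractability);
genotypes are drawn with heterozygote deficit
`P(hom i) = p_i² + Fis·p_i(1−p_i)`, `P(het ij) = 2p_ip_j(1−Fis)`;
missingness is i.i.d. per genotype. Pooling Balding–Nichols
subpopulations produces the Wahlund heterozygote deficit, the main
real-data mechanism behind HWE departures. Allele codes are emitted as
`100 + 2k` so fixtures round-trip through 3-digit GENEPOP.

Not emulated: stepwise mutation dynamics, linkage, allelic dropout beyond
whole-genotype missingness, genotyping error. Passing tests therefore
demonstrate correctness of the estimators and the calibration algebra
under drift-free frequency sampling, not robustness to laboratory
artefacts.

### Study conditions used by the tests and the acceptance script

Chosen once as representative of the motivating setting:

- reference shape: 134 individuals × 33 loci (76-of-145 + 58 pooled),
  7 alleles per locus, Dirichlet(2.0) frequencies, 2% missingness;
- resampling engine checks: n_rep = 1000; rarefaction grid
  n_sub ∈ {5, 10, 20, 40, 80};
- recovery experiments: two populations of 60 and 40 individuals from one
  frequency process (the size imbalance forces the resampling path),
  8 alleles per locus, Dirichlet(1.0), shared panels k ∈ {4, 8, 17}
  (the realistic range from four shared loci upward), 100 trials per k,
  n_rep = 200 per comparison.

## Numerical and design choices

- Half-called genotypes (one allele missing) are coerced to fully missing
  at parse time and logged: the indices assume complete diploid calls, and
  silent data loss would be worse than a visible one.
- Allele pairs are stored sorted; phase is meaningless.
- Locus-name matching across studies is exact, with an explicit
  user-supplied alias map (`{"FH 2004": "FH2004"}`-style); fuzzy matching
  is deliberately refused. Fewer than 4 shared loci warns but proceeds.
- Batch runs derive per-row seeds as `master_seed + row_index`: the batch
  is reproducible as a whole and any row in isolation.
- Ties in sample size are compared directly (no resampling).
- A mean-only published population has no known panel; its comparison uses
  the reference's full panel as the baseline and is flagged accordingly.
- Published populations lacking per-locus A get `Art`/`Ac` absent with a
  flag (common in the literature when clusters share a panel); lacking any
  Ho/He information, `Hoc` is absent with a flag. Failures in a batch
  (e.g. no shared loci) become flagged failure records, never silent drops.
- Unweighted means are used when averaging published per-locus values;
  per-locus sample sizes are rarely printed, so weighting would be
  spuriously precise.

## Known limitations

- The delta-method ratio s.e. ignores the (favourable) correlation between
  numerator and denominator induced by sharing loci; intervals are
  conservative.
- Calibration corrects panel and sample-size incompatibility, not
  ascertainment differences in how studies chose markers.
- The exact-test enumeration is limited to biallelic loci; multiallelic
  p-values are Monte-Carlo estimates with the usual `1/(n_perm+1)`
  granularity.
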