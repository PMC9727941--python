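# Methods

## The estimation problem

The kinship coefficient `phi_ab` of two individuals is the probability
that two alleles sampled at the same autosomal locus, one from each
individual, are identical by descent (IBD).  With `(k0, k1, k2)` the
probabilities of sharing 0/1/2 alleles IBD, `phi = k1/4 + k2/2`; under no
inbreeding the standard values are 0.5 (MZ twins), 0.25 (parent-offspring
and full sibs), 0.125 (half sibs, avuncular), 0.0625 (first cousins).
For a homogeneous population in Hardy-Weinberg and linkage equilibrium,
the per-SNP genotype correlation of a pair equals `rho = 2 phi` at every
SNP, so estimating kinship reduces to estimating a genotype correlation.

The ubiquitous moment estimator (the sample-correlation GRM, scGRM)
averages per-SNP cross-products of genotypes centered at the *observed*
mean dosage `Xbar_j` and scaled by the genotype variance `sigma_j^2`:

    rho_hat_ii' = (1/m) sum_j (X_ij - Xbar_j)(X_i'j - Xbar_j) / sigma_j^2,
    phi_hat = rho_hat / 2.

Centering at the observed mean couples every pair to the cohort.  Under
known variances the exact expectation is

    E rho_hat_ii' = rho_ii' - (1/n) sum_{a!=i} rho_ia
                    - (1/n) sum_{a!=i'} rho_ai' - 1/n + (n-1)/n * rho_bar,

and summed over all pairs, `(n-1)(rho_bar - 1)/2 <= 0`: the estimates are
forced negative on average, which is why large GRMs always contain a mass
of negative "kinship" values.  Both formulas are exposed in `ukin.theory`
and double as oracles for the Monte-Carlo tests.

The UKin correction rebuilds an unbiased estimator out of the scGRM
matrix alone:

    rho_tilde_ii' = rho_hat_ii' + (1/2) sum_{k!=i} rho_hat_ik
                    + (1/2) sum_{l!=i'} rho_hat_li' + 1,

with `phi_tilde = rho_tilde / 2`.  Averaging both sides over all pairs
gives the exact affine identity `mean(rho_tilde) = n*mean(rho_hat) + 1`,
which the experiment runner verifies bit-for-bit.  The implementation
computes the correction from off-diagonal row sums in O(n^2) after the
single O(n^2 m) scGRM pass; a second, deliberately independent per-SNP
implementation (`ukin_per_snp`) exists only to cross-validate the matrix
path in tests.

Comparators: rGRM divides the summed *unscaled* centered cross-products
by the summed variances (weights proportional to `sigma_j^2`), and
KING-robust is the allele-frequency-free moment estimator
`(N_AaAa - 2 N_AA,aa) / (N_Aa(i) + N_Aa(j))` from shared-heterozygote and
opposite-homozygote counts.  Relationship degrees are called from `phi`
by the standard powers-of-2 thresholds (`2^-3/2`, `2^-5/2`, `2^-7/2`,
`2^-9/2`); the published intervals are open, so ties exactly at a
threshold are assigned deterministically to the more distant class.

## Variance source — the consequential knob

`EstimatorConfig.variance_mode` selects `sigma_j^2`:

* `known` — externally supplied true variances `2 p_j (1 - p_j)` (from
  the simulator, or a reference panel).  This is the regime of the
  closed-form expectations, and the only regime in which UKin is exactly
  unbiased.
* `sample` — unbiased sample variance (divisor `count - 1`) from the
  analysis set itself.  This makes two sums *deterministic*: per SNP the
  standardized scores satisfy `sum z^2 = n - 1`, so the all-pairs scGRM
  sum is exactly `-(n-1)/2` whatever the data, and the all-pairs mean of
  UKin correlations is exactly 0.  With self-estimated variances no
  estimator can recover a cohort-wide average relatedness; what UKin
  still fixes is the *relative* distortion between related and unrelated
  pairs.  This is the realistic default for real data.
* `hwe` — `2 phat (1 - phat)` from observed frequencies.

A related subtlety: SNPs that are monomorphic *within the analysis set*
are dropped when the variance is estimated from that set (the scale is
zero), but retained under `known` variances, where their centered scores
are 0 and contribute nothing.  Dropping them under known variances would
select SNPs on realized within-set variability and visibly bias the
family experiment below (a family of full sibs segregates only four
founder haplotypes, so at realistic MAFs roughly a third of SNPs are
family-monomorphic).

Missing genotypes are mean-imputed per SNP before centering (an imputed
entry has centered score 0 and contributes nothing to any cross-product);
KING uses pairwise-complete counts instead.  Estimates are never
truncated to `[0, 0.5]` — negative values are the phenomenon under
study.

## The simulator

Genotypes are generated by pedigree gene-dropping: founder haplotypes are
Bernoulli(`p_j`) with `p_j ~ Uniform[0.05, 0.5]` drawn once per cohort,
and each offspring inherits one uniformly chosen haplotype per parent,
independently across SNPs.  Mendelian transmission realizes the target
IBD distributions *exactly* — full sibs have `(k0,k1,k2) =
(0.25, 0.5, 0.25)` by construction, and the per-SNP genotype correlation
of every pair equals `2 phi` — so no correlated-binary generator is
needed.  Ground truth (`TrueKinship`) is computed from the pedigree by
the recursive tabular kinship algorithm, and `k2` for non-inbred pairs
from products of parental kinships; it is never inferred from the
realized genotypes.

What the generator deliberately does **not** model: linkage
disequilibrium, inbreeding loops, sex chromosomes, population structure
or admixture, genotyping error.  Passing tests therefore demonstrate the
estimators' behavior under the theory's own assumptions (LE, HWE,
homogeneity); on real data, LD and MAF-spectrum effects can dominate the
centering bias studied here (the real-cohort analyses in the literature
show scGRM biases an order of magnitude larger than the closed form
predicts under LE).

Two cohort designs are packaged:

* **Sib families** (`run_sib_family_experiment`): 200 unrelated families
  of 500 full siblings, 10,000 SNPs, analyzed per family with
  within-family centering and known variances.  The family-average scGRM
  kinship concentrates at `(rho_bar - 1)/(2n) = -5e-4` although every
  pair's true kinship is 0.25; UKin concentrates at 0.25.  The identity
  `rho_tilde_bar = 500 rho_hat_bar + 1` holds exactly per family.
* **Mixed cohort** (`run_mixed_cohort_experiment`): 4,000 individuals —
  500 pairs each at kinship 0.125 (half sibs), 0.25 (full sibs), 0.5
  (MZ), pairs mutually unrelated, plus 1,000 singletons — at 50,000
  SNPs.  Estimates are grouped over *all* pairs by true kinship; bias
  and SD are reported on the kinship scale and conventionally printed in
  units of 1e-3.  Kinship-0.125 pairs are realized as half sibs rather
  than avuncular pairs; both have `(0.5, 0.5, 0)` so estimators cannot
  tell the difference.  For MZ pairs UKin is exact by algebra (identical
  rows make the correction collapse to 1 on the correlation scale), so
  bias and SD are zero to floating point.

A case-control generator (`simulate_case_control`) adds
`N(0, 0.05^2)` perturbations to the case-group MAFs of a 5% subset of
risk SNPs, clamped to `[0.05, 0.95]`; it exists for association-style
downstream experiments and is not used by the kinship acceptance runs.

All randomness flows from one integer seed through
`numpy.random.Generator`; passing a `Generator` lets callers chain
experiments deterministically.

## REML heritability

`reml_h2` fits `y = mu*1 + g + e`, `g ~ N(0, sigma_g^2 G)`,
`e ~ N(0, sigma_e^2 I)` with `G = 2K` from any kinship matrix
(diagonal from the estimator's own `i = i'` formula; fixed at 1 for
KING, which defines no diagonal).  `G` is eigendecomposed once and the
restricted likelihood is profiled over `h2 in [0, 1]` on a 101-point
grid followed by bounded scalar refinement — deterministic and free of
starting-value issues for a single component.  The intercept is the only
fixed effect.  Negative eigenvalues (possible for moment-estimator GRMs)
are clipped at zero and counted; a GRM numerically proportional to the
identity is rejected as non-identifiable; n < 10 is refused.  The SE is
the inverse square root of the negative profile-likelihood curvature at
the optimum (finite differences, step 1e-4, pushed inside the boundary
when the estimate is at 0 or 1, in which case the fit is flagged).  The
95% CI is the normal interval `h2 ± 1.96 se`.

`coverage_experiment` repeats simulate → estimate → fit cycles and
reports bias, SD and CI coverage.  Two phenotype generators exist, and
the distinction matters:

* `causal_snps` — the study design: a random 1% (configurable) of SNPs
  receive i.i.d. Gaussian effects on standardized dosages scaled so the
  genetic variance is `h2`, residuals `N(0, 1-h2)`.  With few causal
  SNPs the realized genetic covariance fluctuates around `h2*G`, which
  inflates the spread of `h2` estimates beyond the model-based SE.
* `grm_normal` — phenotypes drawn exactly from
  `N(0, h2*G_true + (1-h2)*I)`.  This is the correctly specified case
  and the right regime for checking CI calibration; with the true-kinship
  GRM the empirical coverage of the normal CI is consistent with 95%.

## Numerical choices and problem sizes

* Estimator cores are single BLAS matrix products over float64
  standardized scores, blocked over SNPs where memory matters; KING
  counts are accumulated in float32 (exact below 2^24) block products.
* The packaged experiment defaults match the study designs above; the
  test suite runs the sib-family design at 50 families and the mixed
  cohort at its full 4,000 × 50,000 scale (a few minutes on one core),
  and the Monte-Carlo unbiasedness check at n = 36, m = 500 over 1,000
  replicates.  These sizes are the package's own trade-off between
  Monte-Carlo resolution and a test suite that stays pleasant to run.
* Degenerate inputs: SNPs with fewer than two non-missing genotypes are
  flagged and excluded; QC refuses to empty a cohort; pairs with no
  heterozygous sites in either member get NaN from KING and are listed
  in the result metadata rather than silently dropped.

## Known limitations

* The LE/HWE/homogeneity assumptions are baked into both the theory and
  the simulator; none of the admixture-aware or LD-weighted estimator
  variants are implemented.
* The minimum-variance two-step GRM (tsGRM) is not implemented — its
  weight-optimization step is specified only in sources not available
  here.
* Under `sample` variance mode the global mean constraints above mean
  UKin's unbiasedness is exact only relative to an external variance
  reference; this is a property of the estimator, not of the
  implementation.
* Heritability comparisons between kinship estimators on LE synthetic
  genotypes are dominated by small-sample REML effects rather than by
  the centering bias.  Concretely: on relative-rich LE cohorts the
  common REML bias (shared by the true-kinship GRM) is small and
  *negative*, while scGRM's underestimation of relatives' kinship adds
  a small positive h2 inflation that UKin removes.  Removing a positive
  component from a negative total moves the estimate *away* from the
  truth, so in this regime UKin's absolute h2 bias is not smaller than
  scGRM's — the paired-block ordering experiment in the test suite
  measures exactly this and is expected to reflect it.  The favorable
  ordering reported on real cohorts arises under positive baseline
  biases driven by features (LD, real MAF spectra, dense panels) that
  the LE simulator deliberately does not model.
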