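# Methods

## The liability-threshold model

A binary disorder is modelled as the indicator that a latent standard
normal "liability" exceeds a threshold τ; the population prevalence K
fixes τ = Φ⁻¹(1 − K). For a pair of relatives measured on two disorders
(X, Y), the liability vector (X₁, Y₁, X₂, Y₂) is multivariate normal with
unit variances and a correlation matrix assembled from variance
components:

- within individual, cross-trait: cov_A + cov_D + cov_C + cov_E;
- cross-relative, same trait *t*: κ_A a²_t + κ_D d²_t + κ_C c²_t;
- cross-relative, cross-trait: κ_A cov_A + κ_D cov_D + κ_C cov_C,

where (a², d², c², e²) are the trait's A/D/C/E variance fractions,
cov_• the cross-trait covariance carried by each component, and κ the
class sharing coefficients (full siblings .50/.25/1.00; maternal
half-siblings .25/0/1.00; paternal half-siblings .25/0/κ_C; cousins
.125/0/κ_C). Environmental sharing for paternal half-siblings and
cousins is not identified by the two-sister-class design, so their κ_C
defaults to 0 and is exposed as a parameter rather than asserted.

ACDE is not attempted: with full- and maternal-half-sibling classes only,
C and D are not jointly identified, so the model menu is ACE, ADE and AE,
compared by AIC = −2ℓ + 2k with ties broken toward fewer parameters.

## Estimation

**Tetrachoric correlations** are two-step maximum likelihood on a 2×2
pair table: thresholds from the margins, then the correlation maximising
the multinomial likelihood (bounded scalar optimisation on
[−.999, .999]; estimates at the bound are flagged as boundary cases).
Standard errors come from the profile-likelihood curvature. Fractional
counts are accepted so that tables reconstructed from published
concordant/discordant summaries are first-class inputs.

**Full model fits** maximise the multinomial log-likelihood of the 16
pair-contingency cells (or 4 cells univariately) per relative class,
summed over classes. Parameters are unconstrained transforms: per-trait
variance fractions via a softmax over the model's components, cross-trait
component correlations via tanh, thresholds direct. This keeps every
2×2 component matrix PSD, hence the 4×4 pair matrix PSD for any κ in
[0, 1], with no redundant scale directions (a normalized equivalent of a
Cholesky parameterisation of the component matrices). Optimisation is
L-BFGS-B with numeric gradients from moment-based starting values, with
optional seeded random restarts. Confidence intervals for derived
quantities (a², cov_A, r_g, coheritability) use the delta method on the
numeric observed-information matrix.

**Thresholds are estimated per relative class** (each class contributes
two per-trait thresholds, shared between the two pair members). This
matters in practice: in the reconstructed register tables the ADHD margin
is 1.90% among full-sister pairs but 4.64% among maternal half-sister
pairs, and forcing a single shared threshold distorts the implied
correlations (driving the ADHD heritability estimate to ~.90, outside the
published interval, versus ~.84 with per-class thresholds). A
`share_thresholds` flag restores the constrained variant.

**The AE correlation solution** (`solve_ae_from_correlations`) solves the
overdetermined linear AE system directly from tetrachoric correlations —
r_class = κ_A(class)·a², cross_class = κ_A(class)·cov_A, phenotypic =
cov_A + cov_E — by least squares weighted by pair counts. This is the
route used to reproduce published coheritability and genetic-correlation
values, because the exact 16-cell tables behind the published bivariate
fits are not published; it is exact when the inputs are mutually
consistent and degrades gracefully (negative implied components are
clipped and flagged) when they are not.

**Reconstruction assumptions.** Published pair summaries give
both-affected / both-unaffected / discordant counts; the orientation
split of the discordant pairs is not published, so reconstruction places
half in each off-diagonal cell. This symmetric split is an assumption,
not an estimate; it is also the maximum-entropy choice and is consistent
with the symmetrised pair likelihood (each unordered pair contributes the
average of both orderings, and the model matrix is exchangeable).

## Numerical integration

The likelihood kernel needs rectangle probabilities of a correlated
Gaussian in 2–4 dimensions, evaluated thousands of times inside the
optimiser, so the integrator is deterministic (quasi-Monte-Carlo noise
breaks quasi-Newton line searches). The bivariate CDF uses Genz's
Gauss–Legendre reduction (absolute error ~1e-14). Three- and
four-dimensional CDFs condition on the leading one or two variables and
integrate the exact conditional bivariate rectangle over Gauss–Legendre
nodes in z-space with the Gaussian weight folded in (tails truncated at
|z| = 8.5, mass < 1e-17); the conditioning partition is chosen to
maximise the smallest conditional variance so that near-singular
correlation structure is absorbed by the exact bivariate kernel, and a
node-doubling escalation engages when an a-priori smoothness score
signals a hard case. Typical accuracy is ~1e-8; randomized scipy QMC
integration and large Monte-Carlo samples serve as independent oracles in
the tests, never in the fitting path. Orthant probabilities for all 2^d
sign patterns are assembled from the 2^d CDF values by inclusion–
exclusion, so each table's cell probabilities sum to one by construction.

## Coaggregation regressions

Pairs enter double-entered (both orientations), so every individual
appears once as index and once as relative; logistic regression of the
relative's diagnosis on the index diagnosis adjusts for both members'
birth years (centred, continuous — a categorical-band option was
considered and rejected as immaterial at simulated scale) and sexes.
The sandwich variance is clustered on the family id, absorbing both the
double-entry dependence and familial clustering (statsmodels GLM;
singleton clusters recover the heteroskedasticity-robust estimator up to
the finite-sample factor n/(n−k)). Separation is flagged when fitted
probabilities converge to within 1e-8 of 0 or 1. The attenuation of ORs
with relatedness is an empirical outcome, estimated but never asserted by
the estimator.

## Polygenic scores

Summary statistics are QC-filtered (minor-allele frequency ≥ .05 and
INFO ≥ .80, both inclusive; strand-ambiguous A/T and C/G variants dropped
by default since their orientation is unresolvable from allele labels).
Greedy clumping keeps the smallest-p unclumped variant as index and
removes neighbours within 1000 kb with dosage r² > .1 in the reference
panel. Scores sum effect-size-weighted effect-allele dosages over
variants below a (strict) p-value threshold, reconciling alleles by
identity or strand complement, reversing dosages for swapped labels and
imputing missing dosages to 2 × effect-allele frequency; the standardized
copy has zero mean and unit variance in the target sample. Association
uses an independence-working-correlation GEE (point estimates equal OLS;
cluster-robust SEs over twin pairs), with ΔR² the difference in OLS R²
between the models with and without the score. Cronbach's alpha uses the
standardized (mean inter-item correlation) form by default.

## The synthetic-data generator

The generator defines the study conditions; it is deliberately simple
and fully specified:

- **Pedigrees** are independent families drawn from preset structures
  (full-sibling/sister pairs and trios, maternal and paternal half-pairs,
  cousin pairs through sister-parents, twin pairs). Children's sexes are
  Bernoulli(½) unless the structure forces female; birth years are
  uniform over 1970–2005 for register-like cohorts (1992–2005 for the
  twin-like genotyped sample). Relative classes are always re-derived
  from parent links, never read from generator labels.
- **Liabilities** are drawn family-block-wise from the exact joint normal
  implied by the architecture (Kronecker sum of component matrices with
  pairwise sharing coefficients), families independent, and thresholded
  at Φ⁻¹(1 − K).
- **Genotypes** are Hardy–Weinberg sums of two haplotypes whose
  indicators follow a thresholded latent Gaussian AR(1) within blocks;
  allele frequency is constant within a block (as for tightly linked real
  variants), and the latent step correlation is calibrated through the
  discretisation so the realised adjacent-dosage correlation equals the
  specified block value. The discovery GWAS is a disjoint sample from the
  same population; effect sizes, p-values, frequencies and simulated INFO
  scores populate the summary statistics, and the true per-individual
  genetic value is returned for recovery tests.
- **Symptom scales** (19 three-category ADHD items summed; 22
  six-category ED items averaged) discretise latent item scores that load
  on a common factor; the factor correlates with the genetic value at a
  specified effect, and the latent inter-item correlation is calibrated
  through the ordinal discretisation (via bivariate-normal cell
  probabilities) so the emitted items hit the scale's target Cronbach's
  alpha (.95 ADHD-like, .90 ED-like). Response-category probabilities are
  skewed to mimic general-population distributions (ADHD item mean ≈ .10;
  ED item mean ≈ 2.2).

What the generator does **not** emulate: recombination maps and realistic
genome-wide LD, assortative mating, X-linkage, ancestry stratification,
diagnostic misclassification, censoring by age, or missing-data
mechanisms of real questionnaires. Passing tests therefore demonstrate
the estimators' correctness and calibration under the stated model, not
robustness to those real-data complications.

## Problem sizes and verification

The test suite verifies parameter recovery at 100 replicates of 100,000
full-sister + 20,000 half-sister pairs with architecture a² = (.82, .45),
r_g = .37, prevalences (2.2%, 1%): mean absolute bias of a², cov_A and
r_g below .02 and 95%-CI coverage between 90 and 99 of 100. Null
calibration of the coaggregation CI uses 500 replicates of 900-family
cohorts; the OR relatedness ordering is checked on a single 60,000-family
mixed cohort with strong shared additive liability. Clumping is checked
against a brute-force oracle on 1,000 random 10-variant instances, and
the end-to-end PRS arm at published-magnitude effects (β ≈ .03–.05,
ΔR² ≈ .001–.003) over 30 seeded replicates. These sizes were chosen as
the smallest at which the Monte-Carlo error of each check is well below
the tolerance it asserts.

## Known limitations

- Published-value reproductions run through reconstructed tables or the
  printed correlation sets and are approximate by construction; the
  joint AE heritability lands at 83.6% against a published ~82% (within
  the published interval), reflecting the symmetric-discordance
  reconstruction and the unpublished covariate handling of the original
  fits.
- Delta-method CIs can be poor near parameter boundaries (e.g. d² → 0 in
  ADE); the AIC comparison is still valid there, but the D-component CI
  should not be interpreted.
- The tetrachoric SE ignores threshold-estimation uncertainty beyond the
  profile curvature; at register-scale counts this is negligible.
- `genotype_pcs` is a convenience SVD for simulated panels, not a
  validated ancestry-inference tool; PCs are consumed as covariates.
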