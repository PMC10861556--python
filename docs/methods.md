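# Methods

This note records the statistical model behind `wfmr`, the assumptions of
the synthetic-data generator, the numerical choices, and the limits of what
the test suite demonstrates.

## The within-family MR model

Let `G_m` and `G_c` be the mother's and child's dosage vectors over a panel
of birth-weight-associated SNPs, and `S_m`, `S_c` the standardized polygenic
scores built from them. The identifying assumption is that variants with
*maternal-specific* effects on offspring birth weight influence the child's
outcome only through the intrauterine environment — except that transmission
creates corr(S_m, S_c) = 1/2, opening a pleiotropy path through the child's
genome. The analysis model is the joint logistic regression

    logit P(D=1 | S_m, S_c, X) = α + β_m S_m + β_c S_c + γ'X

with covariates X (child age, genetic PCs, genotyping batch). Under a
purely fetal effect, the marginal (parent-only) maternal slope converges to
ρ β_c + O(β_c³) with ρ = 1/2 (small-effect approximation; the cubic
correction is negligible at the effect sizes considered), while the joint
β_m is consistent for 0. Under a purely maternal effect, adding S_c — which
is conditionally independent of the outcome given S_m — leaves β_m
unchanged; there is no non-collapsibility penalty because the added
regressor carries no outcome information. Both laws are verified by
simulation at 10⁶ pairs in the test suite.

The attenuation ratio β_m(joint)/β_m(parent-only) is reported as a
diagnostic. Because the two estimates come from nested models with no
standard test for their difference, an optional pair-resampling bootstrap
(default 1000 draws in the CLI, off in the library function where callers
may be running million-pair simulations) provides a percentile CI.

## Sibling design

Same-sex full-sibling pairs discordant for disease are compared with the
exact 1:1 matched conditional likelihood,
`Π expit(β (x_case − x_control))`. Shared terms — the mother's genotype and
hence any intrauterine effect, plus household environment to the extent it
is shared — cancel in the within-pair difference, so β estimates the fetal
effect alone. One pair per family is kept (chosen uniformly at random under
the run seed when several duos are eligible) to preserve independence
across pairs; the multiplicity rule is a package choice, as is keeping
tied pairs (difference 0), which contribute a constant ½ to the likelihood.
No covariates enter the conditional model by default: matching absorbs
family and sex.

## Synthetic cohort generator

The generator reproduces the statistical structure the estimators rely on,
stage by stage, each stage drawing from an independent stream derived from
the global seed (CRC-32 of the stage name mixed into a `SeedSequence`):

* **Panel.** Variant classes default to the 32:68:27:15:71 proportions
  (maternal-only : fetal-only : shared-concordant : shared-opposing :
  unclassified) of the lead-SNP birth-weight panel this design uses; MAFs
  are uniform on [0.05, 0.45]; per-allele weights are half-normal, oriented
  birth-weight-increasing through the defining genome, and rescaled so each
  weight column's additive variance Σ 2p(1−p)w² hits `effect_scale`.
* **Families.** Parents are Binomial(2, p) per locus (HWE, random mating;
  linkage equilibrium). Each child draws one allele per parent with
  P(effect allele) = dosage/2, independently across loci — giving the 0.5
  parent-offspring and full-sibling score correlations. An optional
  `parent_pgs_corr` knob emulates assortative mating by Gaussian-copula
  matching of spouses on their birth-weight genetic value.
* **Birth weight.** bw = mean_g + sd_g (√h2_m z(w_m'G_mother) +
  √h2_f z(w_f'G_child) + √(1−h2_m−h2_f) ε). Components are standardized
  empirically, so the regression slope of bw on the standardized maternal
  component is sd_g √h2_m by construction. Defaults h2_m = 0.02,
  h2_f = 0.05, 3500 ± 500 g: a lead-SNP panel explaining a few percent of
  variance, consistent with a ~40 g shift per SD of the maternal
  instrument. When maternal and fetal weights overlap on shared variants
  the two components correlate through transmission and the total variance
  exceeds 1 by 2√(h2_m h2_f)·corr; the per-component variance targets still
  hold.
* **Disease.** risk = expit(α + β_m S_m + β_c S_c) per child, case status
  Bernoulli(risk). The intercept is calibrated deterministically by Brent
  root-finding on E[risk] = prevalence with 128-node Gauss–Hermite
  quadrature over the normal linear predictor (variance β_m² + β_c² +
  2ρβ_mβ_c), so calibration consumes no randomness and is seed-independent.
  Under the `via_birthweight` mediation mode the maternal coefficient
  multiplies the child's standardized birth weight instead of S_m — a true
  DOHaD mechanism — and the intercept is calibrated on the realized
  empirical linear predictor.
* **Ages, sex, covariates.** Child ages are normal (46.3, 14.2) truncated
  at 18; parents add a truncated-normal generation gap. Sex is
  Bernoulli(½). "Principal components" are i.i.d. noise and the genotyping
  batch is a random factor: structural stand-ins that exercise the model
  interfaces without generating population structure.

What the generator deliberately omits: linkage disequilibrium, X-linked
transmission, imprinting, population stratification, age-dependent
incidence, and PGS measurement error relative to true intrauterine growth.
Passing tests therefore demonstrate the *statistical identification
machinery* — transmission conditioning, sibling cancellation, calibration,
power — not robustness to those real-data complications.

## Logistic fitting

`fit_logistic` is a dense IRLS/Newton solver: score-norm convergence at
‖U(β)‖₂ ≤ 1e-8, Wald SEs from the inverse observed information,
likelihood-monotone step-halving (tolerating rounding-level decreases),
QR-with-pivoting rank checks that name collinear columns, and explicit
separation detection (coefficient divergence beyond |β| > 40 on
standardized inputs raises rather than silently penalising). A Firth
bias-reduced mode (hat-diagonal-adjusted score) is available for small
strata where separation is expected. The fitter is cross-checked in tests
against statsmodels and an independent trust-region optimiser of the exact
likelihood to 1e-6. The conditional-logit solver is the corresponding 1-D
Newton iteration on within-pair differences, verified against brute-force
likelihood search and the symmetrised intercept-free logistic
representation.

Significance is two-sided Wald p < 0.05 throughout, with no
multiple-testing adjustment — the design's endpoints overlap and the
framework treats 0.05 as its working threshold.

## Power analysis

Each replicate: draw N bivariate-normal PGS pairs (ρ = 0.5) → calibrated
logistic risk → Bernoulli status → joint fit → Wald p-values. Power is the
rejection fraction; its Monte-Carlo SE is √(π(1−π)/reps). Replicate seeds
are spawned independently, so results are invariant to threading.
Degenerate draws (no cases) raise by default; optional resampling exists
for exploratory tiny-n runs but would bias power if silent, so it is off.

`min_detectable_or` scans the OR grid {1 + 0.01k} upward and returns the
first grid point whose estimated power reaches the target, reporting the
evaluated grid with MC SEs; at a boundary where true power sits near the
target, Monte-Carlo noise can move the crossing by one grid step, which is
why the bracketing points are exposed rather than treating the boundary as
exact. An analytic benchmark (`analytic_power`, expected Fisher information
by 2-D Gauss–Hermite quadrature) agrees with simulation to < 0.03 and is
used as an independent oracle in tests.

Default problem sizes: 1000 replicates per setting in library defaults, the
type-I-error tests and the reproduction script, and 600 per grid point in
the slowest boundary tests — sizes chosen so Monte-Carlo error is well
inside the quantities' tolerances.

## Known limitations

* Kinship filtering (`max_4th_degree`) exploits the generator's known
  family structure; real cohorts need external relationship inference.
* Allele harmonization, liftover and PLINK formats are out of scope; panels
  are assumed pre-oriented to birth-weight-increasing effect alleles, and
  VCF input is matched on variant ID for biallelic SNVs only.
* The power analysis fixes the PGS-pair correlation at 0.5 and ignores how
  much birth-weight variance the PGS explains, so boundaries are on the
  OR-per-SD-of-PGS scale, not a clinical birth-weight scale.
* Within-variant missing genotypes are mean-imputed (logged); this is a
  package choice where the upstream convention is unstated.
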