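# Methods

## The model

`splitbrood` analyses a half-sib split-brood breeding design: sires each
mated to several unrelated dams, with the offspring of every brood split
among developmental environments (for the leaf-footed cactus bug
*Narnia femorata*: cactus with ripe fruit, unripe fruit, or no fruit,
assigned at the 4th instar). A trait measured across the three diets is
treated as three genetically correlated *character states*. For one
trait the model is

    y = 1 mu + X1 tau + X2 beta + Z (a x tau) + e

where `tau` is the fixed diet effect, `beta` the fixed dissector-block
effect, `a x tau ~ MVN(0, A (x) G)` the vector of environment-specific
additive genetic effects (A the pedigree numerator relationship matrix,
G the unstructured m x m genetic covariance across environments), and
`e ~ MVN(0, sigma2 I)`. Each individual is phenotyped in exactly one
environment, so the marginal covariance of the records is assembled
directly as `V = A_obs o (U G U') + sigma2 I` (`o` elementwise, `U` the
environment incidence); no Kronecker product is ever materialised.
Families are mutually unrelated, so `A_obs` — and hence `V` — is block
diagonal by sire family, and every O(n^3) factorisation is done per
family block; only the small fixed-effect system couples blocks.

Downstream summaries per environment *i*:

* heritability `h2_i = s2_ai / (s2_ai + sigma2)`, with a delta-method SE
  from the asymptotic covariance of the components (inverse
  average-information matrix at the optimum);
* evolvability `I_A = V_A / mean^2` and the coefficient of additive
  genetic variance. Two CV_A variants are always reported:
  `cva_stated = sqrt(V_A)/mean` (the standard definition; `I_A =
  cva_stated^2` identically, and both are invariant to trait rescaling)
  and `cva_printed = V_A/mean`, the variant that published per-diet
  tables for this system actually contain (it scales with the trait and
  breaks the squared identity — the package keeps both side by side and
  the rendered report footnotes the discrepancy);
* cross-environment genetic correlations `r_ij = g_ij / sqrt(g_ii g_jj)`,
  reported missing when a variance sits at its boundary.

Phenotypic variance is defined as `V_A + sigma2` (fixed effects
excluded) — the definition consistent with the published h2 cells.
Trait means are raw (untransformed) per-environment means; the animal
model is likewise fitted on untransformed data, while the
trait-expression stage (below) works on natural logs.

## REML estimation

The restricted log-likelihood, with the constant retained so values are
comparable across software, is

    l_R = -1/2 [ (n-p) log 2pi + log|V| + log|X' V^-1 X| + y' P y ]

with `P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1` and `p = rank(X)`.
The response is standardised internally by its sample SD so that every
tolerance is scale-free; all outputs are transformed back.

Maximisation proceeds in two phases:

1. **EM warm start** (default 20 iterations, fewer if it converges
   sooner). The exact EM updates are
   `G <- G + G (Q - R) G / n` and
   `sigma2 <- sigma2 + sigma2^2 (y'PPy - tr P)/n`,
   where `Q_kl = v_k' A v_l`, `R_kl = tr(P (A o u_k u_l'))`, and
   `v_k` is the environment-k slice of `Py`. EM steps can never decrease
   `l_R`; the test suite asserts this per iteration.
2. **Quasi-Newton refinement**: L-BFGS-B over the lower-triangular
   Cholesky factor of G and `log sigma2`, with exact analytic gradients
   mapped through the factor Jacobian. The factor parameterisation
   keeps every iterate PSD and turns boundary optima (a variance at
   zero, a genetic correlation pinned at +/-1) into ordinary stationary
   points. Average-information (AI) *steps* are deliberately not used
   for the optimisation: near the PSD boundary the AI matrix acquires a
   near-null direction and its Newton direction collapses to
   micro-steps (observed as 500-iteration creep at ~1e-7 ll units per
   iteration). The AI matrix is instead computed once at the optimum,
   where it is the standard curvature estimate, and inverted for
   `vcov_components`.

**Convergence.** Declared when the factor-space projected gradient
(KKT measure; variance floors handled by zeroing descent components)
has max-norm below `grad_tol` (default 1e-4), *or* when a restart — two
EM steps followed by a fresh quasi-Newton run — improves `l_R` by less
than `ll_tol` (default 1e-8). The second clause is needed because at
n ~ 10^3 the likelihood's float64 noise floor can leave a gradient norm
of ~1e-3 at a point that a derivative-free audit confirms is the
optimum to ~1e-11 ll units. Non-convergence raises (default) or warns,
carrying the full ll trajectory.

**Constraints.** Default `constrain="psd"`: G is kept PSD, genetic
variances floored at 1e-10 x var(y) (estimates at the floor are flagged
and printed as 0.0), the residual at 1e-8 x var(y). The alternative
`constrain="none"` reproduces the behaviour of classic unstructured
(`us`) REML fits in animal-breeding software, where G may become
indefinite. The choice matters for simulation studies of estimator
bias: the PSD-constrained estimator of a near-zero variance component
is upward-biased (truncation at the boundary; measured bias ~ +2.8 on a
true value of 1.0 at the default design scale), whereas the
unconstrained estimator is mean-unbiased in the same experiment. The
parameter-recovery checks therefore use `constrain="none"`; reported
data analyses use the PSD default.

**Inference on fixed effects.** Approximate F-tests per factor: Wald
statistic on the treatment-coded coefficients divided by the contrast
count, with denominator df `n - rank(X)` — a deliberately simple,
documented choice (software-specific approximations such as
Kenward-Roger are out of scope). Adjusted environment means are
estimable functions with blocks averaged at equal weight, so they do
not depend on the coding reference level. BLUPs of all three
environment-specific breeding values are reported for every pedigree
individual (including unphenotyped parents) via `u_hat = (G (x) A) Z' P y`.

## Pedigree and kinship

`A` is built dense by the recursive tabular method
(`A_ii = 1 + A_{s,d}/2`, `A_ij = (A_{j,s(i)} + A_{j,d(i)})/2`), with
unknown parents treated as unrelated non-inbred founders — the natural
convention for a field-collected colony. Designs of ~10^3 individuals
never need sparse inverse-A machinery. Validation: duplicate ids,
cycles, and undefined parents are errors (undefined parents optionally
auto-inserted as founders). The test suite checks A entrywise (exactly,
tolerance zero) against an independent recursive-coancestry oracle on
random pedigrees up to 200 individuals, including inbred ones.

## Synthetic data

The generator reproduces the study design: 35 sire families x 3 dams,
~10 offspring per dam, offspring assigned to diets individually
(split-brood) with weights proportional to the published per-family
medians 11/6/14 — giving ~1050 phenotyped males, matching the study's
1039 — plus a small probability (default 0.01) that a whole
sire x environment cell is empty, mirroring the reported unbalance.
Founder breeding-value vectors are drawn from MVN(0, G); offspring get
the parental average plus Mendelian sampling MVN(0, G/2) (exact for
non-inbred parents, which this design guarantees). Phenotype:
environment mean + dissector-block effect + own-environment breeding
value + N(0, sigma2) residual. Three dissectors with small fixed
offsets are the default (the study does not report its dissector
count or effects). Everything is driven by one explicit seed.

Default trait parameter sets mirror the published per-diet magnitudes
(body mass: V_A 36.53/0.97/1.51, V_P ripe 90.68, means
23.51/12.96/12.29 mg; femur area and testis mass analogous) with a
common residual matched to the ripe-diet phenotypic variance and a
cross-environment genetic correlation of 0.5 (the study reports no
correlation estimates; 0.5 is a moderate, realistic choice). Two
deliberate departures: testis-mass variances are rescaled to be
compatible with the milligram means (the published variance scale is
not; heritabilities are preserved), and the pipeline's synthetic mode
redraws the residual of any non-positive phenotype so the log-scale
stage is well defined (a slight lower-tail truncation; parameter
recovery simulations run without it).

What the generator does **not** emulate: between-trait genetic and
residual correlations (each trait is simulated and fitted separately,
as in the study), skewness and heteroscedasticity of real growth data,
environment-specific residual variances (the model has one sigma2, so
the generator does too), and maternal or common-environment effects.
Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness
to their violation.

## Trait expression and allometry

Each trait is natural-log transformed (non-positive values are a
loud error), compared across diets by one-way ANOVA with Tukey(-Kramer)
HSD at alpha = 0.05 (studentized-range tail probabilities from scipy;
unbalanced groups use the Kramer adjustment), and summarised with a
compact letter display (insert-and-absorb). The three allometry
ANCOVAs (femur ~ body, testis ~ body, testis ~ femur, each with diet)
first fit the full interaction model; the diet x covariate interaction
is retained only when its type-II p-value is <= 0.20, otherwise the
common-slope model is reported — the screening rule used in the study.
Adjusted means are evaluated at the grand covariate mean and compared
pairwise with a Tukey-style studentized-range test on their estimated
differences (the exact Tukey variant used by the original point-and-
click software is unknowable; this choice is documented, not asserted
as theirs). Type-II sums of squares are used for main effects when the
interaction is dropped. The one-way F is identical to the
full-versus-null regression F (asserted to 1e-10 in tests).

## Problem sizes and determinism

Default problem sizes used by the test suite and the acceptance script:
study scale (~1050 individuals) for single fits and the end-to-end
pipeline; 100 replicates at study scale for parameter recovery;
500 small-design (n = 180) REML fits for the Wald type-I calibration
and 1000 draws for the ANOVA one; oracle comparisons at n <= 50 where
brute-force dense evaluation is exact. A study-scale fit takes well
under a second on one core thanks to the family-block factorisation.
All randomness flows from explicit integer seeds; repeated pipeline
runs at a fixed seed are byte-identical (floats are written with
shortest round-trip `repr`-equivalent precision, no timestamps in
outputs, config hash excludes the output path).

## Known limitations

* Single residual variance across environments; the published per-diet
  V_P differences suggest the original analysis may have allowed more
  (the printed table is internally consistent with per-diet residuals),
  but the stated model has one sigma2 and this package follows it.
* Denominator df for the approximate F-test is `n - rank(X)`;
  p-values for small designs are approximate (calibration at the
  default design is ~5.7% empirical at nominal 5%).
* `vcov_components` (hence SE(h2)) is an asymptotic quantity; at
  boundary estimates the AI matrix is singular and a pseudo-inverse is
  used, with SEs reported as 0 for floored components.
* Dense A limits practical pedigrees to a few thousand individuals.
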