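# Methods

## The exposure model

The quantity modelled is the *standard AUC*, y = AUC₀₋₁₂ / dose (ng·hr/ml
per mg/day), the exposure a patient extracts per milligram of daily dose.
The regression is

y = exp(b₀ + Σᵢ bᵢxᵢ)

with 13 candidate covariates: two indicator variables per locus for six
loci — wild (0,0), heterozygous (1,0), homozygous variant (0,1) — and the
daily dose in mg/day, untransformed, as the thirteenth.  Fitting minimizes
the squared error between ln y and the linear predictor (ordinary least
squares on the log scale), with exactly k = 8 of the 13 candidates in the
final model.

The two-indicator coding deserves a note: it estimates separate effects for
heterozygous and homozygous-variant carriage with no additivity constraint,
so dominant, recessive, and additive allele action are all representable.
The cost is two degrees of freedom per locus, which is why subset selection
matters at n = 44.

### Subset selection

Which 8 of the 13 candidates enter the model is not identified a priori, so
selection is part of the estimator:

- **forward** (default): start empty; at each step add the candidate that
  most reduces the leave-one-out (LOO) mean squared error of the
  log-scale OLS fit, computed by the hat-matrix identity
  e₍loo₎ = e/(1−h).  Ties break to the lower column index.  Greedy search
  can stall: on noiseless synthetic cohorts it recovers the planted
  8-column support in roughly 19 of 20 seeds, picking a correlated proxy
  column in the remainder.
- **exhaustive**: score all C(13,8) = 1287 subsets by the same LOO
  criterion.  At n = 44 this costs well under a second and recovers the
  planted support whenever it is identifiable in the realized design.
- an explicit index list forces the subset (used for calibration studies
  where selection noise is not the question).

Leverage-one observations (h = 1) make the LOO error of their own point
indeterminate (0/0); such points are dropped from the PRESS mean.  Without
this safeguard any subset containing a uniquely parameterized genotype
pattern would be discarded wholesale, which systematically excludes the
true support on small cohorts.

Constant columns (e.g. the dose column when every patient takes 10 mg/day)
are never selectable, since they are collinear with the intercept.

### Quartile stratification and dose advice

*Calculated AUC* = predicted standard AUC × dose.  The 25th and 75th
percentiles of the **training** cohort's calculated AUC (linear
interpolation between order statistics, the numpy default convention) are
frozen into the fitted model; they are never recomputed at prediction
time, matching prospective use.  A new patient's calculated AUC at or
below Q1 is "low" (consider a higher starting dose — response is
exposure-linked), at or above Q3 is "high" (consider a lower dose —
toxicity is exposure-linked), otherwise "mid" (maintain).  Both boundaries
are inclusive.  The advice is categorical; no mapping to milligrams is
implied.

Model fit diagnostics report R² on the log scale (the scale of the loss)
and on the AUC scale (the scale a calibration plot shows); the two can
differ materially because the exponential back-transform stretches the
upper tail.

## Non-compartmental analysis

AUC₀₋₁₂ is the linear trapezoid over the observed samples.  The log-linear
trapezoid is deliberately not used: with a pre-dose sample at steady state
the profile is non-monotone and the linear rule is the conventional,
assumption-free choice.  Clearance is dose/AUC with the dose per 12-hr
interval (daily dose / 2, twice-daily dosing) by default — the AUC spans
one interval — with the full daily dose available as an option since
published summaries rarely state which basis was used; the basis changes
clearance by exactly a factor of 2 and nothing else.  Unit arithmetic:
mg → ng (×10⁶), then ng/(ng·hr/ml) = ml/hr → L/hr (÷10³); 5 mg over
100 ng·hr/ml gives 50 L/hr.

Profiles with fewer than 3 samples, no t = 0 sample, or zero AUC are marked
non-evaluable rather than discarded or imputed, mirroring how clinical
tables carry "not evaluated" rows.  Negative concentrations are an input
error, never clipped.  The trough is defined as the 12-hr (end-of-interval)
sample; the pre-dose C-0hr is reported separately since the two need not
agree in real data.

## The synthetic cohort

The generator emulates the statistical structure the pipeline assumes, with
the planted regression as the single source of truth:

1. **Genotypes**: per-locus Hardy–Weinberg draws, P(wild, hetero, variant)
   = ((1−q)², 2q(1−q), q²).  Default variant-allele frequencies 0.2–0.4.
2. **Exposure**: ln(standard AUC) = b₀ + Σ locus effects + (dose effect ×
   dose) + ε, ε ~ N(0, σ).  Defaults: b₀ = ln 15 (so a 10 mg/day all-wild
   patient has AUC ≈ 150 ng·hr/ml, a typical clinical magnitude),
   locus effects 0.15–0.70 on the log scale (variant carriage at
   metabolism/efflux loci raises exposure), residual σ = 0.5, no dose
   effect.  Under these defaults the realized exposure spread across a
   60-patient cohort is roughly 20–50-fold; pushing toward the ~100-fold
   spread seen clinically would also need dose heterogeneity, which the
   default single-dose policy (point mass at 10 mg/day) intentionally
   omits so that dose is cleanly separable in recovery studies.
3. **Profiles**: the steady-state one-compartment oral-absorption curve
   over the τ = 12 hr interval,
   C(t) = A·[e^(−kₑt)/(1−e^(−kₑτ)) − e^(−kₐt)/(1−e^(−kₐτ))],
   whose exact interval integral is A·(1/kₑ − 1/kₐ); A is scaled so that
   integral equals the patient's true AUC.  kₐ ~ U(0.3, 2.0)/hr,
   kₑ ~ U(0.05, 0.5)/hr, resampled while |kₐ−kₑ| < 10⁻³ (the superposition
   is singular at kₐ = kₑ).  Observed concentrations multiply the curve by
   independent mean-one lognormal noise with configurable CV (default
   0.1).  A consequence of exact steady state: C(0) = C(12) on the
   noiseless curve, so pre-dose and trough samples only differ through
   measurement noise — real data disagree for additional reasons
   (adherence, circadian kinetics) the generator does not model.
4. **Outcomes**: responder status (CR/PR), grade ≥ 2 hand-foot syndrome
   and grade-2 hypothyroidism are Bernoulli draws from logistic links in
   ln(actual AUC); hypertension grade is drawn independently of exposure
   (it is the designated negative control).  Link intercepts are
   calibrated to plausible event rates (~27% response, ~20% HFS, ~75%
   hypothyroidism) at a median exposure of ~150 ng·hr/ml; within-category
   splits (CR vs PR; SD/PD/NE; HFS grade 2 vs 3) use fixed conditional
   probabilities so the tabulation layer can be exercised end to end.

One master seed feeds deterministic per-operation sub-streams
(`numpy.random.SeedSequence.spawn`), so every artifact is bit-reproducible
and adding patients to one stage does not perturb another.

### What passing tests do and do not show

The generator's world is the model's world: one compartment, exact steady
state, lognormal noise, Hardy–Weinberg genotypes, no covariates beyond the
panel and dose.  Recovery results therefore demonstrate the *pipeline* is
correct and calibrated — not that six polymorphisms explain real axitinib
exposure, which also reflects age, body weight, smoking, drug–drug
interactions, and adherence.

## Numerical properties of sparse-sampling NCA

The 7-point trapezoid on the steady-state curve family carries a
deterministic quadrature bias depending on (kₐ, kₑ): at most ~2.5% in
relative terms across the supported ranges (measured against the analytic
interval integral; the test suite asserts a conservative 15% envelope).
Composite-trapezoid error scales as k²h²/12, so a 0.1-hr grid still leaves
~10⁻³ relative error at kₐ = 2/hr, and a 5×10⁻⁴-hr grid ~10⁻⁷; the
noiseless recovery check uses the latter so quadrature does not mask
regression error at the 10⁻⁶ level.  Because the bias is common to all
patients to first order, it loads on the fitted intercept and largely
cancels from genotype contrasts — which is why calibration studies of the
slope coefficients are run at the sparse grid while intercept-sensitive
checks use the dense one.

## Statistical tests

Two-sided p-values throughout.  Kruskal–Wallis and Mann–Whitney use the
tie-corrected scipy implementations behind this package's validation and
degenerate-case handling (all-equal data → statistic 0, p = 1; identical
multisets → p = 1).  The Mann–Whitney U convention is U = #{(a,b): a < b}
+ half-ties, so a stochastically smaller first sample yields a large U;
the mirrored statistic is n₁n₂ − U.

The Cochran–Armitage trend test is implemented directly as the score test:
T = Σ wₖ r₁ₖ centred at its hypergeometric expectation and standardized by
the exact permutation variance n₁n₂/(N(N−1)) · Σᵢ(sᵢ−s̄)², with default
scores (0, 1, 2) — the variant-allele count.  The statistic lives on a
lattice, so its normal p is validated against a *mid-p* permutation oracle
(atom at the observed value counted half); measured agreement is within
0.06 at genotype-cell counts of 5–20 and improves with n.  The plain
permutation p is systematically larger at coarse lattices and is the
honest choice for tiny tables.

The trend scan dichotomizes exposure at the median by default (the
quantile is configurable), builds one 2×3 table per variant, and ranks by
raw p; a Bonferroni column is provided but no adjustment is applied by
default.  Empirical type-I error of all four tests at α = 0.05 sits inside
the binomial 99% band over 5,000 null replicates at the simulation sizes
used in the acceptance suite (3×25, 20+20, n = 30, n = 80); the
Kruskal–Wallis chi-square approximation is measurably conservative below
~15 per group.

## Tabulation conventions

Percentages are always recomputed from counts against the full cohort n
(including non-evaluable patients) and rounded half-up to one decimal —
banker's rounding would differ on exact .x5 values such as 1/16 = 6.25%.
Objective response rate is the CR + PR count over the same denominator.

## Design choices made where the design was open

- The identity of the 8 selected covariates is treated as an output of
  selection, not an input; the package never claims a particular published
  subset or coefficient set, which is unrecoverable from text sources.
- Genotype categories (not allele pairs) are the canonical representation;
  at the triallelic ABCB1 2677G>T/A site any two non-reference alleles
  (including T/A compound heterozygotes, VCF GT 1/2) count as
  homozygous-variant, since the three-way coding admits no finer split.
- The dose basis for clearance (interval vs daily) and the trough
  definition are explicit configuration, as published PK tables rarely pin
  them down.
- Quartiles freeze at training time; percentile convention is linear
  interpolation; category boundaries are inclusive on both sides.
- Problem sizes in the validation suites (50 stochastic cohorts, 5,000
  null replicates, 100 scan runs over 500 variants, 1,000 null scans at
  n = 200) were chosen once as the smallest sizes at which the binomial /
  KS bands being asserted are informative.

## Known limitations

- One-compartment, first-order, exact-steady-state kinetics only; no
  lag time, no nonlinear absorption, no accumulation transients.
- The exposure model is log-linear with independent loci; no epistasis,
  no covariates beyond the panel and dose.
- Forward selection is greedy and can return a non-optimal subset;
  exhaustive search is the fallback at this problem size.
- The trend scan assumes complete genotype data for scanned variants and
  performs no covariate adjustment or genomic-inflation control.
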