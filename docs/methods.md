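# Methods

## Model

The SPAM is a trait-state covariance-structure model for two constructs
(X, Y) each measured at two occasions.  A latent trait loads on the general
level of each construct (loadings a1 = a and a2 = s·a with s = ±1 fixed by
the sign of the association between the constructs); the general levels load
equally on their two occasion measurements (b for X1/X2, c for Y1/Y2); and
an occasion-specific state factor adds covariance d between X and Y measured
at the same occasion.  With all observed variables standardized the implied
correlation structure is

    r_x1x2 = b²,  r_y1y2 = c²,
    r_x1y2 = r_x2y1 = s·a²·b·c          (cross-lagged)
    r_x1y1 = r_x2y2 = s·a²·b·c + d      (concurrent)

The model contains no directed path between the constructs, yet implies
nonzero adjusted cross-lagged regression effects whenever a, b, c > 0,
because adjusting for the earlier outcome conditions on a variable
correlated with the predictor's trait component (regression to the mean).

Assumptions: multivariate normality; equal loadings across occasions; equal
trait-loading magnitudes for the two constructs; a single state covariance
common to both occasions; two waves only.

## Closed-form effects

The four diagnostic effects are plug-in functions of the six correlations:
the adjusted effects come from the two-predictor normal equations; the
change-score effects divide the covariance difference by the standard
deviation of the difference of *standardized* components, `sqrt(2(1-r))`
per construct.  The square root is required for the coefficients to be
standardized (they must equal the least-squares coefficients on z-scored
data), and the package's central identity test enforces exactly that:
on data generated with exactly the target correlations, every closed form
agrees with the corresponding least-squares coefficient to 1e-8.

Sign-pattern classification uses a zero band ε (default 0.02 on the
standardized scale; no canonical value exists, 0.02 is roughly the
sampling error of a correlation at n ≈ 2,500).  Verdicts: a true
increasing effect predicts (+, −, +, +) for (lagged-forward,
lagged-reversed, change, change-on-change); a true decreasing effect the
mirror image; spuriousness predicts the lagged pair to share a sign with
the change effect zero or opposed and the change-on-change effect zero or
opposed to the change effect.  Everything else is inconclusive.

Note the sign structure of the lagged pair is *not* a theorem for every
admissible parameter vector: a state covariance large relative to a²bc can
flip the adjusted effects.  It holds throughout the empirically fitted
region (all five built-in construct pairs, both directions), which is what
the sign-structure tests assert.

## Maximum-likelihood fit

`fit_spam` minimizes the normal-theory discrepancy
F = ln|Σ| − ln|S| + tr(SΣ⁻¹) − 4 and reports χ² = (N−1)·F at the minimum.
By default the four indicator residual variances are free during
optimization — the convention of SEM software, which this package matches
so that its χ² values are comparable with published SEM fits.  On
standardized input the variance parameters absorb no correlation-structure
information (they matter only when the two cross-lagged or the two
concurrent sample correlations differ, where rescaling indicators can
absorb part of the asymmetry), so reported degrees of freedom count the
structural parameters only: df = 10 moments − 4 parameters = 6.  The
baseline model is independence (Σ = I), F_b = −ln|S|, df_b = 6, and
CFI/TLI/RMSEA follow their standard definitions with these df; TLI is
stored uncapped and reported capped into [0, 1].  A
`residual_variances="unit"` mode pins the diagonal at 1 (the strictly
4-parameter fit); parameter estimates are virtually identical, the
discrepancy is larger when the sample violates the pairwise equality
constraints.

Optimization: Nelder-Mead within bounds (a, b, c ∈ (1e-6, 1−1e-6), d in
(−1, 1), variances in (0.05, 20)), started from closed-form
method-of-moments values (b = √r_x1x2, c = √r_y1y2,
a = √(mean |cross| / bc), d = mean concurrent − mean cross-lagged), with a
restart polish; convergence to ~1e-14 in F.  When the sample *is* a SPAM
implied matrix the moment start is already the global minimum and is
returned directly, which makes self-fit recovery exact.  Non-convergence is
flagged on the result, never silent.  The (N−1) multiplier follows the
Wishart convention; at N = 10,000 the difference from N·F is far below
reporting precision.

## Simulation

Exact mode centers an iid normal draw, whitens it with the inverse Cholesky
factor of its own sample covariance and recolors with the Cholesky factor
of the target, so sample correlations equal the target to machine
precision for any n > 4.  This makes the evaluation pipeline deterministic
given its input, which is why it is the default (and why fitted statistics
are reproducible at full precision).  Stochastic mode draws rows
independently.  All randomness flows through one seeded generator per call.

## Meta-analysis

Per-study correlations and effects are pooled on the Fisher-z scale with
sampling variance 1/(n−3).  **Caveat**: 1/(n−3) is the correlation
convention; applying it to the transformed standardized regression effects
treats them like correlations.  They are bounded functions of correlations
and of similar scale, but their exact sampling variance differs; pooled
effect rows should be read with that approximation in mind.  τ² is
estimated by REML (default; profiled restricted likelihood, bounded scalar
optimization) or DerSimonian–Laird; Cochran's Q uses fixed-effect weights;
I² = max(0, (Q − df)/Q)·100 with a Q-profile confidence interval mapped to
the I² scale through the typical within-study variance.  The CI multiplier
is 1.96.

The synthetic multi-study generator perturbs a population SPAM's implied
correlations on the z scale by N(0, τ_z) per entry, repairs invalid
matrices by eigenvalue clipping (1e-8) plus unit-diagonal renormalization
(fixture generation only, never user data), then records sample
correlations of a stochastic draw with n ~ Uniform(150, 800) — the scale of
the individual panel studies behind the pooled tables.  Default τ_z = 0.1
matches the substantial heterogeneity (I² mostly above 60%) those pooled
tables report.  A missing pattern blanks all entries involving Y2 to
emulate studies without a second measurement of Y (2 of 10 studies in the
loneliness/social-anxiety literature), which reproduces the K = 10 / K = 8
split across pooled rows.  The generator emulates between-study
heterogeneity and missingness but not non-normality, measurement-model
differences between instruments, or correlated sampling errors within
studies — passing recovery tests therefore validates the estimators under
the random-effects model, not robustness to those violations.

## Evaluation pipeline

`spam_evaluation` runs: input correlations → exact N = 10,000 simulation →
SPAM fit → simulation from the fitted implied correlations → least-squares
estimation of the four effects in both directions → comparison (deltas) of
predicted versus input-implied effects and sign classification.  N = 10,000
with exact generation is the default so reports are byte-reproducible;
stochastic mode is available behind a flag.  `analyze_two_wave` applies the
same machinery to raw data, adding conventional OLS 95% confidence
intervals on the standardized scale (all variables, including change
scores, are z-scored before the interval fit so point estimates coincide
with the closed forms).

## Known limitations

* Two waves, two constructs, equal loadings across occasions only.
* No standard errors for SPAM parameters; no RMSEA confidence interval.
* The SPAM is observationally equivalent to variants replacing the trait
  with a directed cross-sectional path; fit cannot distinguish them.
* χ² at N = 10,000 is extremely sensitive to third-decimal rounding of
  input correlations (it scales with the squared gap between the paired
  cross-lagged and concurrent entries), so χ² computed from 2-decimal
  published inputs can differ by several units from values computed on the
  unrounded originals.  Parameter estimates are first-order in the inputs
  and unaffected at reporting precision.
* Problem sizes in the test suite (n = 2,000 for the oracle-equivalence
  battery, k ≤ 30 studies, 50 meta-analysis replicates) were chosen to keep
  the suite fast while leaving Monte-Carlo error well below the asserted
  tolerances.
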