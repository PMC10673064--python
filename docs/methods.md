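# Methods

This note records the statistical procedures `survrank` implements, the
conventions and tolerances it adopts where more than one defensible choice
exists, and what its synthetic-data tests do and do not demonstrate.

## Data model

A cohort is one row per subject: follow-up time in months (positive),
an event indicator (1 = death observed, 0 = right-censored), and named
covariates. Every analyzed factor is binary with 1 = the unfavorable level
(positive margin, infiltrated nodes, elevated CRP, ASA grade 2–3,
right-sided primary, multiple metastases, large metastasis, low albumin,
high fibrinogen), so positive Cox coefficients always mean worse survival.
Continuous markers are binarized either at a laboratory reference cutpoint
(`threshold_ge` / `threshold_le`, e.g. CRP ≥ 6 mg/L, albumin ≤ 38 g/L) or
at the sample median when no reference range exists (metastasis size); with
even n the median is the mean of the two central order statistics, and
values equal to the cutpoint take the "≥" side. Missing covariate values
are an error, never imputed. Cohort-summary percentages are rounded
half-away-from-zero to one decimal, the convention of clinical "N (%)"
tables.

## Kaplan–Meier and log-rank

The product-limit estimator uses the standard conventions: S is
right-continuous (the value at an event time is the post-jump value), and
when events and censorings share a time the events are counted first, the
censored subjects leaving the risk set afterwards. Median survival is the
smallest t with Ŝ(t) ≤ 0.5; its 95% interval inverts the Brookmeyer–Crowley
test statistic on the log(−log) scale with Greenwood variance, the default
of the major statistics packages. A curve that never reaches 0.5 yields a
flagged undefined median, not an error.

The two-sample log-rank statistic is (Σ(O−E))²/ΣV with the hypergeometric
mean and variance at each distinct event time, referred to χ²(1). With no
events the statistic is undefined and the result flagged. Weighted variants
(Wilcoxon, Tarone–Ware) and stratification are out of scope.

## The integral IS

IS = ∫₀^tmax [M(t) − m(t)] dt with M the favorable-level curve. Both curves
are step functions, so the integral is computed as an exact signed
rectangle sum over the union of their step points — no quadrature error;
tests verify agreement with adaptive quadrature to 1e-9. The differences
are **signed**: where the curves cross, areas of opposite sign cancel, so a
factor with inconsistent (crossing) separation scores lower than one with
the same unsigned area and clean separation. A detected sign change is
additionally reported as `crossing_detected`.

`tmax` defaults to the smaller of the two groups' last observed follow-up
times, so neither step function is extrapolated beyond its support; an
explicit override is accepted for sensitivity analysis, with extrapolation
(last value carried forward) flagged. IS has the units of months and
satisfies |IS| ≤ tmax; no variance or CI is attached — it is a descriptive
ranking quantity.

## Cox proportional hazards

The partial likelihood is maximized by Newton–Raphson from b = 0 with
step-halving (the log-likelihood never decreases between iterations);
convergence when the log-likelihood changes by < 1e-9 or the gradient
max-norm falls below 1e-8, with at most 50 iterations. Tied event times use
the Breslow approximation by default — matching the default of the
SPSS-style tooling this pipeline mirrors — with Efron's correction
available by flag; the two agree exactly on untied data. Gradient and
Hessian are analytic and are verified against central differences.

Inference is Wald: se from the inverse observed information, z = b/se,
two-sided normal p, CI = exp(b ∓ 1.96·se). No regularization and no
stepwise selection: the multivariate model enters all factors at once.
Monotone likelihood (separation) and singular information are surfaced as
flagged fits with a diagnostic message, never silent output. The
proportional-hazards assumption itself is not formally tested; curves are
exposed for visual assessment.

Two cross-module identities anchor correctness: for a single binary factor
the score (gradient) at b = 0 equals the log-rank O − E in all cases, and
the full score test g²/I equals the log-rank chi-square exactly when event
times are distinct. With ties the hypergeometric log-rank variance carries
a (n−d)/(n−1) multiplicity correction that the Breslow information lacks,
so the second identity is checked (to 1e-8) on untied data.

## Rank aggregation

Ranks R1a (log-rank chi-square, descending), R1b (IS, descending), R2a and
R2b (univariate and multivariate Exp(b), descending) break ties by the
smaller p-value of the same engine, then lexicographic name — the
hierarchy implied by published tables in which two factors share a hazard
ratio and the smaller p receives the better rank. Every rank column is a
permutation of 1..K. The final ranking defaults to the multivariate order,
which is the rule that reproduces the motivating study's printed final
ranks exactly; since that study describes its final rule as combining IS
with the multivariate analysis, the blend (mean of R1b and R2b, ties to
R2b) is retained as the selectable `mean_is_multivariate` method rather
than the default.

Hazard ratios display with 2 decimals (3 when < 1); p-values with 3
decimals and "<0.001" below that.

## Synthetic cohorts

The generator draws independent Bernoulli factors at specified prevalences
and event times from h(t|x) = λ·k·t^(k−1)·exp(x'β) by inverse transform;
k = 1 (exponential baseline) is the default because the ranking procedure
asserts nothing about the baseline shape and the exponential gives closed
forms for test oracles (a Weibull shape is accepted for robustness checks).
Censoring is the minimum of an administrative horizon and an optional
independent exponential dropout time. Factors are independent by default;
an exchangeable Gaussian-copula correlation hook exists because real
clinical factors are correlated, but no joint distribution is published to
emulate.

The study-like default reproduces the *conditions* of the motivating
cohort: n = 371; nine factors at the published prevalences (e.g. 233/371
infiltrated nodes, 44/371 positive margins); conditional log hazard ratios
equal to the logs of the published multivariate hazard ratios (1.79 down
to 0.982); baseline rate calibrated by exact enumeration of the 2⁹
covariate patterns so that marginal survival at 40 months is exactly 0.5
(the published median OS); administrative horizon 264 months with
exponential dropout at rate 1/300 per month, giving the long-follow-up,
light-censoring regime (~15–20% censored) of a 21-year surgical series.

What passing tests show — and what they do not: the generator matches the
analysis model by construction (proportional hazards, independent factors,
exponential baseline, independent censoring), so parameter-recovery and
ranking tests demonstrate the *correctness of the estimators and the
pipeline*, not robustness to the correlated covariates, non-proportional
effects or informative censoring that real clinical data may contain. The
published per-variable statistics themselves derive from confidential
patient data and are not reproducible; they enter only as frozen inputs to
the rank-reconstruction checks.

## Problem sizes and tolerances

The simulation suites use: 200 replicates at n = 10000 for multivariate
coefficient recovery (each Monte-Carlo mean within 2 MC standard errors of
truth); 2000 null replicates at n = 200 per group for log-rank type-I
error (accepted band 0.040–0.061 around the nominal 0.05, the central
~99% binomial range); 200 replicates at n = 5000 for the end-to-end check
that the two strongest true effects occupy the final top 3 in ≥ 95% of
replicates; 100 random curve pairs for the rectangle-sum/quadrature
identity (1e-9); 30 cohorts of ≤ 8 subjects for the Newton/brute-force
identity (1e-6, restricted to draws with an interior maximum — near
separation the partial likelihood is too flat for a bounded scalar
optimizer to localize); and 30 untied samples for the log-rank/score
identity (1e-8). All simulations are seeded and deterministic.

## Known limitations

No competing risks, time-varying effects, stratification or covariate
imputation; no variance for IS; no formal proportional-hazards diagnostic;
the final-ranking blend rule is heuristic by design. The generator's
independence and exponential-baseline assumptions are conveniences for
testability, not claims about clinical data.
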