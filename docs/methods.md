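# Methods

## Model and protocol

All inference concerns a logistic regression with a fixed structure shared
by every site: a binary outcome, a binary exposure, further covariates, and
an implicit intercept at position 0, `logit P(Y=1|x) = x'β`.  The per-site
Bernoulli log-likelihood is evaluated as

    ℓ(β) = Σ_i [ y_i η_i − softplus(η_i) ],   η_i = x_i'β,

with `softplus` computed through `log1p`/`logaddexp` so any representable
linear predictor is overflow-free.

The federated protocol has two rounds:

1. **Round 1 (site → coordinator):** each site fits its own model and shares
   coefficient estimates, standard errors and Wald intervals.  The
   coordinator forms, per coefficient, the conservative envelope of the
   regional intervals — the smallest lower and largest upper bound — and
   segments it at a uniform increment into a lattice axis.  Because every
   site's interval is contained in the envelope, no site's plausible values
   are excluded from the search.
2. **Round 2 (site → coordinator):** each site evaluates ℓ at every lattice
   cell and shares the resulting tensor.  For independent, non-overlapping
   sites the cellwise sum of these tensors *is* the pooled-data
   log-likelihood restricted to the lattice, so the summed tensor's argmax
   estimates the global model without any record leaving a site.

The protocol's validity rests on four assumptions, enforced where they are
checkable: a single common effect across sites (testable post hoc via Q/I²);
scientific comparability of the cohorts (not checkable in software);
identical model structure at every site (enforced through parameter-name
checks and grid fingerprints); and independent, non-duplicated observations
across sites (duplicate site identifiers are rejected, since summing a
site's tensor twice double-counts its records).

## Estimation details

**Local fits** use iteratively reweighted least squares (Newton scoring),
converging when the relative deviance change drops below `tol = 1e-8`
(`max_iter = 50`).  Standard errors come from the inverse observed
information, which equals the expected information for the logit link.
Wald intervals use the exact standard-normal quantile (1.959964 at 95%),
not the 1.96 shorthand; at two-decimal rounding the case study's printed
intervals are consistent with either.  Degenerate inputs fail loudly: a
single-class outcome (the situation that forces a jurisdiction out of the
analysis) and separation (diverging linear predictors during iteration, a
singular information matrix, or saturated fitted probabilities,
|η| > 25, at a purported optimum) raise typed errors rather than returning
unusable coefficients.  No regularisation, weights, or missing-data
handling: complete-case, identically specified inputs are a precondition.

**Axes** are anchored at the exact, unrounded envelope bound and generated
by integer indexing, `values[k] = lower + k·increment`, never by repeated
addition — bit-reproducible across platforms.  When the range is not an
increment multiple the axis stops at the last value inside the bound
(undershooting keeps every lattice point inside the declared plausible
range); a range narrower than one increment yields a legitimate single-value
axis.  Grid identity across sites is checked by a SHA-256 fingerprint over
axis names, full-precision bounds and the increment — never by float
comparison of vectors.

**Tensor evaluation** is defined cellwise, and two implementations produce
it.  The chunked brute force (`method="cells"`) batches lattice cells,
accumulates η term by term and reduces records with a fixed pairwise
summation, so results are bitwise independent of the chunk size.  The
default for large grids (`method="lattice"`) is an exact
sufficient-statistics decomposition: the linear term `Σ y_i η_i` separates
over axes, and because all axes share one increment, the partial predictor
`β₀ + Σ_{binary j} β_j x_j` lives on a one-dimensional lattice, so the
softplus mass of each covariate pattern is tabulated once per binary-covariate
combination and gathered into the tensor.  For the case-study structure
(binary exposure and sex, integer ages) this turns hundreds of millions of
cells × thousands of records into a few million softplus evaluations plus
cheap gathers.  The two methods agree to ~1e-12 per cell (floating-point
regrouping only); unit tests pin both against a per-cell oracle.

**Memory.** A materialised tensor is refused above a configurable ceiling
(default 2 GiB).  Above it, `federated_scan` performs the same cellwise
summation in blocks that partition the intercept axis — pass 1 locates the
combined argmax (ties to the lowest row-major index), pass 2 projects the
relative-likelihood region — holding one block rather than one tensor.  The
desk-scale demonstration grid (five sites at a tenth of the case-study
sizes, increment 0.01) has ~5×10⁸ cells and scans in about a minute on one
CPU; these problem sizes are the package's default demonstration scale.

**Likelihood regions.** The region at threshold `c` is the cell set with
`ℓ ≥ ℓ_max + ln c`; the per-parameter interval is the projection of that
joint region onto the axis (min/max axis value over member cells).  The
published method derives intervals "from the region", which is this
projection; a profile-likelihood interval coincides for unimodal surfaces
and is not separately implemented.  The default cutoff 0.147 is kept
literally as published and is configurable; the analytically calibrated
value `exp(−χ²₁(0.95)/2) = 0.1465` is exposed as
`likelihood_threshold(0.95)`.

**Meta-analysis** is the common-effect inverse-variance method, one pooling
per parameter, with Cochran's Q, I² = max(0, (Q−(k−1))/Q) (clamped at zero,
per the standard definition) and the upper-tail χ²_{k−1} heterogeneity p.
Random-effects models are deliberately out of scope.  **RPAB** divides by
the magnitude of the global estimate, keeping the metric sign-unambiguous
for negative coefficients; for the positive exposure coefficient this
coincides with dividing by the estimate itself.

## Synthetic data

The generator emulates the case study's marginal structure: five sites of
1,700/8,002/6,089/23,946/2,604 patients; site-specific exposure prevalence
0.59/0.62/0.52/0.44/0.67 and male proportions 0.51–0.55; ages truncated
normal per site (means 62.7–64.7 years, SDs ≈ 12, bounds within 18–104)
rounded to whole years, since age is computed as visit year minus birth
year; outcome Bernoulli through the logit link at the global coefficients
(−7.0460, 0.2542, −0.0737, 0.0770), which reproduce the ~15% outcome
prevalence.  Sex is coded 1 = male.  A heterogeneity mode draws each site
with its own exposure coefficient (defaults mirror the observed regional
spread 0.566…0.163) to exercise Q/I² under a violated common-effect
assumption.

Randomness uses NumPy `SeedSequence` substreams keyed by (master seed,
SHA-256 of the site id), so per-site data are bit-reproducible,
order-insensitive, and unchanged when sites are added or removed.

What the generator does *not* model, and what passing tests therefore do
not establish about real data: within-site covariate dependence (e.g. an
age–hypertension correlation — no joint distribution was available, so
covariates are drawn independently), site-level differences in outcome
definition or data quality, visit structure, and any outcome-definition
logic.  Tests on synthetic networks validate the estimation machinery, not
epidemiological conclusions.

## Numerical and design choices

* Sites are summed in the declared configuration order; combined with the
  fixed per-cell reduction order this makes every pipeline output
  deterministic given (configuration, seed).
* The fitting algorithm, tolerance and CI quantile are not pinned down by
  the published method description; IRLS at `1e-8` with the exact normal
  quantile are conventional choices, documented here.
* The combined-lattice argmax tracks the pooled-data MLE only up to lattice
  discretisation, and for strongly collinear axes the effect is anisotropic:
  with age uncentered, the intercept and age axes are nearly collinear
  (correlation ≈ −0.98), so a half-increment snap of the age coefficient
  shifts the compensating intercept by roughly mean-age × snap — dozens of
  increments — while the exposure and sex coefficients land within one
  increment and the log-likelihood gap stays well under one unit.  This is
  inherent to grid search on a ridge, shrinks proportionally with the
  increment, and would vanish if age were centred; age is kept uncentered to
  match the published model.  Per-axis error under refinement is therefore
  only *typically* decreasing: the tensor maximum is monotone under nested
  refinement, per-axis distances can fluctuate by an increment.
* Likelihood intervals are reported alongside Wald/meta confidence
  intervals without mixing the two semantics.

## Limitations

Logit link and complete-case data only; no random-effects pooling; no
secure-aggregation or network transport (sites are directories); grid cost
grows exponentially with parameter count, so models much beyond a handful
of coefficients need coarser increments, narrower envelopes, or the
streaming scan.
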