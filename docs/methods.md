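# Methods

## Structural model and units

The structural model is one-compartment disposition with first-order
absorption from a patch depot and first-order elimination.  Units are fixed
package-wide: amounts in ng (the 34.3 mg patch is 3.43e7 ng), volumes in mL,
time in hours, concentrations in ng/mL, so the published parameter table is
usable verbatim.  Volume and clearance are apparent (V/F, CL/F);
bioavailability is not a separate parameter.

While the patch is worn the concentration is the standard closed form
D·Ka/(V·(Ka−ke))·(e^(−ke·t′) − e^(−Ka·t′)) with ke = CL/V; when
|Ka − ke| < 1e−10·Ka the limit form D·Ka·t′·e^(−Ka·t′)/V is substituted to
avoid catastrophic cancellation.  Patch removal discards the unabsorbed
depot by default — the reservoir physically leaves with the patch — after
which the central compartment decays mono-exponentially; `truncate_at_removal=False`
lets the depot keep draining, since the original analysis's handling is not
documented.  The closed form agrees with adaptive Runge–Kutta integration to
better than 1e−8 relative wherever the concentration exceeds 1e−6 ng/mL;
below that, subtractive cancellation limits the relative precision of any
evaluation route (five orders of magnitude below the assay limit, so without
practical consequence).

A two-compartment variant (peripheral volume V2, inter-compartmental
clearance CL2) is provided for model discrimination.  It is evaluated
through the eigendecomposition of the linear system — the tri-exponential
solution in numerically stable form — and reduces to the one-compartment
profile as CL2 → 0.

The reference random-effect values are interpreted as variances (ω²), not
standard deviations: ω²_V = 1.546 implies a lognormal volume spread with a
~3.5-fold inter-quartile range, large but plausible for apparent V/F of a
transdermal product where absorbed fraction and volume are confounded.  This
interpretation is fixed throughout; every simulation and every recovery
target uses it consistently.

## Estimation

FOCE-ELS as implemented here: per subject, the conditional mode η̂ of the
penalized objective Σⱼ[(yⱼ−fⱼ)²/Rⱼ + ln Rⱼ] + ηᵀΩ⁻¹η is found by a damped
Gauss–Newton iteration with the residual-variance derivative omitted from
the gradient (exact for the additive-error final model; for
proportional/combined residuals R is evaluated at the conditional
prediction, i.e. with η–ε interaction).  Convergence uses the gradient norm
(< 1e−6) or the Newton decrement (< 1e−10): the decrement is the
scale-invariant criterion that remains meaningful when a variance is pinned
near zero and the gradient scale explodes.  Subjects whose descent stalls
with a non-trivial decrement get a derivative-free polish; the best mode
found is always used, so one hard conditional problem degrades one subject's
approximation rather than poisoning the population objective.  Near
flip-flop kinetics (ke crossing Ka within the η range, which the large
volume variance makes common) the conditional surface can be multimodal;
the solver therefore always starts from η = 0, keeping the objective a pure
function of the population parameters.

Subjects sharing a sampling grid are stacked into batch groups so the inner
iteration, the finite-difference Jacobians (central, step 1e−4 on η) and the
OFV linear algebra run vectorized; censored positions contribute nothing via
masking (zero Jacobian row, unit residual variance, zero residual).  The
per-subject contributions are combined with exact summation, making the OFV
independent of subject order to the last bit.

The outer problem minimizes the OFV over log-transformed parameters
(covariate coefficients stay linear) with L-BFGS-B under bounds; ω² is
bounded below at 1e−12 rather than removed, mirroring the published model
structure where the absorption-rate variance collapsed to ~5e−11.  Because
finite-difference quasi-Newton methods can stop prematurely on these
surfaces, the minimization restarts from its own solution (up to
`outer_passes`, default 3) until a pass improves the OFV by less than 0.1;
a pass that cannot improve the incumbent also serves as the stationarity
check behind the convergence flag.  `staged_fit` adds the standard
pharmacometric remedy for the fragile absorption-rate variance: a first pass
with ω²_Ka pinned at the floor, then a release from that solution.  Without
staging, a generic start can strand the search on a high-ω²_Ka ridge.

Initial values come from the naive-pooled method (structural fit to pooled
observations with η = 0, ω² starting at 0.1, σ at the pooled residual SD).
Under the reference model's very large volume variance the pooled fit
overestimates Ka by a factor of 3–4.5 — a property of the pooled
approximation, acceptable for a starting point — while V and CL start within
a factor of 3.

Standard errors come from the central finite-difference Hessian of the OFV
at the optimum: the covariance is 2·H⁻¹, and for log-transformed parameters
the SE of the log is directly the relative SE (RSE% = 100·SE_log).  A
non-positive-definite Hessian reports absent RSEs.

BLQ handling: below-quantification records are excluded from the likelihood
(M1) and pre-dose samples are treated as BLQ.  An exact-likelihood check
(adaptive Gauss–Hermite quadrature) showed that this exclusion is
informative when the additive error is large relative to low
concentrations — the marginal likelihood of the censored dataset genuinely
prefers an inflated Ka — so datasets can carry slightly negative measured
values, and the self-consistency experiments simulate without a
quantification limit (`lloq=None`).  Exposure simulations, by contrast,
apply the LLOQ (default 0.1 ng/mL, the assay limit being unpublished)
because the published exposure summaries derive from quantifiable data.

## Covariate screening

Continuous covariates use the power form θᵢ = θ_TV·(cov/median)^θx with the
median frozen from the dataset when the candidate grid is built; sex
(0 = male, 1 = female) uses θᵢ = θ_TV·e^(θx·[cov=1]).  Forward inclusion
accepts the largest OFV drop exceeding 3.84 (χ²₁, p < 0.05), one addition
per iteration with full refits; backward elimination removes the weakest
effect whose deletion raises the OFV by at most 6.64 (p < 0.01), one removal
per step.  Ties break by larger drop, then lexicographic (parameter,
covariate).  The default grid crosses all five covariates (age, weight,
height, BMI, sex) with Ka, V and CL; collinearity between weight and BMI is
deliberately left to the search.  Changes in ω² are recorded in the trace as
a diagnostic only, never as an inclusion gate, since no threshold for
"reduction of IIV" is defined.

## Validation tools

Goodness of fit reports PRED (η = 0), IPRED (η = η̂) and CWRES
V^(−1/2)·(y − f(η̂) + F·η̂) with the symmetric eigendecomposition square
root; under a correct model CWRES is approximately standard normal and
essentially all values lie within ±4.

The bootstrap resamples subjects with replacement, stratified by study so
every replicate preserves the design mix (unstratified available), refits
each replicate from the original final estimates, and reports percentile
intervals over converged replicates with the convergence count.

The VPC simulates full-design replicates (default 1000) with IIV and
residual error at the estimated parameters and compares simulated 5th/50th/
95th percentile curves with observed percentiles at the nominal design times
(no binning — the designs are fixed-schedule).  Simulated values below the
LLOQ are censored and excluded, matching observed-data handling.

## Trial simulation and bridging

Replicate trials under a target design draw subjects parametrically from
(θ, Ω) — self-contained, requiring no access to the original subjects'
empirical Bayes estimates — add residual error to the sampled concentrations
(so grid maxima see assay noise exactly as observed data would; toggleable),
censor below the LLOQ, and compute per-subject NCA.  The per-trial statistic
is the median (mean by flag); across-trial summaries are the median and the
5th–95th percentile interval using the linear-interpolation percentile
definition.  All-BLQ virtual subjects (possible in the far tail of the
volume distribution) are dropped from that trial's medians, as an
unquantifiable profile would be in practice.

The coverage decision rule counts observed external points inside the
pointwise 5th–95th band at their nominal times.  The band is a nominal 90%
interval, so a same-population dataset scatters around 0.90 coverage; the
verdict threshold defaults to 0.85 to operationalize "approximately 90%"
with room for that sampling noise (a hard 0.90 cut would reject half of all
genuinely comparable datasets).  Discriminative power at this threshold is
moderate: halving clearance (doubling exposure) drops coverage only to
~0.80 because the volume variance makes the reference band very wide; a
three-fold mis-scaling is rejected essentially always.

## Noncompartmental analysis

AUC_last is the linear trapezoid over quantifiable samples up to the last
quantifiable time; interior BLQ records are skipped and a leading pre-dose
BLQ anchors the curve at (0, 0).  Cmax is the maximum quantifiable
concentration, Tmax the earliest time achieving it.  Cavg defaults to
AUC_last/t_last: the published Chinese AUC/Cavg pair implies a normalizing
span of ~178 h, consistent with per-subject last-quantifiable normalization
and inconsistent with both the wear time (144 h) and the full sampling span
(240 h).  The alternative (AUC over the wear interval divided by wear
duration) is selectable.  Log-down trapezoids are deliberately not used; the
few-percent difference is absorbed by the wide acceptance tolerances on the
exposure metrics.

## Synthetic data

The generator reproduces the five published study designs (subject counts,
dose, wear durations of 6–9 days, nominal sampling times) and per-study
demographic summaries.  Continuous covariates are truncated normals at
physiologic bounds (age 18–85 y, weight 40–150 kg, height 140–210 cm, BMI
16–45 kg/m²; the bounds are this package's choice, only means ± SD being
published) with the location moment-matched so the truncated mean equals the
published mean; BMI can optionally be recomputed from weight and height.
Two published inconsistencies are resolved as: the Chinese arm uses its 14
listed sampling times (24×14 = 336 records, although the printed sample
count is 360), and the age/BMI study uses 60 subjects (660 samples ÷ 11
times, against a printed subject count of 59).

What the generator does not emulate: real assay error structure
(heteroscedastic, mildly skewed, never negative — the additive model with
σ ≈ 1.18 ng/mL produces sub-zero draws at low concentrations), dropout,
occasion effects, patch-adhesion failures, or correlation between random
effects.  Passing recovery tests therefore demonstrates estimator
self-consistency under the stated model, not robustness to real-data
violations of it.

## Problem sizes and seeds

Simulation-based checks run at desk scale chosen to keep the full suite
fast while leaving the statistical properties testable: parameter recovery
uses five 112-subject replicates (the published pooled size); the
trial-simulation comparison uses the full 1000 × 24; the null-covariate
calibration uses 200 replicates of a 20-subject reduced model (IIV on
clearance only) so each of the 400 refits is cheap; bootstrap coverage uses
20 repetitions × 200 resamples of a 12-subject one-free-parameter model.
Every stochastic component takes an explicit seed (package default
20230626), and the acceptance script derives all of its seeds from its
`--seed` argument.

Under the reference conditions the typical absorption rate constant is
weakly identified: the additive residual SD (1.18 ng/mL) is comparable to
every absorption-phase concentration, giving the ML estimate of tvKa a
sampling SD near 13% at n = 112 (fits re-initialized at truth converge to
the same optima).  Recovery is therefore assessed on the median estimate
across the five seeds, which is stable at the few-percent level for tvV and
tvCL and within ~10% for tvKa.
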