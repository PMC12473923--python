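# Methods

## Structural model and units

Denosumab kinetics after subcutaneous dosing are described by a depot and
a central compartment with first-order absorption (KA, 1/day) and two
parallel elimination routes from the central compartment: a linear
clearance CL/F (L/day, non-specific catabolism) and a saturable
Michaelis–Menten route Vmax·C/(Km + C) standing in for target
(RANKL)-mediated disposition, which dominates at low concentrations and
saturates above roughly 60 mg doses. Bioavailability F is not separately
identifiable after SC dosing alone, so the model is apparent-parameterized
(CL/F, V/F) and the full labeled dose enters the depot.

Internal units are mg, L, day; concentration is mg/L (numerically µg/mL).
Km and Vmax are carried as 0.124 mg/L and 0.139 mg/day (phase-I set) and
0.162 mg/L / 0.128 mg/day (pooled set). On this scale the saturable route
contributes meaningfully at trough concentrations (C ~ Km ~ 0.1–0.2 mg/L,
i.e. 100–200 ng/mL) and the simulated 120 mg exposure reproduces the
published magnitude; datasets store DV in ng/mL as assays report it, and
the reader converts (÷1000).

## Random effects, residual error, covariates

η on CL, V and KA, independent (diagonal Ω), exponential:
P_i = exp(µ + η_i). IIV is reported as CV% = 100·ω, the convention under
which the reference values (37/13/61% phase I; 34.6/15.7/60% pooled) are
stored; at KA's 60% level the alternative convention
100·sqrt(exp(ω²)−1) would differ appreciably, so the choice matters and
is fixed package-wide. Residual error is proportional with SD σ (17% /
19.5%). Body weight enters clearance as a power law centered at 70 kg;
the study indicator shifts log V/F additively (phase-I-like population is
the reference level, study = 0, consistent with the pooled typical volume
9.00 L ≈ the phase-I-only estimate 9.33 L); treatment-arm shifts on CL, V
or KA are available for pairwise covariate testing only.

## ODE integration

The two-state system (plus a cumulative-elimination state used for mass-
balance checking) is integrated by an adaptive embedded Dormand–Prince
5(4) pair compiled with numba, rtol 1e-8 / atol 1e-10 mg by default. The
system is not stiff at physiological parameters — eigenvalues are at most
~(CL + Vmax/Km)/V ≈ 0.15/day — so an explicit pair is accurate and fast;
the integrator agrees with the Bateman closed form to < 1e-8 relative
when Vmax = 0 and with scipy's LSODA elsewhere. Dose events restart the
integration exactly at the dose time; an observation falling on a dose
time is evaluated predose. Two guards matter for estimation, where the
optimizer visits absurd parameter vectors: the step count per solve is
capped at 20,000 (failure propagates as an infinite OFV rather than a
hang — very large Vmax with tiny Km makes the washout tail arbitrarily
stiff), and integration short-circuits once both amounts fall below the
absolute tolerance.

## Likelihood approximation

Per subject, −2 log of the marginal likelihood is approximated by the
Laplace method at the conditional mode η*:

    OFV_i = Σ_j [ln(2π v_j) + (y_j − f_j)²/v_j]
          + Σ_k [ln ω²_k + η*²_k/ω²_k] + ln det G,

v_j = σ²f_j² + eps², evaluated at the conditional prediction
(interaction). The variance floor eps = 1e-6 mg/L keeps
imputed-zero leading records (predicted concentration exactly 0) from
producing a degenerate residual variance; such records contribute a
constant and carry no information. The inner mode search is a damped
Newton (Levenberg–Marquardt) iteration with Gauss–Newton curvature,
forward-difference prediction gradients, a trust clamp of 2 on the step,
and a warm start from the previous conditional mode compared against the
prior mode (whichever has the better joint density) — the comparison
makes the objective insensitive to stale warm starts.

Two curvature choices for ln det G coexist deliberately. Reported OFVs
(`marginal_ofv`, fit results, likelihood-ratio tests) use an exact
finite-difference Hessian of the joint negative log density at the mode
(central steps 1e-3 per axis, forward cross terms, Gauss–Newton
fallback if the estimate is not positive definite); on single-η instances
this matches 41-node adaptive Gauss–Hermite quadrature to better than 0.1
across an ω × σ × data-scale grid, whereas the pure Gauss–Newton
(classical FOCE) information deviates by up to ~0.4. Inside the
optimizer loop the Gauss–Newton form is used instead — it is cheaper and
smoother under evaluation noise — together with relaxed integration
tolerance (rtol 1e-6); the fitted parameters are then re-evaluated once
at the tight settings.

## Optimization

Free parameters are the five log-scale typical values, the active
covariate coefficients, and log ω²/log σ². The outer minimizer is
COBYQA (derivative-free trust region with a quadratic model), chosen
because the objective carries mild, hysteretic evaluation noise from the
warm-started inner optimization and adaptive integration; quasi-Newton
line searches over finite-difference gradients stall on that noise far
from the optimum, while the trust-region model averages over it. A main
stage (budget 1200 evaluations) is followed by up to four fresh-model
restarts with a small initial radius (0.05, widened to 0.3 while a
restart still improves the OFV by more than 5); convergence is declared
when a restart improves the OFV by less than 0.5, the restart-to-restart
reproducibility of the objective. Non-convergence triggers up to two
jittered re-initializations, and an overall evaluation budget bounds the
worst case. Generous box bounds (e.g. CL/F in
[9e-4, 20] L/day, Km in [1e-5, 150] mg/L) keep the search out of regions
where the ODE becomes pathologically stiff.

Initial values come from a crude noncompartmental pass over the data:
CL from dose over the observed trapezoidal AUC, V from dose over Cmax
(both deflated 20% for the unobserved tail/accumulation), a generic
KA = 0.3/day, Km at 5% of the median Cmax and Vmax sized so the saturable
route matches the linear one at mid-range concentrations. Starting from
data-derived values rather than the generating truth keeps recovery
experiments honest.

Standard errors come from the inverse observed information (numeric
Hessian of the OFV at the optimum; Cov = 2 H⁻¹), differenced on the
tight-tolerance exact-curvature objective with per-parameter steps
calibrated so each diagonal OFV increment is a few units — a fixed step
is either drowned in evaluation noise along flat directions or biased by
higher-order terms along steep ones (e.g. σ at small residual error).
Estimates are
reported on the natural scale by the delta method — exp(µ)·SE(µ) for
log-scale typical values — with 95% CIs transformed consistently. %RSE for log-scale parameters is
quoted on the natural scale; the convention is stated because the two
scales differ noticeably at RSEs above ~20%.

## Synthetic trials

The generator reproduces the two source designs as the analysis
conditions: phase-I-like — three 85-subject arms, one 35 mg SC dose,
23 nominal times (predose, 8 h, 16 h, 1–3 days, then through day 253),
weight ~ Normal(82.97, 8.492²) kg truncated to [50, 130]; phase-III-like —
2:1:1 arms totalling 555 (largest-remainder split 278/139/138), 60 mg SC
at days 0/183/365, six sparse samples (day 0 predose, day 11, months
1/3/6/12 with a 30.4-day month; month-6 and -12 samples are predose
troughs), weight ~ Normal(63.196, 8.787²) kg on [40, 110]. Observations
are DV = C(1+ε) floored at zero (flooring, not redrawing — negative draws
are rare at σ ≤ 0.2); DV below the LLOQ (default 20 ng/mL — the assay
limit is not published; only flagging depends on it) is flagged BLQ.
Scheduled samples can be dropped at a configurable missing rate (default
0: nominal design). With the phase-I truth, trailing samples beyond
~day 115 fall below the LLOQ and are removed by the analysis policy,
leaving roughly three quarters of scheduled records — the same order as
the realized sample counts in the source studies.

What the generator does not emulate: visit-time jitter (nominal times
only, though a window option could be added), dropout and enrollment
dynamics, anti-drug-antibody effects, assay heteroscedasticity beyond the
proportional term, and any pharmacodynamic feedback. Passing recovery
tests therefore demonstrates correctness of the estimator under the
stated generating model, not robustness to those real-data features.

## Diagnostics and VPC

PRED is the typical-subject prediction (η = 0 at the subject's
covariates), IPRE the prediction at the empirical Bayes estimates, and
CWRES the FOCE-linearized conditional weighted residual,
chol(FΩF' + diag(σ²·IPRE²))⁻¹(DV − IPRE + F·η̂); under the true model
CWRES is standard normal to good approximation and the test suite checks
|mean| < 0.1 and SD within [0.85, 1.15]. The VPC simulates the complete
dataset (same doses, times, covariates) 500 times by default with both
variability levels, bins observations per nominal time on rich designs
(quantile bins otherwise), and compares observed 5/50/95 percentiles with
the median and 90% sampling band of the simulated percentiles. BLQ
records are excluded from the observed percentiles (they are excluded
from the analysis dataset); simulated values are retained whatever their
magnitude. That asymmetry selection-biases the observed percentiles
upward in bins dominated by BLQ samples — under the final parameter set
the 60 mg month-6/12 troughs sit near the quantification limit, so the
sparse-design VPC is only interpretable in bins with a low BLQ fraction
(a likelihood-based BLQ treatment would remove the artifact and is out of
scope). The self-consistency check asks that the observed median lie
between the simulated 5th and 95th percentile curves in ≥ 90% of bins —
the standard visual-predictive-check reading; the median's own 90%
sampling band is also reported but is not the acceptance band, since even
a perfect model leaves the observed median outside it in 10% of bins by
construction.

## Derived exposure and bioequivalence

Cmax, AUC0–τ and AUC0–∞ are computed from the noiseless empirical-Bayes
individual profile (model-based exposure, not NCA on raw observations):
trapezoidal integration on a ≥ 2000-point grid, horizon extended by
doubling until C < 1e-4·Cmax, then an analytic terminal tail
C·V/(CL + Vmax/Km) — at washout concentrations far below Km the
saturable route is linear with clearance Vmax/Km. τ is 253 days for the
single-dose 35 mg comparison (the last scheduled sample) and 183 days
for 60 mg regimens; the source analysis never defines τ, so the choice is
recorded here. Bioequivalence uses the parallel-group two-sample
analysis of log metrics: GMR = exp(mean log ref − mean log test) — the
reference products are the numerator, the biosimilar the denominator —
with a Welch-t 90% CI, passing when the CI lies within 80–125%.

The 120 mg extrapolation simulates n ≥ 2000 virtual subjects with IIV and
demographics drawn from the pooled two-study mixture (study label with
probability 255/810 vs 555/810, weight from the matching truncated
normal), a single SC dose, no residual error, and reports the arithmetic
mean and SD of AUC0–∞ in mg·day/L and ng·day/mL (×1000). The published
summary value at this dose (753,000, SD 285,200) carries no printed
units; ng·day/mL is the internally consistent reading given the L/day
clearance scale, and the simulation reproduces it on that scale at the
pooled parameter set.

## Numerical and testing choices

Scaled problem sizes keep the full pipeline testable: recovery
experiments in the test suite use 204 rich subjects (phase I) and
102 + 222 pooled subjects, as the package's standard verification sizes;
the acceptance script fits one 204-subject rich trial and one 102 + 222
pooled trial. At these sizes a fit takes a few minutes on one CPU. Recovery assertions use the reference 95%
confidence intervals of the published estimates as the target bands and
require each parameter to land inside in the majority of seeded
replicates — at reduced n the estimator's sampling spread exceeds the
full-data CI width, so occasional single-replicate misses are expected
and the majority criterion is the designed behavior, not slack.

Known limitations: no M3 (likelihood-based) BLQ handling — the
impute/drop policy is the analysis rule; diagonal Ω only; Wald (not
bootstrap) intervals; no two-compartment alternative (the reference
analysis discarded it for non-convergence, and the single-compartment
form fits the synthetic designs by construction); treatment effects are
single-arm-indicator shifts, adequate for pairwise tests but not a
general design matrix.
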