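# Methods

## Structural model and units

Certepetide disposition is a two-compartment linear mammillary model with
central volume `vc` (L), elimination clearance `cl` (L/h), peripheral
volume `vp` (L) and distribution clearance `q` (L/h). Doses are in mg,
times in hours, concentrations in ng/mL; the single unit conversion
(1 mg/L = 1000 ng/mL) lives in `twocomp.MG_PER_L_TO_NG_PER_ML`.

All solutions are closed-form bi-exponentials. The disposition exponents
are the roots of `λ² − (k10+k12+k21)λ + k10·k21 = 0` with
`k10 = cl/vc`, `k12 = q/vc`, `k21 = q/vp`; at the published estimates the
terminal exponent is 0.380 /h (t½ ≈ 1.8 h). In the degenerate `q = 0`
limit the model collapses to one compartment; the slow exponent is then
reported as `k10` and the vanishing second term is handled explicitly
rather than through limits of 0/0 expressions.

Steady state under repeated dosing is analytic: each post-infusion
exponential term accumulates by the geometric factor
`e^{-λτ}/(1−e^{-λτ})`. Brute-force superposition of many doses exists
only as a test oracle. Cmax within an interval is located on a grid of
2000 points concentrated across the infusion (where the peak of an
IV-infusion profile sits) followed by parabolic refinement; with the
1-minute infusion this resolves the very narrow peak to well under 0.01%.
One behaviour worth noting: at a fixed q8h regimen, steady-state Cmax
*increases* with `vp`, because a larger peripheral volume slows the
terminal phase and raises accumulation; the intuitive "bigger volume,
lower peak" holds for a single dose only.

## Covariate model

Typical values follow the final published structure: power-of-weight
effects on `vc` and `vp` (reference 70 kg), and clearance split into
nonrenal and renal parts, linear in baseline Cockcroft–Gault creatinine
clearance referenced to 90 mL/min. Power exponents are unconstrained;
proportional (categorical) effects are bounded below by −1 so parameters
stay positive; inter-individual variability is log-normal, applied as
`e^η`. The Cockcroft–Gault formula is used in its standard mg/dL form
with the 0.85 female factor (the source analysis cites but does not print
it), and derived CrCL is deliberately uncapped — values above 120 mL/min
occur and are retained. An age-on-CL power effect (reference 60 y) is
available to the selection machinery so the intermediate model of the
historical development path is reachable, although the final model drops
it.

## Estimation: FOCE with interaction

The objective is the NONMEM-style OFV, −2 × the approximate marginal
log-likelihood. Per subject, the conditional mode η̂ of the random
effects is found by a damped Gauss–Newton search vectorised across all
subjects simultaneously; structural gradients with respect to η come from
forward differences of the closed-form kinetics (step 1e-5). The marginal
contribution then uses the first-order expansion about η̂ with the
residual SD `W = sqrt(σ1²·IPRED² + σ2²)` evaluated at the mode
(the "interaction" term; the proportional error makes it necessary), and
the Woodbury identity for the per-subject log-determinant and quadratic
form. The no-IIV limit reduces exactly to the weighted least-squares
deviance `Σ[(y−f)²/W² + log(2πW²)]`, which the tests assert to 1e-8.

Numerical choices, all verified to leave the OFV noise floor (~1e-5,
from warm-start path dependence) far below the outer finite-difference
steps:

- inner gradient tolerance 1e-4 with a stall detector (a subject that
  cannot improve along a damped Newton direction at small gradient is at
  its mode to finite-difference precision);
- inner steps capped at 3 η-units per iteration and η clipped to ±15 —
  values beyond are numerically meaningless and only arise from
  ill-conditioned curvature during early outer iterations;
- outer optimisation by L-BFGS-B on transformed parameters (log for
  positive structural values and variances, identity for power exponents,
  log1p for proportional effects), gradient step 1e-4;
- warm-started conditional modes cached across outer evaluations.

BLQ records carry no likelihood contribution: the M1 convention removes
post-dose records below 50 ng/mL upstream, and anything still flagged
(predose zeros) is skipped by the encoder.

The covariance step is a central finite-difference Hessian of the OFV on
the natural (reported) scale, inverted and doubled; 95% CIs are
`estimate ± 1.96·SE`, matching the published table's convention. The
condition number is the eigenvalue ratio of the induced correlation
matrix (< 1000 taken as stability, as in the source analysis). Reported
CV% uses `sqrt(e^{ω²}−1)·100` for IIV but plain `sqrt(σ²)·100` for the
proportional residual — the only pair of conventions that reproduces all
four published CV values (the log-normal formula on σ1² = 0.0393 would
give 20.0%, not the printed 19.8%).

CWRES follows the FOCE linearisation: the residual vector
`y − f(η̂) + Gη̂` decorrelated by the Cholesky factor of
`GΩGᵀ + diag(W²)`; it collapses to `(y−pred)/W` without IIV and is
approximately standard normal under a correct model (asserted as mean
within ±0.1, SD within [0.85, 1.15] on ~555 simulated records).

Stepwise selection uses ΔOFV against the χ²(1 df) quantile at α = 0.001
(10.83) for both the forward inclusions and backward eliminations; the
historical analysis prints only the backward cutoff ("large change" for
forward steps), so using one threshold for both passes is a design
choice, configurable per call.

## Synthetic cohort

The generator reproduces the trial design: 31 subjects in dose groups
5/4/12/10 at 0.2/0.8/1.6/3.2 mg/kg (the published per-dose subject counts
5/4/15/14 double-count intra-subject escalation, which the generator does
not model), three occasions 7 days apart (run-in plus two cycle day-1
visits; carry-over is negligible at ~92 terminal half-lives), and seven
samples per occasion (predose, then 3, 15, 30 min, 1, 3, 6 h after the
end of the 1-minute infusion) — 651 observation records, of which the
post-dose BLQ fraction (~10%, mostly later-occasion troughs and 6-h
samples of the lowest dose group) is removed by M1.

Weight and serum creatinine are sampled log-normally, age normally, all
truncated by rejection to the published ranges (weight median 73.7 kg,
σ_log 0.17, [54, 121]; age 62.1 ± 8.5 y, [42.6, 79.3]; creatinine median
0.78 mg/dL, σ_log 0.20, [0.4, 1.6]; 64.5% male). Creatinine — not CrCL —
is the sampled primitive; CrCL is always derived through Cockcroft–Gault,
so its published median (~97 vs 96.8 mL/min), its correlation with age
and weight, and the ~61% normal-renal share all emerge mechanistically
rather than being imposed. The creatinine scale and spread are the only
calibrated quantities, fixed once against those summaries.

Observations follow `DV = IPRED·(1+ε1) + ε2` with one η draw per subject;
negative draws are truncated at zero and flagged BLQ. What this generator
does *not* emulate: intra-subject dose escalation, inter-occasion
variability (the source models none), time-varying covariates, dropout,
or the co-administered chemotherapy. Passing recovery tests therefore
demonstrate correctness of the estimator under the stated model, not
robustness to those real-data complications. The generator also produces
651 design records versus the 1142 analysed in the source study, whose
extra occasions are undocumented; recovery uncertainty here is
correspondingly wider.

## Diagnostics and applications

**VPC.** 500 replicates reuse the observed design, covariates and record
structure with fresh η and ε; records a replicate simulates below the
LLOQ are excluded replicate-wise, mirroring M1. Binning is by nominal
time after dose (the design is nominal-time structured), stratified by
weight-normalised dose level, with a quantile fallback for irregular
designs; percentiles are type-7, and the 95% bands are
percentile-of-percentiles across replicates. Empty or single-observation
bins are dropped with a warning.

**Forest plots.** Parameter uncertainty propagates by smoothed parametric
bootstrap: draws from MVN(estimates, covariance), rejecting vectors with
non-positive structural parameters or variances (an error is raised if
more than half are rejected — the covariance is then implausible). When
reproducing the published medians the covariance is diagonal, built from
SEs back-derived as CI-width/3.92, since the full matrix is unpublished;
at these CV levels the ratio medians are insensitive to off-diagonals.
Ratios are computed within each draw against the same draw's reference
subject (70 kg, CrCL 90, age 60), under a fixed 224 mg q8h 1-minute
infusion; linear kinetics make the ratios dose-invariant. The AUC ratios
at CrCL 50/150 reproduce the published 1.38/0.706 to well within ±0.02.
The 100-kg Cmax ratio computes to ≈0.74 under every reading of the
stated procedure we could construct (bolus limit 0.73, single-dose limit
0.72); the published 0.703 (0.708 elsewhere in the same source) is not
reproducible from the printed parameters, and the package reports its
computed value rather than matching the print.

**Renal exposure.** Empirical Bayes parameters with each subject's own
covariates give per-subject Cmax,ss/AUC,ss (reference regimen) and CL,
summarised as boxplot statistics (quartiles, 1.5·IQR whiskers, outliers)
over the conventional CrCL categories (≥90, 60–89, 30–59, <30 mL/min).
AUC rises and CL falls monotonically with impairment — forced by the
linear renal clearance model.

## Problem sizes and determinism

Default analysis sizes: 31 subjects (~555 quantifiable records), 500 VPC
replicates, 1000 bootstrap draws; the test suite additionally runs a
20-seed recovery panel (mean relative bias of every structural fixed
effect within ±10%; observed ≤4%) and scaled-down selection simulations
on 16-subject cohorts. A full fit takes a few seconds on one CPU. All
randomness flows from explicit seeds via `numpy.random.SeedSequence`
stream-splitting; pipeline reruns with the same configuration are
byte-identical, and every artifact embeds the configuration hash and
seed.

## Known limitations

- FOCE is an approximation; its error grows with ω² and data sparsity
  (quantified in the tests against dense-quadrature oracles: ~1e-3 OFV
  units at ω² = 0.0025, ~0.05 at ω² = 0.04 for single-observation
  subjects).
- The covariance step is the inverse Hessian (R-matrix analogue); no
  sandwich estimator.
- No M3 likelihood handling of BLQ data, no off-diagonal Ω, no
  inter-occasion variability, no SAEM/importance sampling.
- Weight-exponent estimates are noisy at n = 31 (SE ≈ 0.2–0.3); single
  cohorts can yield exponents far from truth without model error.
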