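# certepk — population pharmacokinetics of certepetide

Certepetide (LSTA1 / CEND-1) is a 9-amino-acid cyclic tumour-penetrating
peptide given as a 1-minute intravenous push alongside chemotherapy in
patients with metastatic pancreatic ductal adenocarcinoma. Its plasma
kinetics are well described by a two-compartment model with linear
elimination, a short terminal half-life (~1.8 h) and predominantly renal
clearance. `certepk` re-implements that population-PK analysis as a
reusable, tested Python pipeline for pharmacometricians who want to study,
extend or stress-test the model without NONMEM and without access to the
original trial data.

## The model

Individual parameters arise from log-normal inter-individual variability
around covariate-adjusted typical values:

```
P_i   = P_typ(x_i) · exp(η_P,i),        η_P,i ~ N(0, ω²_P)
Vc,i  = θ_Vc · (WT_i/70)^θWT-Vc · e^η
Vp,i  = θ_Vp · (WT_i/70)^θWT-Vp · e^η
CL_i  = (θ_CL,NR + θ_CL,R · CrCL_i/90) · e^η          (Cockcroft–Gault CrCL)
Q_i   = θ_Q                                            (no IIV)
y_ij  = F_ij · (1 + ε1_ij) + ε2_ij,     W² = σ1²F² + σ2²   (σ2² fixed to 0)
```

Estimation is native FOCE with interaction (first-order conditional
expansion about each subject's conditional mode, η-dependent residual SD),
reporting the NONMEM-style objective function value (−2 × approximate
marginal log-likelihood), empirical Bayes η, shrinkage, CWRES, a
finite-difference covariance step and its condition number. Covariate
selection is stepwise with backward elimination at ΔOFV ≥ 10.8
(χ², 1 df, α = 0.001). Diagnostics and applications include visual
predictive checks (500 replicates, percentile-of-percentiles bands),
smoothed-parametric-bootstrap forest plots of steady-state Cmax/AUC
ratios against the 0.8–1.25 relevance band, and EBE-based exposure
summaries by renal-function category.

Because the trial data are not public, the `cohort` module simulates
trial-like datasets: 31 subjects at 0.2/0.8/1.6/3.2 mg/kg, three PK
occasions, sampling at predose and 3, 15, 30 min, 1, 3, 6 h after the end
of the infusion, LLOQ 50 ng/mL, and baseline covariates matching the
published medians/ranges, with CrCL derived mechanistically via
Cockcroft–Gault.

## Worked example

```python
from certepk.reference import final_model, initial_model
from certepk.cohort import simulate_cohort
from certepk.dataset import apply_m1_filter
from certepk.estimation import fit

truth = final_model()                       # published parameter set
ds, info = simulate_cohort(truth, seed=2026)
analysis, n_blq = apply_m1_filter(ds)       # M1: drop post-dose BLQ records
print(len(ds.observations), n_blq)          # 651 65

result = fit(analysis, initial_model())     # FOCE-I from displaced initials
print(round(result.ofv, 1), round(result.condition_number, 1))
# 8754.4 51.7
print({k: round(v, 2) for k, v in result.estimates.theta.items()})
# {'vc': 6.1, 'cl_nr': 2.27, 'cl_r': 4.53, 'vp': 9.88, 'q': 22.95,
#  'wt_vc': 0.38, 'wt_vp': 1.16}
```

The 651-record design loses 65 below-quantification records to the M1
filter; the fit recovers the generating structural values (Vc 5.87,
CL_NR 2.56, CL_R 4.32, Vp 10.3, Q 24.9) within their estimation
uncertainty — the weight exponents are the noisiest quantities on a
31-subject cohort — and the condition number (~52, well below 1000)
indicates a stable fit.

The command line mirrors the library:

```bash
certepk simulate --seed 1 --out sim.csv
certepk data validate sim.csv
certepk fit sim.csv --model final --out fit.json
certepk vpc sim.csv fit.json --nrep 500 --seed 1
certepk forest --n 1000 --seed 1
certepk run --seed 1 --out-dir full_run      # whole pipeline
```

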