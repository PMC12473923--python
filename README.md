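# denopk

Population pharmacokinetics of denosumab on synthetic trials: a
one-compartment model with first-order subcutaneous absorption and
parallel linear + saturable (Michaelis–Menten) elimination, estimated by
approximate marginal likelihood (FOCE with interaction / Laplace), with
visual predictive checks, model-based bioequivalence against the 80–125%
margin, and exposure extrapolation to the 120 mg therapeutic dose.

## Who this is for

Pharmacometricians and biostatisticians who want a self-contained,
testable reimplementation of a denosumab popPK meta-analysis workflow:
the original serum concentration data are not public, so the package
ships a synthetic-trial generator that emulates the two source designs —
a rich single-dose 35 mg study in 255 healthy men (23 samples over 253
days) and a sparse 60 mg every-6-months study in 555 postmenopausal
women (6 samples) — and every downstream stage (estimation, diagnostics,
bioequivalence, simulation) is exercised against those virtual trials
with known ground truth.

## The model

Amounts in mg, volumes in L, time in days, concentration C = A_c/V in
mg/L (≡ µg/mL):

    dA_d/dt = −KA·A_d
    dA_c/dt =  KA·A_d − (CL/V)·A_c − Vmax·C/(Km + C)

Individual parameters are log-normal around typical values (MU
referencing), with body weight as a power covariate on clearance centered
at 70 kg and a study shift on the apparent volume:

    CL_i/F = exp(µ_CL + β_BW·ln(WT_i/70) + η_CL,i)     η ~ N(0, ω²)
    V_i/F  = exp(µ_V + β_study·STUDY_i + η_V,i)
    KA_i   = exp(µ_KA + η_KA,i)

Observed concentrations carry proportional residual error,
DV = C·(1 + ε), ε ~ N(0, σ²). Concentrations below the assay limit
(default LLOQ 20 ng/mL) are imputed to zero at the start of a profile and
dropped when trailing or isolated between measurable values.

The marginal likelihood is approximated per subject by a Laplace
expansion about the conditional mode of (η_CL, η_V, η_KA), with the
residual variance evaluated at the conditional prediction (FOCE-I).
Reported OFVs use an exact finite-difference curvature at the mode and
agree with a 41-node adaptive Gauss–Hermite quadrature oracle to < 0.1 on
single-random-effect instances.

## Worked example

```python
from denopk import estimation, reference, synthetic_trial
from denopk.dataset_io import apply_blq_policy_all

truth = reference.phase1_reference_model()      # published 35 mg estimates
design = synthetic_trial.phase1_design(n_per_arm=34, seed=20250926)
trial = synthetic_trial.simulate_trial(design, truth, seed=20250926)
subjects, _ = apply_blq_policy_all(trial.subjects)

fit = estimation.fit(subjects, estimation.nca_init(subjects), seed=1)
print(estimation.format_fit_table(fit))
```

prints (102 subjects, 1784 retained records; a few minutes on one CPU):

```
Parameter       Estimate    %RSE                95% CI  IIV CV%
KA (1/day)        0.4073     6.4      [0.3591, 0.4619]      62%
V/F (L)            9.156     1.7        [8.859, 9.463]      13%
CL/F (L/day)      0.1217     7.6      [0.1049, 0.1412]      31%
BW~CL              1.614    18.4        [1.031, 2.197]
Km (mg/L)         0.1237    14.8     [0.09263, 0.1653]
Vm (mg/day)       0.1402     8.5      [0.1187, 0.1657]
Residual            17.7%  (proportional CV)
OFV -2202.676 | converged: True
```

against generating values KA 0.406, V/F 9.33 L, CL/F 0.123 L/day, BW~CL
1.32, Km 0.124 mg/L, Vm 0.139 mg/day, σ 17% — every fixed effect is
recovered within its uncertainty at this reduced sample size, and the
η-shrinkages (CL 1%, V 9%, KA 2%) confirm the rich design individualizes
all three random effects.

The numbered drivers under `analysis/` chain the full workflow
(simulate → fit phase I → pooled fit + covariate tests → VPC →
bioequivalence → 120 mg extrapolation), writing their tables under
`results/`; the `denopk` console script exposes the same stages
(`denopk simulate|fit|covtest|vpc|be|extrapolate`).

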