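# rifpk — population pharmacokinetics of single-dose oral rifampicin

Rifampicin, the backbone of first-line tuberculosis therapy, shows saturable
(Michaelis–Menten) elimination: exposure rises more than proportionally with
dose, and body size and composition drive much of the between-subject
variability.  `rifpk` implements a complete population-PK analysis pipeline
for a single-dose, two-period crossover study in healthy volunteers
(24 subjects, 600 mg oral dose, rich sampling to 24 h, assay LLOQ 0.1 mg/L),
aimed at modellers who want a transparent, fully testable re-implementation
of this kind of analysis — including its estimation algorithm — rather than
a black-box run in commercial software.

## The model

Plasma concentration follows a one-compartment model with lagged zero-order
input and Michaelis–Menten elimination,

    dA/dt = rate_in(t) − Vmax·C/(Km + C),   C = A/V,
    rate_in = dose/Tk0  on (Tlag, Tlag + Tk0],  else 0,

with apparent (oral) parameters Tlag, Tk0, V/F, Vmax/F, Km.  Individual
parameters are log-normal around covariate-adjusted typical values:

    P_i,occ = θ_P · Π_c (COV_c,i / ref_c)^β_c · exp(η_P,i + κ_P,i,occ)

with inter-individual variability η (on V/F and Vmax/F in the base model),
inter-occasion variability κ (on Tlag, Tk0, V/F, Vmax/F; the Tlag and Tk0
components correlated), a combined residual error g = a + b·f, and
observations below the LLOQ treated as interval-censored on [0, LLOQ).
Covariate references are observation-weighted means; fat-free mass comes
from the sex-specific Janmahasatian model and body surface area from the
Mosteller formula.  Estimation is by SAEM (Metropolis-within-Gibbs E-step
with truncated-Gaussian imputation of the censored data), the marginal
likelihood (OFV = −2 log L) by defensive-mixture importance sampling, and
model comparison by a hybrid-penalty corrected BIC.

Three fitted parameterizations ship as presets: `base` (no covariates),
`sex_bw` (sex + body weight) and `ffm` (fat-free mass with fixed exponents
1 on V/F and 0.75 on Vmax/F — the final model).

## Worked example

```python
import numpy as np
from rifpk import DesignSpec, SAEMSettings, fit_saem, load_preset, simulate_study

model = load_preset("ffm")                       # generating truth
study = simulate_study(model, DesignSpec(), np.random.default_rng(101))
print(study.table.n_obs(count_predose=False))    # 912 post-dose samples
print(study.table.n_censored())                  # 164 BQL rows incl. predose

fit = fit_saem(study.table, model, SAEMSettings(seed=708))
for p in ("Tlag", "Tk0", "V", "Vmax", "Km"):
    print(p, round(fit.theta[p], 3))
```

prints (this exact seed):

```
912
164
Tlag 0.37
Tk0 0.424
V 36.21
Vmax 204.652
Km 21.352
```

i.e. the fit recovers the generating values (0.340 h, 0.470 h, 36.2 L,
190 mg/h, 20.1 mg/L) within the sampling noise of a 24-subject study —
each estimate lies inside the study's reported bootstrap 95% CI for that
parameter.  V/F is the tightest-determined parameter (Cmax ≈ dose/V under
fast input); Vmax and Km move together along their saturation ridge, so
their individual estimates scatter more than their ratio.

The numbered scripts under `analysis/` run the full narrative on a shared
reference study: `01_simulate_study.py` (design + censoring bookkeeping),
`02_fit_models.py` (base vs FFM fits, ΔOFV), `03_covariate_selection.py`
(stepwise search; the body-composition descriptors FFM and sex race closely —
as their published ΔOFVs of 56.4 vs 51.2 suggest — while preparation is
always rejected), `04_diagnostics.py` (NPDE, pcVPC, bootstrap), `05_exposure_simulation.py`
(AUC vs fat-free mass at 600 mg), `06_recovery_study.py` (long-running
replicate-bias assessment).  A thin CLI (`rifpk simulate|fit|select|
diagnose|expose`) exposes the same stages.

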