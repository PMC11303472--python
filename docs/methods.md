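# Methods

## Structural model

Single oral dose into one compartment: zero-order input of duration `Tk0`
(h) starting after a lag `Tlag` (h), Michaelis–Menten elimination with
maximum rate `Vmax` (mg/h) and half-saturation concentration `Km` (mg/L),
apparent volume `V` (L).  A single dose cannot separate bioavailability
from the disposition parameters, so all parameters are apparent oral
quantities (V/F, Vmax/F) with F ≡ 1 internally.

Two computational routes exist and are cross-checked in the tests:

* **Reference route** (`predict_conc`): `scipy.integrate.solve_ivp`
  (LSODA, analytic Jacobian of the elimination term, rtol 1e-10), with the
  integration restarted at `Tlag` and `Tlag + Tk0` so the adaptive stepper
  never straddles an input discontinuity.
* **Fast route** (`predict_conc_fast`, used inside all estimation and
  simulation loops): classical RK4 with 64 fixed steps across the input
  window, then the exact solution of post-absorption MM decay via the
  Lambert W function, `C(t) = Km·W0(u·exp(u − (Vmax/V)(t−t_end)/Km))` with
  `u = C_end/Km`, evaluated through an overflow-safe Newton iteration on
  `w + log w = y`.  Agreement between the routes is ~1e-9 relative.

AUC uses composite Simpson quadrature on the input window plus the closed
form `(V/Vmax)(Km·ΔC + ΔC²/2)` for the MM segment; AUC(0–∞) is exact once
the input ends.  Zero `Vmax` raises a divergence error for AUC(0–∞).

For the base-model family comparison, the kernel also integrates
first-order-absorption and linear-elimination variants (generic RK4, step
0.005 h, input gated per integration segment so RK4 stages at a boundary
cannot sample the wrong branch of the piecewise-constant input).  The
catalogue spans the one-compartment family {zero/first-order} × {lag/no
lag} × {MM/linear}; transit-compartment and multi-compartment variants are
out of scope.

## Statistical model

Individual log-parameters per occasion,
`ψ = (log Tlag, log Tk0, log V, log Vmax)`, are Gaussian around
covariate-adjusted population means with covariance built from IIV
(subject level) and IOV (occasion level) components; the IOV components of
Tlag and Tk0 are correlated (ρ).  Km carries no random effect in any
shipped model.  Variabilities are reported as CV%; the exact log-normal
relation `ω = sqrt(log(1+(CV/100)²))` is the default (at the largest
shipped CV of 66.9% the linear approximation is off by ~9%), with the
approximate convention available as a switch.

Continuous covariates are power terms normalized by the
observation-weighted mean of the fitted dataset; sex (and preparation) are
categorical terms acting as `exp(β)` off the reference level.  The
multiplicative `exp(β)` form is used rather than a literal `1 + β` linear
factor because it cannot produce negative parameters and matches log-normal
parameter distributions.  The normalization reference is resolved once from
the dataset and stored in the model object, so simulation and fitting of
the same dataset always share the same reference; shipped presets fall back
to demographics-derived constants (e.g. FFM ≈ 50.1 kg, the 11:13
male:female weighted median) only when no dataset is available.

Residual error is combined additive + proportional, `g = a + b·f`
("combined1"); the quadrature convention `sqrt(a² + (b·f)²)` is available
as a switch.  Observations below the LLOQ enter the likelihood as the
Gaussian probability mass on `[0, LLOQ)` — the interval is bounded below at
zero because concentrations cannot be negative.  Predose samples are kept
as censored rows; they inform the additive error component.  Interval
probabilities are floored at a configurable value to avoid log-underflow.

## SAEM estimator

Latent variables: the stacked per-occasion `ψ` (8 dimensions for a
2-occasion study).  Each iteration:

1. **E-step** — Metropolis-within-Gibbs per subject and chain: an
   independent draw from the Gaussian prior, a componentwise random walk
   (only the affected occasion's likelihood is re-evaluated), and a joint
   random walk along the prior Cholesky directions.  Proposal scales adapt
   toward 0.3 acceptance during burn-in/exploration.  Censored
   observations are imputed from the residual model truncated to
   `[0, LLOQ)` by inverse-CDF sampling.
2. **M-step** (stochastic approximation, step 1 during exploration, then
   `k^(-0.7)`):
   * means and free covariate coefficients by ordinary least squares on
     the smoothed ψ statistics (the coefficient of a categorical or
     log-ratio column is the β estimate; the update is exact because the
     parameter prior is linear-Gaussian in these coefficients);
   * variance components by structured moment matching: the cross-occasion
     second moment estimates ω², the within-occasion moment minus ω²
     estimates γ², the within-occasion Tlag–Tk0 cross moment estimates
     ρ·γ₁·γ₂, all with nonnegativity clamps and ρ clipped to ±0.95.  The
     second-moment statistics are re-centred at the current means each
     iteration (stochastic approximation of the EM map rather than raw
     sufficient-statistic bookkeeping);
   * Km (no random effect) and a joint shift of all individual log-Vmax
     values are updated together by a short Nelder–Mead argmin of the
     complete-data likelihood, smoothed by the SA step.  This joint
     update matters: Vmax and Km lie on a long ridge (only their ratio is
     identified below saturation) and coordinate-wise updates stall on it;
   * residual (a, b) by minimizing the smoothed heteroscedastic Gaussian
     pseudo-likelihood (warm-started 2-D Nelder–Mead).  The two inner
     optimizations alternate between iterations during exploration.
3. During the smoothing phase two MH sweeps run per iteration: the
   variance components need the within-iteration posterior spread, which a
   single sweep underexplores (a single-sweep chain visibly shrinks ω/γ).

Initialization: fixed effects from a naive-pooled nonlinear least-squares
fit on the uncensored observations, constrained to one decade around the
starting model (pooled LS on IOV-smeared data otherwise collapses the lag
to zero); variances at 30 CV%; ρ at 0; error at a = 0.1, b = 0.15.  A
`warm_start` switch instead takes every numeric starting value from the
supplied model — used for covariate-selection member fits and bootstrap
replicates.

Default schedule: 50 burn-in + 500 exploration + 300 smoothing iterations,
2 chains.  Convergence is declared when each fixed effect's relative spread
over the last 60 iterations is below 5%.  Empirical Bayes summaries are
the smoothed posterior means of ψ; the reported RSEs come from a linearized
(first-order) Fisher approximation and are indicative only — the bootstrap
is the reference uncertainty method.

## Marginal likelihood, BICc

OFV = −2 log L by importance sampling per subject with a defensive mixture
proposal: 90% multivariate t (4 df) centred at the subject's empirical
conditional mean with 1.3× the conditional covariance accumulated during
smoothing, 10% prior draws to bound the weights.  Full conditional
covariances matter: with an independent-per-coordinate proposal the
8-dimensional correlated posteriors defeat the sampler and the OFV is
biased upward by hundreds of points with a deceptively small reported SE.
The Monte Carlo SE is reported alongside.  Without random effects the
integral collapses and the OFV is computed exactly.

BICc uses the hybrid penalty: variance-related parameters × log(N
subjects), fixed effects and error parameters × log(n observations); a
switch gives the plain BIC.

## Covariate selection

Greedy forward inclusion (accept the largest ΔOFV ≥ 3.84 per round) then
backward elimination (remove terms whose removal costs < 10.8, weakest
first).  The backward cut-off is the literal published value: its label
"P < 0.01" corresponds to the 1-df chi-square 0.001 quantile (10.83), and
it is deliberately not recomputed from a distribution.  Size-descriptor
exponents are fixed at 1 (V) and 0.75 (Vmax) during selection; estimated
exponents are available via the `fixed=False` flag on a candidate term.

Four design choices keep the ΔOFVs honest rather than artifacts of Monte
Carlo noise.  First, every member fit is warm-started from the current
parent's fitted values with a smoothing-heavy schedule (short exploration,
long smoothing): the stochastic-approximation averaging in the smoothing
phase is what pins down the member estimates, and short-smoothing refits
of even an identical model scatter their OFV by several points.  Second,
the recorded base OFV comes from one warm refit of the cold base fit under
the same member protocol, so the baseline has the same convergence depth
as every candidate — a cold baseline occasionally misconverges by tens of
OFV points at small n, which would masquerade as a large covariate effect
in every candidate ΔOFV.  Third, every OFV in a search is evaluated by
importance sampling under one shared proposal (the base fit's conditional
moments) and one shared draw seed; the per-subject posteriors of the
individual log-parameters are pinned down by the rich data and barely move
between nested covariate models, so the Monte Carlo error is common to all
members and cancels in every difference.  Fourth, each member fit's SAEM
seed derives from the run seed plus a stable hash of the candidate path,
so traces replay exactly.

At strongly scaled-down sizes (the null-calibration suite runs 8-subject
studies) one further choice is needed: member fits hold the variance
components fixed at the base fit's estimates (shared nuisance parameters)
and estimate only the means, covariate coefficients and residual error.
Re-estimating an 8-subject variance per member adds ΔOFV noise of several
points, enough to cross even the 10.8 backward bar by chance; fixing the
nuisance variances removes that noise and makes the candidate's
likelihood-ratio the only moving part.  This slightly understates each
candidate's gain (a real covariate would also shrink a variance), i.e. it
is conservative for inclusion.  Scaled-down designs must also keep the
absorption-phase samples dense: with the first sample at 0.33 h a 0.34 h
lag is unidentified and fits drift into a degenerate near-linear mode.

## Synthetic-study generator

Emulates the trial design: 24 subjects (11 male / 13 female), two-period
crossover with complete washout (occasions are independent; no carryover
state), 600 mg single dose per occasion, predose + 19 nominal post-dose
samples (0.16–24 h), LLOQ 0.1 mg/L.  Covariates are truncated normals per
sex (mean = reported median, SD = range/4, truncated to the reported
range); (BW, BH) pairs are rejection-sampled until BMI lies in the
18.5–30 kg/m² eligibility window — rejection rather than clipping keeps
BMI = BW/BH² exact, which the event-table validator asserts.  FFM and BSA
are derived, never sampled; female and male FFM ranges come out disjoint,
as in the study population.  Preparation labels alternate test-reference /
reference-test by enrolment order and have no effect in the generating
model.

Simulated concentrations get combined-error noise; any value below the
LLOQ (including negative draws from the additive term and essentially all
predose samples) becomes a censored row with DV = LLOQ, never truncated to
zero — this keeps the generator coherent with the censored likelihood.
Under the FFM preset the generator yields exactly 912 post-dose
observations of which ~11–12% are BQL, bracketing the 10.8% reported for
the design it emulates.  Draw order (covariates, then η, then κ, then
noise, subject-major) is fixed, making studies byte-reproducible under a
seed.

What the generator does not emulate: dropout, sampling-time deviations,
assay batch effects, auto-induction on repeated dosing (absent from a
single-dose model by design), or model misspecification of any kind —
passing recovery tests therefore demonstrates estimator correctness under
the assumed model, not robustness of the published analysis to real-data
violations.

## Problem sizes in the shipped tests and scripts

The test suite runs the recovery experiment at the full study design
(24 subjects, 10 seeds, default SAEM schedule) and scales down only the
auxiliary machinery: the null covariate-selection calibration uses 100
replicates of an 8-subject, 10-sample design with shortened schedules; the
bootstrap self-consistency demonstration uses tens of replicates rather
than the 1000 a full analysis would run (the `analysis/04` script uses 50;
the API default is 1000); the pcVPC keeps its 1000 replicates where it
appears in `analysis/04` and uses 100–200 in unit tests.  The
replicate-bias study (50 full studies) lives in `analysis/06_recovery_study.py`
rather than the test suite.  These sizes are the package's own choices,
recorded here so that anyone re-running at larger sizes knows what changes.

## Known limitations

* Estimated covariate coefficients on Km are unsupported (Km has no random
  effect, so its coefficients have no closed-form M-step); none of the
  shipped or published models needs them.
* The moment-matching variance M-step is consistent but not the exact
  structured-covariance MLE; at n = 24 its extra variance is negligible
  against sampling noise.
* The linearized RSEs understate uncertainty for variance components (they
  are reported as NaN there); use the bootstrap.
* NPDE decorrelation uses the Monte Carlo covariance of the simulated
  observation vectors; censored rows enter through single conditional
  imputations and are flagged — their residuals are simulation-based
  quantities, not data.
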