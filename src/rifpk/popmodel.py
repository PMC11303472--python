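"""Population model: fixed effects, covariates, IIV/IOV, residual error, censored likelihood.

Individual parameters are log-normal around covariate-adjusted typical values:

    P_i,occ = theta_P * covariate_factor_P(i) * exp(eta_P,i + kappa_P,i,occ)

with subject-level effects ``eta ~ N(0, omega^2)`` (inter-individual
variability, IIV) and occasion-level effects ``kappa ~ N(0, gamma^2)``
(inter-occasion variability, IOV), independent across occasions.  The IOV
effects on Tlag and Tk0 are jointly normal with correlation ``rho``.  Km never
carries a random effect in the shipped models.

Variabilities are reported as CV%; by default the exact log-normal relation
``omega = sqrt(log(1 + (cv/100)^2))`` is used (the linear approximation
``omega = cv/100`` is available as a convention switch, relevant at the
printed CVs of up to 67%).

The residual model is combined additive + proportional,
``g = a + b*f`` ("combined1"); observations below the limit of
quantification are interval-censored on ``[0, LLOQ)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .covariates import CovariateEffect, covariate_log_offset
from .structural import PRIMARY_VARIANT, StructuralParams, StructuralVariant

__all__ = [
    "PARAM_ORDER",
    "PopulationModel",
    "IndividualEffects",
    "individual_params",
    "cv_to_omega",
    "omega_to_cv",
    "residual_sd",
    "obs_loglik",
]

#: occasion-level parameter order used throughout the package
PARAM_ORDER = ("Tlag", "Tk0", "V", "Vmax")


def cv_to_omega(cv_percent: float, exact: bool = True) -> float:
    """Log-scale SD from a coefficient of variation in percent."""
    if cv_percent < 0:
        raise ValueError("cv_percent must be nonnegative")
    cv = cv_percent / 100.0
    return math.sqrt(math.log1p(cv * cv)) if exact else cv


def omega_to_cv(omega: float, exact: bool = True) -> float:
    """Coefficient of variation in percent from a log-scale SD."""
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    return 100.0 * (math.sqrt(math.expm1(omega * omega)) if exact else omega)


def residual_sd(pred, a: float, b: float, error_model: str = "combined1"):
    """Residual SD at a predicted concentration: g = a + b*f (combined1).

    The "combined2" convention ``sqrt(a^2 + (b*f)^2)`` is available as a
    switch.
    """
    pred = np.asarray(pred, dtype=float)
    if error_model == "combined1":
        out = a + b * pred
    elif error_model == "combined2":
        out = np.sqrt(a * a + (b * pred) ** 2)
    else:
        raise ValueError(f"unknown error model {error_model!r}")
    return float(out) if out.ndim == 0 else out


def obs_loglik(
    dv,
    cens,
    pred,
    a: float,
    b: float,
    lloq: float = 0.1,
    error_model: str = "combined1",
    log_floor: float = -700.0,
):
    """Log-density of one (or many) observations under the censored model.

    Uncensored rows contribute ``log N(dv; pred, g^2)``; censored rows the
    Gaussian probability mass on the interval ``[0, LLOQ)`` (concentrations
    cannot be negative, so the censoring interval is bounded below at zero).
    Interval probabilities that underflow are floored at ``exp(log_floor)``.
    """
    dv = np.atleast_1d(np.asarray(dv, dtype=float))
    cens = np.atleast_1d(np.asarray(cens, dtype=int))
    pred = np.atleast_1d(np.asarray(pred, dtype=float))
    g = np.maximum(residual_sd(pred, a, b, error_model), 1e-10)
    out = np.empty_like(dv)
    unc = cens == 0
    out[unc] = norm.logpdf(dv[unc], loc=pred[unc], scale=np.atleast_1d(g)[unc])
    if np.any(~unc):
        gc = np.atleast_1d(g)[~unc]
        pc = pred[~unc]
        pmass = norm.cdf((lloq - pc) / gc) - norm.cdf((0.0 - pc) / gc)
        out[~unc] = np.log(np.maximum(pmass, math.exp(log_floor)))
    return float(out[0]) if out.size == 1 else out


@dataclass(frozen=True)
class IndividualEffects:
    """Random effects for one subject: eta (per subject), kappa (per occasion)."""

    eta: Mapping[str, float]
    kappa: Sequence[Mapping[str, float]]


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, covariate submodels, variance structure and error model."""

    theta: Mapping[str, float]
    covariate_effects: tuple[CovariateEffect, ...] = ()
    iiv_cv: Mapping[str, float] = field(default_factory=dict)
    iov_cv: Mapping[str, float] = field(default_factory=dict)
    corr_iov_tlag_tk0: float = 0.0
    error_a: float = 0.06
    error_b: float = 0.11
    lloq: float = 0.1
    variant: StructuralVariant = PRIMARY_VARIANT
    cv_exact: bool = True
    error_model: str = "combined1"
    name: str = ""

    def __post_init__(self):
        missing = {"Tlag", "Tk0", "V", "Vmax", "Km"} - set(self.theta)
        if missing:
            raise ValueError(f"theta missing entries: {sorted(missing)}")
        for d in (self.iiv_cv, self.iov_cv):
            if "Km" in d:
                raise ValueError("Km cannot carry a random effect")
            for p, cv in d.items():
                if p not in PARAM_ORDER:
                    raise ValueError(f"unknown random-effect parameter {p!r}")
                if cv < 0:
                    raise ValueError("CV% must be nonnegative")
        if not -1.0 < self.corr_iov_tlag_tk0 < 1.0:
            raise ValueError("correlation must lie in (-1, 1)")
        if self.error_a < 0 or self.error_b < 0 or (
            self.error_a == 0 and self.error_b == 0
        ):
            raise ValueError("error parameters must be nonnegative, not both zero")
        if self.lloq <= 0:
            raise ValueError("lloq must be positive")
        object.__setattr__(self, "covariate_effects", tuple(self.covariate_effects))
        object.__setattr__(self, "theta", dict(self.theta))
        object.__setattr__(self, "iiv_cv", dict(self.iiv_cv))
        object.__setattr__(self, "iov_cv", dict(self.iov_cv))

    # ---- variance structure -------------------------------------------
    def omega(self, param: str) -> float:
        return cv_to_omega(self.iiv_cv.get(param, 0.0), self.cv_exact)

    def gamma(self, param: str) -> float:
        return cv_to_omega(self.iov_cv.get(param, 0.0), self.cv_exact)

    def iiv_block(self) -> np.ndarray:
        """4x4 covariance of eta over PARAM_ORDER (diagonal)."""
        return np.diag([self.omega(p) ** 2 for p in PARAM_ORDER])

    def iov_block(self) -> np.ndarray:
        """4x4 covariance of kappa within one occasion (rho couples Tlag, Tk0)."""
        g = np.array([self.gamma(p) for p in PARAM_ORDER])
        blk = np.diag(g**2)
        blk[0, 1] = blk[1, 0] = self.corr_iov_tlag_tk0 * g[0] * g[1]
        return blk

    def sigma(self, n_occasions: int = 2, floor: float = 1e-10) -> np.ndarray:
        """Joint covariance of stacked per-occasion log-parameters (D = 4*n_occ)."""
        h = self.iiv_block()
        within = h + self.iov_block()
        d = 4 * n_occasions
        sig = np.zeros((d, d))
        for o1 in range(n_occasions):
            for o2 in range(n_occasions):
                sig[o1 * 4:(o1 + 1) * 4, o2 * 4:(o2 + 1) * 4] = (
                    within if o1 == o2 else h
                )
        sig[np.diag_indices(d)] = np.maximum(np.diag(sig), floor)
        return sig

    # ---- covariates ----------------------------------------------------
    def log_offsets(self, cov: Mapping[str, object]) -> np.ndarray:
        """Covariate log-offsets c_P for PARAM_ORDER, one subject-occasion."""
        return np.array(
            [covariate_log_offset(self.covariate_effects, p, cov) for p in PARAM_ORDER]
        )

    def has_unresolved_references(self) -> bool:
        return any(
            s.form == "power" and s.reference is None for s in self.covariate_effects
        )

    def resolve_references(self, references: Mapping[str, float]) -> "PopulationModel":
        """Fill in power-term normalization constants (observation-weighted means)."""
        specs = tuple(
            s.resolved(float(references[s.covariate]))
            if s.form == "power" and s.reference is None
            else s
            for s in self.covariate_effects
        )
        return replace(self, covariate_effects=specs)

    # ---- parameter bookkeeping ----------------------------------------
    def n_fixed_params(self) -> int:
        """Estimated fixed effects + free covariate betas + error parameters."""
        n_theta = 5 if self.variant.elimination == "mm" else 4
        if not self.variant.lag:
            n_theta -= 1
        n_beta = sum(1 for s in self.covariate_effects if not s.fixed)
        n_err = (self.error_a > 0) + (self.error_b > 0)
        return n_theta + n_beta + n_err

    def n_random_params(self) -> int:
        """Estimated variance components + correlations."""
        n = sum(1 for cv in self.iiv_cv.values() if cv > 0)
        n += sum(1 for cv in self.iov_cv.values() if cv > 0)
        n += 1 if self.corr_iov_tlag_tk0 != 0 else 0
        return n


def individual_params(
    model: PopulationModel,
    cov: Mapping[str, object],
    eff: IndividualEffects,
    occasion: int = 1,
) -> StructuralParams:
    """Map population parameters + covariates + random effects to one
    subject-occasion's structural parameters."""
    if not 1 <= occasion <= len(eff.kappa):
        raise ValueError(f"occasion {occasion} outside effects ({len(eff.kappa)})")
    kap = eff.kappa[occasion - 1]
    offs = model.log_offsets(cov)
    vals = {}
    for j, p in enumerate(PARAM_ORDER):
        vals[p] = model.theta[p] * math.exp(
            offs[j] + eff.eta.get(p, 0.0) + kap.get(p, 0.0)
        )
    km_off = covariate_log_offset(model.covariate_effects, "Km", cov)
    vals["Km"] = model.theta["Km"] * math.exp(km_off)
    return StructuralParams(**vals)


def draw_effects(
    model: PopulationModel, n_subjects: int, n_occasions: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample eta (n_subjects, 4) and kappa (n_subjects, n_occ, 4) arrays."""
    omega = np.array([model.omega(p) for p in PARAM_ORDER])
    eta = rng.standard_normal((n_subjects, 4)) * omega
    gblk = model.iov_block()
    z = rng.standard_normal((n_subjects, n_occasions, 4))
    diag_max = float(np.diag(gblk).max())
    if diag_max == 0.0:
        kappa = np.zeros_like(z)
    else:
        # relative jitter keeps the factorization stable without injecting
        # phantom variability into zero-IOV components
        chol = np.linalg.cholesky(gblk + np.eye(4) * 1e-12 * diag_max)
        kappa = z @ chol.T
    return eta, kappa
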