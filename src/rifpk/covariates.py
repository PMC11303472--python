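"""Body-size descriptors and covariate submodels for PK parameters.

Continuous covariates act multiplicatively on a population parameter through
power models normalized by a reference value (the observation-weighted mean of
the fitted dataset),

    PK_i = PK_pop * (COV_i / COV_ref) ** beta,

and categorical covariates act as a multiplicative factor ``exp(beta)`` for the
non-reference level (females are the reference sex).  Fat-free mass uses the
semi-mechanistic sex-specific prediction from body weight and BMI
(Janmahasatian model); body surface area uses the Mosteller formula.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ffm",
    "bsa_mosteller",
    "weighted_mean",
    "CovariateEffect",
    "apply_covariates",
    "covariate_log_offset",
]

# Janmahasatian fat-free-mass coefficients: FFM = 9270*BW / (c1 + c2*BMI)
_FFM_COEF = {
    "male": (9.27e3, 6.68e3, 216.0),
    "female": (9.27e3, 8.78e3, 244.0),
}


def ffm(sex: str, bw, bmi):
    """Fat-free mass (kg) from sex, body weight (kg) and BMI (kg/m^2)."""
    if sex not in _FFM_COEF:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    bw = np.asarray(bw, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    if np.any(bw < 0) or np.any(bmi <= 0):
        raise ValueError("ffm requires bw >= 0 and bmi > 0")
    num, c1, c2 = _FFM_COEF[sex]
    out = num * bw / (c1 + c2 * bmi)
    return float(out) if out.ndim == 0 else out


def bsa_mosteller(bw, bh_m):
    """Body surface area (m^2), Mosteller: sqrt(BH_cm * BW / 3600).

    Height is accepted in meters (as reported) and converted to cm internally.
    """
    bw = np.asarray(bw, dtype=float)
    bh_m = np.asarray(bh_m, dtype=float)
    if np.any(bw <= 0) or np.any(bh_m <= 0):
        raise ValueError("bsa_mosteller requires bw > 0 and bh > 0")
    out = np.sqrt(bh_m * 100.0 * bw / 3600.0)
    return float(out) if out.ndim == 0 else out


def weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    """Average of per-subject covariate values weighted by observations per subject."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("weighted_mean of empty input")
    if values.shape != weights.shape:
        raise ValueError("values and weights must have the same length")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(weights * values) / np.sum(weights))


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate term on one structural parameter.

    Parameters
    ----------
    parameter:
        Structural parameter the term acts on (``V``, ``Vmax``, ``Tlag``,
        ``Tk0`` or ``Km``).
    covariate:
        Covariate name (``FFM``, ``BW``, ``BH``, ``BSA``, ``BMI``, ``age``,
        ``sex``, ``preparation``).
    form:
        ``"power"`` (continuous, weighted-mean normalized) or
        ``"categorical"`` (multiplicative ``exp(beta)`` off the reference
        level).
    beta:
        Exponent (power) or log-scale coefficient (categorical).
    reference:
        Normalization constant for power terms (``None`` means "resolve from
        the dataset's observation-weighted mean"), or the reference level for
        categorical terms (``"female"``, ``"reference"``).
    fixed:
        Whether ``beta`` is held fixed during estimation.
    """

    parameter: str
    covariate: str
    form: str = "power"
    beta: float = 1.0
    reference: float | str | None = None
    fixed: bool = True

    def __post_init__(self):
        if self.form not in ("power", "categorical"):
            raise ValueError(f"unknown covariate form {self.form!r}")

    def resolved(self, reference) -> "CovariateEffect":
        return replace(self, reference=reference)

    def log_factor(self, cov: Mapping[str, object]) -> float:
        """log of the multiplicative factor this term contributes for one subject."""
        if self.covariate not in cov:
            raise KeyError(
                f"covariate {self.covariate!r} (term on {self.parameter}) "
                "missing from subject covariates"
            )
        value = cov[self.covariate]
        if self.form == "power":
            if self.reference is None:
                raise ValueError(
                    f"unresolved reference for power term {self.covariate} on "
                    f"{self.parameter}; resolve against a dataset first"
                )
            value = float(value)
            ref = float(self.reference)
            if value <= 0 or ref <= 0:
                raise ValueError(
                    f"power covariate {self.covariate} requires positive values"
                )
            return self.beta * np.log(value / ref)
        # categorical: exp(beta) off the reference level
        ref = self.reference if self.reference is not None else "female"
        return self.beta * (0.0 if value == ref else 1.0)


def covariate_log_offset(
    specs: Sequence[CovariateEffect], parameter: str, cov: Mapping[str, object]
) -> float:
    """Summed log-scale covariate offset for one parameter and one subject."""
    return float(sum(s.log_factor(cov) for s in specs if s.parameter == parameter))


def apply_covariates(
    pop_value: float, specs: Sequence[CovariateEffect], cov: Mapping[str, object]
) -> float:
    """Individual typical value: population value times all covariate factors.

    The composition is multiplicative, so terms can be applied jointly or one
    at a time in any order.
    """
    log_fac = sum(s.log_factor(cov) for s in specs)
    return float(pop_value * np.exp(log_fac))
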