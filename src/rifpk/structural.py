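"""Single-dose structural model: lagged zero-order input, Michaelis-Menten elimination.

The drug amount in the (single) central compartment follows

    dA/dt = rate_in(t) - Vmax * C / (Km + C),      C = A / V,

with ``rate_in = dose/Tk0`` on ``(Tlag, Tlag + Tk0]`` and zero elsewhere.
``Tk0`` is the *duration* of the zero-order input; all parameters are apparent
oral quantities (V/F, Vmax/F) with bioavailability fixed at 1 internally.

Two computational routes are provided and tested against each other:

* :func:`predict_conc` — adaptive ``scipy.integrate.solve_ivp`` with the
  integration restarted at both input discontinuities (the reference route);
* :func:`predict_conc_fast` — fixed-step RK4 across the input window plus the
  exact Lambert-W closed form of post-absorption MM decay (the route used
  inside estimation and simulation loops).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels as K

__all__ = [
    "StructuralParams",
    "StructuralVariant",
    "ConcProfile",
    "predict_conc",
    "predict_conc_fast",
    "auc",
    "AUCDivergenceError",
]


class AUCDivergenceError(ArithmeticError):
    """Raised when AUC(0, inf) does not exist (no elimination)."""


@dataclass(frozen=True)
class StructuralParams:
    """Individual-level PK parameters for one subject-occasion.

    Tlag and Tk0 in hours, V in liters (V/F), Vmax in mg/h (Vmax/F),
    Km in mg/L.
    """

    Tlag: float
    Tk0: float
    V: float
    Vmax: float
    Km: float

    def __post_init__(self):
        for name in ("Tlag", "Tk0", "V", "Km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.Vmax < 0:
            raise ValueError("Vmax must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.Tlag, self.Tk0, self.V, self.Vmax, self.Km])


@dataclass(frozen=True)
class StructuralVariant:
    """One-compartment model family member for the base-model catalogue.

    absorption: "zero" (Tk0 = input duration) or "first" (Tk0 slot = ka, 1/h).
    elimination: "mm" (Vmax, Km) or "linear" (Vmax slot = CL, L/h; Km unused).
    """

    absorption: str = "zero"
    lag: bool = True
    elimination: str = "mm"

    def __post_init__(self):
        if self.absorption not in ("zero", "first"):
            raise ValueError("absorption must be 'zero' or 'first'")
        if self.elimination not in ("mm", "linear"):
            raise ValueError("elimination must be 'mm' or 'linear'")

    @property
    def flags(self) -> tuple[int, int, int]:
        return (
            1 if self.absorption == "zero" else 0,
            1 if self.lag else 0,
            1 if self.elimination == "mm" else 0,
        )

    def label(self) -> str:
        return (
            f"{'lag' if self.lag else 'nolag'}-{self.absorption}-order-"
            f"{self.elimination}"
        )


PRIMARY_VARIANT = StructuralVariant("zero", True, "mm")


@dataclass(frozen=True)
class ConcProfile:
    times: np.ndarray
    conc: np.ndarray


def _rhs(t, a, params: StructuralParams, dose: float):
    tlag, tk0, v, vmax, km = (
        params.Tlag, params.Tk0, params.V, params.Vmax, params.Km,
    )
    c = max(a[0], 0.0) / v
    rate = dose / tk0 if tlag < t <= tlag + tk0 else 0.0
    return [rate - vmax * c / (km + c)]


def _jac(t, a, params: StructuralParams, dose: float):
    v, vmax, km = params.V, params.Vmax, params.Km
    c = max(a[0], 0.0) / v
    return [[-vmax * km / (v * (km + c) ** 2)]]


def predict_conc(
    params: StructuralParams,
    dose: float,
    times,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> ConcProfile:
    """Solve the structural ODE at the requested times (reference route).

    Integration restarts at ``Tlag`` and ``Tlag + Tk0`` so that the adaptive
    stepper never straddles an input discontinuity.
    """
    times = np.asarray(times, dtype=float)
    if dose <= 0:
        raise ValueError("dose must be positive")
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    breaks = [params.Tlag, params.Tlag + params.Tk0]
    conc = np.zeros_like(t_sorted)
    a0 = 0.0
    t0 = 0.0
    segments = [*breaks, max(float(t_sorted[-1]) if t_sorted.size else 0.0, breaks[-1])]
    for t1 in segments:
        if t1 <= t0:
            continue
        mask = (t_sorted > t0 + 1e-15) & (t_sorted <= t1 + 1e-15)
        t_eval = t_sorted[mask]
        sol = solve_ivp(
            _rhs,
            (t0, t1),
            [a0],
            method="LSODA",
            jac=_jac,
            t_eval=np.unique(np.concatenate([t_eval, [t1]])),
            rtol=rtol,
            atol=atol,
            args=(params, dose),
        )
        if not sol.success:  # pragma: no cover - defensive
            raise ArithmeticError(
                f"ODE solver failed for params {params}: {sol.message}"
            )
        if t_eval.size:
            # map each requested time onto the solver grid
            idx = np.searchsorted(sol.t, t_eval)
            conc[mask] = sol.y[0][idx] / params.V
        a0 = sol.y[0][-1]
        t0 = t1
    conc[t_sorted <= params.Tlag + 1e-15] = 0.0
    conc = np.maximum(conc, 0.0)
    out = np.empty_like(conc)
    out[order] = conc
    return ConcProfile(times=times, conc=out)


def predict_conc_fast(
    params: StructuralParams, dose: float, times
) -> ConcProfile:
    """Semi-analytic route (RK4 input window + Lambert-W MM decay)."""
    times = np.asarray(times, dtype=float)
    if dose <= 0:
        raise ValueError("dose must be positive")
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    out = np.empty_like(times)
    K._conc_zero_mm(
        times, times.shape[0], params.Tlag, params.Tk0, params.V, params.Vmax,
        params.Km, dose, out,
    )
    return ConcProfile(times=times, conc=out)


def auc(params: StructuralParams, dose: float, t_end: float = np.inf) -> float:
    """Area under the concentration-time curve to ``t_end`` (default infinity).

    The absorption window is integrated by composite Simpson quadrature on the
    RK4 grid; the post-absorption MM segment contributes its closed form
    ``(V/Vmax) * (Km*(C1 - C2) + (C1^2 - C2^2)/2)``.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    if t_end < 0:
        raise ValueError("t_end must be nonnegative")
    if np.isinf(t_end) and params.Vmax <= 0:
        raise AUCDivergenceError(
            "AUC(0, inf) diverges: Vmax = 0 means no elimination"
        )
    val = K._auc_zero_mm(
        params.Tlag, params.Tk0, params.V, params.Vmax, params.Km, dose,
        float(t_end),
    )
    if not np.isfinite(val):
        raise AUCDivergenceError("AUC integration diverged")
    return float(val)
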