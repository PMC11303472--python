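"""Stochastic approximation EM for the censored nonlinear mixed-effects model.

The latent variables are the stacked per-occasion individual log-parameters
``psi_i = (log Tlag, log Tk0, log V, log Vmax)_{occ=1..n}``, Gaussian around
covariate-adjusted population means with the IIV/IOV covariance structure of
:class:`~rifpk.popmodel.PopulationModel`.  Each iteration runs a
Metropolis-within-Gibbs sweep (independent prior draws, componentwise and
joint random walks) over every subject's psi, imputes the BQL observations
from the Gaussian residual model truncated to [0, LLOQ), and performs
stochastic-approximation M-step updates:

* population means and free covariate coefficients — closed-form least
  squares on the smoothed psi statistics;
* variance components — structured moment matching on the smoothed
  within-/cross-occasion second moments (with nonnegativity clamps);
* Km (no random effect) — smoothed 1-D argmin of the complete-data
  log-likelihood;
* residual-error (a, b) — 2-D minimization of the smoothed heteroscedastic
  Gaussian pseudo-likelihood.

Step size is 1 during exploration and ``k**(-0.7)`` during smoothing.
The marginal likelihood (OFV = -2 log L) is computed afterwards by
importance sampling with a defensive mixture proposal: a multivariate t at
each subject's empirical conditional mean and covariance (accumulated
during the smoothing phase) mixed with a share of prior draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.special import ndtr, ndtri

from . import _kernels as K
from .dataio import EventTable
from .popmodel import PARAM_ORDER, PopulationModel, cv_to_omega, omega_to_cv

__all__ = ["SAEMSettings", "FitResult", "FitData", "fit_saem", "ofv", "bicc",
           "EstimationError", "ConfigError"]


class EstimationError(RuntimeError):
    pass


class ConfigError(ValueError):
    pass


@dataclass
class SAEMSettings:
    """SAEM schedule and Monte Carlo sizes.

    n_burnin iterations adapt the MH proposals without touching statistics;
    n_explore iterations use step size 1; n_smooth iterations decrease the
    step as k**(-step_exponent).
    """

    n_burnin: int = 50
    n_explore: int = 500
    n_smooth: int = 300
    n_chains: int = 2
    step_exponent: float = 0.7
    adapt_target: float = 0.3
    ofv_mc_size: int = 2000
    convergence_window: int = 60
    init_error_a: float = 0.1
    init_error_b: float = 0.15
    init_cv: float = 30.0
    nls_init: bool = True
    warm_start: bool = False  # take all numeric starting values from model0
    fix: frozenset = field(default_factory=frozenset)
    seed: int = 1234

    def __post_init__(self):
        if min(self.n_burnin, self.n_explore, self.n_smooth) < 0 or (
            self.n_explore + self.n_smooth == 0
        ):
            raise ConfigError("iteration counts must be positive")
        if not 0.5 < self.step_exponent <= 1.0:
            raise ConfigError("step_exponent must lie in (0.5, 1]")
        if self.n_chains < 1:
            raise ConfigError("need at least one chain")
        self.fix = frozenset(self.fix)


class FitData:
    """Dense per-(subject, occasion) arrays consumed by the numba kernels."""

    def __init__(self, table: EventTable):
        df = table.df
        self.lloq = table.lloq
        self.subject_ids = table.subjects
        self.ns = len(self.subject_ids)
        occs = sorted(df["OCC"].unique())
        self.nocc = len(occs)
        self.covs = table.covariates()
        kmax = 0
        per = {}
        for (sid, occ), grp in df.groupby(["ID", "OCC"], sort=False):
            dose_rows = grp[grp["EVID"] == 1]
            t_dose = float(dose_rows["TIME"].iloc[0])
            amt = float(dose_rows["AMT"].iloc[0])
            obs = grp[grp["EVID"] == 0]
            per[(sid, occ)] = (
                obs["TIME"].to_numpy(float) - t_dose,
                obs["DV"].to_numpy(float),
                obs["CENS"].to_numpy(np.int64),
                amt,
            )
            kmax = max(kmax, len(obs))
        self.kmax = kmax
        self.times = np.zeros((self.ns, self.nocc, kmax))
        self.y = np.zeros((self.ns, self.nocc, kmax))
        self.cens = np.zeros((self.ns, self.nocc, kmax), dtype=np.int64)
        self.nobs = np.zeros((self.ns, self.nocc), dtype=np.int64)
        self.dose = np.zeros((self.ns, self.nocc))
        for i, sid in enumerate(self.subject_ids):
            for o, occ in enumerate(occs):
                if (sid, occ) not in per:
                    continue
                tt, yy, cc, amt = per[(sid, occ)]
                n = len(tt)
                self.times[i, o, :n] = tt
                self.y[i, o, :n] = yy
                self.cens[i, o, :n] = cc
                self.nobs[i, o] = n
                self.dose[i, o] = amt
        self.mask = np.zeros((self.ns, self.nocc, kmax), dtype=bool)
        for i in range(self.ns):
            for o in range(self.nocc):
                self.mask[i, o, : self.nobs[i, o]] = True
        self.n_obs_total = int(self.nobs.sum())

    def cov_dicts(self) -> list[list[dict]]:
        """Per-subject, per-occasion covariate mappings."""
        out = []
        for sid in self.subject_ids:
            sc = self.covs[sid]
            out.append([sc.as_dict(o + 1) for o in range(self.nocc)])
        return out


@dataclass
class FitResult:
    """SAEM estimates, uncertainty, objective function and EBEs."""

    model: PopulationModel
    theta: dict
    theta_rse: dict
    iiv_cv: dict
    iov_cv: dict
    corr_iov_tlag_tk0: float
    error_a: float
    error_b: float
    ofv: float
    ofv_se: float
    bicc: float
    converged: bool
    trajectory: pd.DataFrame
    ebe: pd.DataFrame
    psi_mean: np.ndarray
    psi_var: np.ndarray
    psi_cov: np.ndarray
    prior_mean: np.ndarray
    n_obs: int
    n_subjects: int
    seed: int

    def summary(self) -> pd.DataFrame:
        rows = [
            {"parameter": p, "estimate": self.theta[p],
             "rse_pct": self.theta_rse.get(p, float("nan"))}
            for p in ("Tlag", "Tk0", "V", "Vmax", "Km")
        ]
        for p, cv in self.iiv_cv.items():
            rows.append({"parameter": f"IIV {p} (CV%)", "estimate": cv,
                         "rse_pct": float("nan")})
        for p, cv in self.iov_cv.items():
            rows.append({"parameter": f"IOV {p} (CV%)", "estimate": cv,
                         "rse_pct": float("nan")})
        rows.append({"parameter": "corr IOV Tlag-Tk0",
                     "estimate": self.corr_iov_tlag_tk0, "rse_pct": float("nan")})
        rows.append({"parameter": "additive error (mg/L)",
                     "estimate": self.error_a, "rse_pct": float("nan")})
        rows.append({"parameter": "proportional error (%)",
                     "estimate": 100 * self.error_b, "rse_pct": float("nan")})
        rows.append({"parameter": "OFV", "estimate": self.ofv,
                     "rse_pct": float("nan")})
        rows.append({"parameter": "BICc", "estimate": self.bicc,
                     "rse_pct": float("nan")})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _design(model: PopulationModel, fd: FitData):
    """Fixed covariate offsets and free-beta design columns per parameter.

    Returns (off_fixed[ns,nocc,4], free: dict p_idx -> list of (spec, x[ns,nocc])).
    """
    cd = fd.cov_dicts()
    off = np.zeros((fd.ns, fd.nocc, 4))
    free: dict[int, list] = {}
    for s in model.covariate_effects:
        if s.parameter == "Km":
            if not s.fixed:
                raise ConfigError("free covariate coefficients on Km are not "
                                  "supported (Km carries no random effect)")
            continue
        j = PARAM_ORDER.index(s.parameter)
        x = np.zeros((fd.ns, fd.nocc))
        for i in range(fd.ns):
            for o in range(fd.nocc):
                # log_factor = beta * basis; recover the basis with beta=1
                x[i, o] = replace(s, beta=1.0).log_factor(cd[i][o])
        if s.fixed:
            off[:, :, j] += s.beta * x
        else:
            free.setdefault(j, []).append([s, x])
    km_off = np.zeros(fd.ns)
    for s in model.covariate_effects:
        if s.parameter == "Km":
            for i in range(fd.ns):
                km_off[i] = s.log_factor(cd[i][0])
    if np.any(km_off != 0):
        raise ConfigError("covariates on Km are not supported by fit_saem")
    return off, free


def _prior_means(mu: np.ndarray, off: np.ndarray, free: dict, betas: dict):
    m = mu[None, None, :] + off
    for j, terms in free.items():
        for t_i, (_spec, x) in enumerate(terms):
            m[:, :, j] = m[:, :, j] + betas[(j, t_i)] * x
    return m


def _pooled_nls(fd: FitData, model: PopulationModel, off: np.ndarray,
                ltheta0: np.ndarray) -> np.ndarray:
    """Naive pooled nonlinear least squares on the uncensored observations."""
    flags = model.variant.flags
    unc = fd.mask & (fd.cens == 0)
    yobs = fd.y[unc]
    if len(yobs) < 6:
        return ltheta0

    def resid(lth):
        lpsi = np.empty((1, fd.ns, fd.nocc, 4))
        lpsi[0] = lth[None, None, :4] + off
        preds = np.zeros((1, fd.ns, fd.nocc, fd.kmax))
        K._predict_all(lpsi, lth[4], fd.times, fd.nobs, fd.dose, *flags, preds)
        f = preds[0][unc]
        return (yobs - f) / (0.1 + 0.11 * f)

    # pooled LS on data with inter-occasion variability can collapse the lag
    # to zero; keep the refinement within a decade of the starting point
    lb = ltheta0 - math.log(10.0)
    ub = ltheta0 + math.log(10.0)
    try:
        sol = least_squares(resid, ltheta0, method="trf", bounds=(lb, ub),
                            max_nfev=300)
        if np.all(np.isfinite(sol.x)):
            return sol.x
    except Exception:
        pass
    return ltheta0


def _impute_censored(rng, preds, y, cens_mask, a, b, lloq):
    """Draw BQL observations from the residual model truncated to [0, LLOQ)."""
    out = y.copy()
    f = preds[cens_mask]
    g = np.maximum(a + b * f, 1e-10)
    lo = ndtr((0.0 - f) / g)
    hi = ndtr((lloq - f) / g)
    u = lo + rng.random(f.shape) * np.maximum(hi - lo, 1e-14)
    u = np.clip(u, 1e-13, 1.0 - 1e-13)
    out[cens_mask] = np.clip(f + g * ndtri(u), 0.0, lloq)
    return out


def _error_update(S_f, S_r2, a0, b0, fix_a, fix_b, maxiter=30):
    """Minimize the smoothed heteroscedastic Gaussian pseudo-likelihood.

    Warm-started at the current values; a short Nelder-Mead is enough because
    the update runs every iteration.
    """

    def obj(la_lb):
        a = math.exp(la_lb[0]) if not fix_a else a0
        b = math.exp(la_lb[1]) if not fix_b else b0
        g = np.maximum(a + b * S_f, 1e-10)
        return float(np.sum(np.log(g) + S_r2 / (2.0 * g * g)))

    if fix_a and fix_b:
        return a0, b0
    x0 = [math.log(max(a0, 1e-8)), math.log(max(b0, 1e-8))]
    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 2e-4, "fatol": 1e-8})
    a = math.exp(res.x[0]) if not fix_a else a0
    b = math.exp(res.x[1]) if not fix_b else b0
    return min(a, 1e3), min(b, 10.0)


def _approx_theta_rse(fd, model, m, lkm, a, b):
    """Crude relative standard errors of the fixed effects via a linearized
    (first-order) Fisher information at the population prediction.

    The nonparametric bootstrap in the diagnostics module is the reference
    uncertainty method; these RSEs are indicative only.
    """
    flags = model.variant.flags
    names = list(PARAM_ORDER) + ["Km"]
    h = 1e-4
    base = np.zeros((1, fd.ns, fd.nocc, fd.kmax))
    lpsi = m[None].copy()
    K._predict_all(lpsi, lkm, fd.times, fd.nobs, fd.dose, *flags, base)
    cols = []
    for j in range(5):
        pert = np.zeros((1, fd.ns, fd.nocc, fd.kmax))
        if j < 4:
            K._predict_all(lpsi + h * (np.arange(4) == j), lkm,
                           fd.times, fd.nobs, fd.dose, *flags, pert)
        else:
            K._predict_all(lpsi, lkm + h, fd.times, fd.nobs, fd.dose,
                           *flags, pert)
        cols.append(((pert - base)[0][fd.mask]) / h)
    jac = np.column_stack(cols)
    g = np.maximum(a + b * base[0][fd.mask], 1e-10)
    w = 1.0 / (g * g)
    fim = jac.T @ (jac * w[:, None])
    try:
        cov = np.linalg.inv(fim + np.eye(5) * 1e-12)
        se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_log = np.full(5, np.nan)
    return {nm: 100.0 * se_log[j] for j, nm in enumerate(names)}


# ---------------------------------------------------------------------------
# main driver
# ---------------------------------------------------------------------------

def fit_saem(table: EventTable, model0: PopulationModel,
             settings: SAEMSettings | None = None,
             compute_ofv: bool = True) -> FitResult:
    """Fit the population model to an event table by SAEM.

    ``model0`` supplies the model structure (variant, covariate terms,
    which parameters carry IIV/IOV, correlation structure) and starting
    points; numeric initial values follow the package defaults (pooled NLS
    for the fixed effects, 30 CV% variances, rho = 0) unless disabled via
    ``settings``.
    """
    st = settings or SAEMSettings()
    fd = FitData(table)
    model = model0
    if model.has_unresolved_references():
        model = model.resolve_references(table.reference_values())
    if model.lloq != table.lloq:
        model = replace(model, lloq=table.lloq)

    var_fixed = {"omega", "gamma", "rho"} <= st.fix
    if fd.ns < 2 and not var_fixed:
        raise ConfigError("need >= 2 subjects unless all variances are fixed")
    has_iiv = {p: p in model.iiv_cv for p in PARAM_ORDER}
    has_iov = {p: p in model.iov_cv for p in PARAM_ORDER}
    # a model without any random effect degenerates to a pooled fit: the
    # latent psi stay pinned at the (floored) prior and the NLS/ridge/error
    # updates carry the whole estimation
    est_rho = (has_iov["Tlag"] and has_iov["Tk0"] and "rho" not in st.fix)

    flags = model.variant.flags
    off, free = _design(model, fd)

    # ---- numeric initialization ---------------------------------------
    ltheta = np.log([model.theta[p] for p in list(PARAM_ORDER) + ["Km"]])
    betas = {}
    for j, terms in free.items():
        for t_i, (spec, _x) in enumerate(terms):
            betas[(j, t_i)] = spec.beta
    if st.nls_init and not st.warm_start:
        ltheta = _pooled_nls(fd, model, off, ltheta)
    mu = ltheta[:4].copy()
    lkm = float(ltheta[4])

    if st.warm_start or "omega" in st.fix:
        omega2 = np.array([model.omega(p) ** 2 for p in PARAM_ORDER])
    else:
        omega2 = np.array([
            cv_to_omega(st.init_cv, model.cv_exact) ** 2 if has_iiv[p] else 0.0
            for p in PARAM_ORDER
        ])
    if st.warm_start or "gamma" in st.fix:
        gamma2 = np.array([model.gamma(p) ** 2 for p in PARAM_ORDER])
    else:
        gamma2 = np.array([
            cv_to_omega(st.init_cv, model.cv_exact) ** 2 if has_iov[p] else 0.0
            for p in PARAM_ORDER
        ])
    if st.warm_start or "rho" in st.fix:
        rho = model.corr_iov_tlag_tk0
    else:
        rho = 0.0
    a = model.error_a if (st.warm_start or "error_a" in st.fix) \
        else st.init_error_a
    b = model.error_b if (st.warm_start or "error_b" in st.fix) \
        else st.init_error_b

    nocc, ns, nc = fd.nocc, fd.ns, st.n_chains
    d = 4 * nocc

    def build_sigma():
        h_blk = np.diag(omega2)
        g_blk = np.diag(gamma2)
        g_blk[0, 1] = g_blk[1, 0] = rho * math.sqrt(gamma2[0] * gamma2[1])
        within = h_blk + g_blk
        sig = np.zeros((d, d))
        for o1 in range(nocc):
            for o2 in range(nocc):
                sig[o1 * 4:(o1 + 1) * 4, o2 * 4:(o2 + 1) * 4] = (
                    within if o1 == o2 else h_blk
                )
        sig[np.diag_indices(d)] = np.maximum(np.diag(sig), 1e-10)
        chol = np.linalg.cholesky(sig)
        prec = np.linalg.inv(sig)
        return sig, chol, prec

    sigma, chol, prec = build_sigma()
    m = _prior_means(mu, off, free, betas)

    rng = np.random.default_rng(st.seed)
    lpsi = np.tile(m[None], (nc, 1, 1, 1)) + 0.05 * rng.standard_normal(
        (nc, ns, nocc, 4))
    ll_occ = np.zeros((nc, ns, nocc))
    K._all_occ_loglik(lpsi, lkm, fd.times, fd.y, fd.cens, fd.nobs, fd.dose,
                      a, b, fd.lloq, *flags, ll_occ)

    rw_scales = 0.4 * np.sqrt(np.tile(np.maximum(np.diag(sigma)[:4], 1e-6), nocc))
    rw_joint = 0.3
    acc = np.zeros(2 + d)
    tot = np.zeros(2 + d)

    # SA statistics
    S_psi = m.copy()
    S_within = np.diag(omega2 + gamma2) + 1e-10 * np.eye(4)
    S_cross = np.diag(omega2)
    S_f = np.zeros((ns, nocc, fd.kmax))
    S_r2 = np.full((ns, nocc, fd.kmax), (a + 1e-3) ** 2)
    S_psi2 = S_psi**2 + 0.01  # marginal spread diagnostics
    d_lat = 4 * nocc
    S_outer = np.einsum("ni,nj->nij", m.reshape(ns, d_lat), m.reshape(ns, d_lat))
    S_outer += np.eye(d_lat)[None] * 0.01

    cens_mask = fd.mask & (fd.cens == 1)
    n_iter = st.n_burnin + st.n_explore + st.n_smooth
    traj_rows = []
    preds = np.zeros((nc, ns, nocc, fd.kmax))

    free_design = {}
    for j, terms in free.items():
        free_design[j] = np.column_stack(
            [np.ones(ns * nocc)] + [x.reshape(-1) for (_s, x) in terms]
        )

    for k in range(1, n_iter + 1):
        acc[:] = 0.0
        tot[:] = 0.0
        # two sweeps per iteration once averaging starts: the variance
        # components need the within-iteration posterior spread, which a
        # single sweep underexplores
        n_sweeps = 2 if k > st.n_burnin + st.n_explore else 1
        for sw in range(n_sweeps):
            seed_k = int((st.seed * 2654435761 + k * 97 + sw * 31) %
                         (2**31 - 63))
            K._mh_sweep(seed_k, lpsi, ll_occ, lkm, m, chol, prec, rw_scales,
                        rw_joint, fd.times, fd.y, fd.cens, fd.nobs, fd.dose,
                        a, b, fd.lloq, *flags, acc, tot)

        if k <= st.n_burnin + st.n_explore:
            rates = acc / np.maximum(tot, 1.0)
            rw_scales *= np.exp(0.4 * (rates[1:1 + d] - st.adapt_target))
            np.clip(rw_scales, 1e-3, 5.0, out=rw_scales)
            rw_joint = float(np.clip(
                rw_joint * math.exp(0.4 * (rates[1 + d] - 0.25)), 1e-3, 3.0))
        if k <= st.n_burnin:
            continue

        kk = k - st.n_burnin
        step = 1.0 if kk <= st.n_explore else (kk - st.n_explore) ** (
            -st.step_exponent)

        psi_bar = lpsi.mean(axis=0)
        S_psi += step * (psi_bar - S_psi)
        S_psi2 += step * ((lpsi**2).mean(axis=0) - S_psi2)
        vec = lpsi.reshape(nc, ns, d_lat)
        outer_k = np.einsum("cni,cnj->nij", vec, vec) / nc
        S_outer += step * (outer_k - S_outer)

        # ---- means / free betas ----------------------------------------
        for j in range(4):
            target = (S_psi[:, :, j] - off[:, :, j]).reshape(-1)
            if j in free_design:
                coef, *_ = np.linalg.lstsq(free_design[j], target, rcond=None)
                if f"mu{j}" not in st.fix and PARAM_ORDER[j] not in st.fix:
                    mu[j] = coef[0]
                for t_i in range(len(free[j])):
                    betas[(j, t_i)] = coef[1 + t_i]
            else:
                if PARAM_ORDER[j] not in st.fix:
                    mu[j] = target.mean()
        m = _prior_means(mu, off, free, betas)

        # ---- variance components ---------------------------------------
        e = lpsi - m[None]
        w_k = np.einsum("cnoi,cnoj->ij", e, e) / (nc * ns * nocc)
        S_within += step * (w_k - S_within)
        if nocc > 1:
            pairs = []
            for o1 in range(nocc):
                for o2 in range(o1 + 1, nocc):
                    pairs.append(np.einsum("cni,cnj->ij", e[:, :, o1], e[:, :, o2]))
            c_k = sum(pairs) / (nc * ns * len(pairs))
            c_k = 0.5 * (c_k + c_k.T)
            S_cross += step * (c_k - S_cross)

        if "omega" not in st.fix:
            for j, p in enumerate(PARAM_ORDER):
                if has_iiv[p]:
                    omega2[j] = max(S_cross[j, j], 1e-8) if nocc > 1 else max(
                        S_within[j, j], 1e-8)
        if "gamma" not in st.fix and nocc > 1:
            for j, p in enumerate(PARAM_ORDER):
                if has_iov[p]:
                    base_var = omega2[j] if has_iiv[p] else 0.0
                    gamma2[j] = max(S_within[j, j] - base_var, 1e-8)
        if est_rho:
            denom = math.sqrt(gamma2[0] * gamma2[1])
            if denom > 1e-10:
                rho = float(np.clip(S_within[0, 1] / denom, -0.95, 0.95))

        # ---- residual error and Km -------------------------------------
        K._predict_all(lpsi, lkm, fd.times, fd.nobs, fd.dose, *flags, preds)
        r2_k = np.zeros((ns, nocc, fd.kmax))
        f_k = preds.mean(axis=0)
        for ic in range(nc):
            y_imp = _impute_censored(rng, preds[ic], fd.y, cens_mask, a, b,
                                     fd.lloq)
            r2_k += (y_imp - preds[ic]) ** 2
        r2_k /= nc
        S_f += step * (f_k - S_f)
        S_r2 += step * (r2_k - S_r2)
        # cold fits run both inner optimizations every iteration; warm-start
        # refits begin at converged values, so a sparse cadence loses nothing
        do_err = (not st.warm_start) or kk % 2 == 0 \
            or kk == st.n_explore + st.n_smooth
        if st.warm_start:
            do_ridge = (kk % 5 == 4) or (kk > st.n_explore and kk % 2 == 0)
        else:
            do_ridge = True
        if do_err:
            a, b = _error_update(S_f[fd.mask], S_r2[fd.mask], a, b,
                                 "error_a" in st.fix, "error_b" in st.fix)

        if do_ridge and "Km" not in st.fix \
                and model.variant.elimination == "mm":
            # Vmax and Km sit on a long likelihood ridge (only their ratio is
            # well identified below saturation); coordinate updates stall on
            # it, so optimize a joint shift of log-Km and of every individual
            # log-Vmax (the population mean follows through the psi stats)
            j_vmax = 3

            def neg_ll(xy):
                dv, dk = xy
                lpsi[:, :, :, j_vmax] += dv
                val = -K._total_obs_loglik(
                    lpsi, lkm + dk, fd.times, fd.y, fd.cens, fd.nobs, fd.dose,
                    a, b, fd.lloq, *flags)
                lpsi[:, :, :, j_vmax] -= dv
                return val

            ridge_iter = 12 if st.warm_start else 18
            res = minimize(neg_ll, [0.0, 0.0], method="Nelder-Mead",
                           options={"maxiter": ridge_iter, "xatol": 2e-3,
                                    "fatol": 1e-6})
            dv, dk = res.x
            dv = float(np.clip(step * dv, -0.5, 0.5))
            dk = float(np.clip(step * dk, -0.5, 0.5))
            if abs(dv) > 1e-12 or abs(dk) > 1e-12:
                # shift the outer-product stats consistently with the mean
                mean_flat = S_psi.reshape(ns, d_lat)
                sel = np.arange(nocc) * 4 + j_vmax
                for jj in sel:
                    S_outer[:, jj, :] += dv * mean_flat
                    S_outer[:, :, jj] += dv * mean_flat
                    S_outer[:, jj, jj] += dv * dv
                for jj in sel:
                    for jj2 in sel:
                        if jj != jj2:
                            S_outer[:, jj, jj2] += dv * dv
                lpsi[:, :, :, j_vmax] += dv
                S_psi[:, :, j_vmax] += dv
                mu[j_vmax] += dv
                lkm += dk
                m = _prior_means(mu, off, free, betas)
                K._all_occ_loglik(lpsi, lkm, fd.times, fd.y, fd.cens, fd.nobs,
                                  fd.dose, a, b, fd.lloq, *flags, ll_occ)

        sigma, chol, prec = build_sigma()

        if not np.all(np.isfinite(mu)) or not np.isfinite(lkm):
            raise EstimationError(
                f"SAEM diverged at iteration {k}: non-finite estimates "
                f"(mu={mu}, lKm={lkm})")

        traj_rows.append({
            "iter": k, "step": step,
            **{p: math.exp(mu[j]) for j, p in enumerate(PARAM_ORDER)},
            "Km": math.exp(lkm),
            **{f"omega2_{p}": omega2[j] for j, p in enumerate(PARAM_ORDER)},
            **{f"gamma2_{p}": gamma2[j] for j, p in enumerate(PARAM_ORDER)},
            "rho": rho, "a": a, "b": b,
        })

    traj = pd.DataFrame(traj_rows)

    # ---- assemble results ----------------------------------------------
    theta = {p: math.exp(mu[j]) for j, p in enumerate(PARAM_ORDER)}
    theta["Km"] = math.exp(lkm)
    iiv_cv = {p: omega_to_cv(math.sqrt(omega2[j]), model.cv_exact)
              for j, p in enumerate(PARAM_ORDER) if has_iiv[p]}
    iov_cv = {p: omega_to_cv(math.sqrt(gamma2[j]), model.cv_exact)
              for j, p in enumerate(PARAM_ORDER) if has_iov[p]}

    new_specs = []
    for s in model.covariate_effects:
        if not s.fixed and s.parameter in PARAM_ORDER:
            j = PARAM_ORDER.index(s.parameter)
            for t_i, (spec, _x) in enumerate(free[j]):
                if spec is s:
                    s = replace(s, beta=float(betas[(j, t_i)]))
        new_specs.append(s)
    fitted_model = replace(
        model, theta=theta, covariate_effects=tuple(new_specs),
        iiv_cv=iiv_cv, iov_cv=iov_cv,
        corr_iov_tlag_tk0=rho if est_rho or "rho" in st.fix else 0.0,
        error_a=a, error_b=b,
    )

    psi_var = np.maximum(S_psi2 - S_psi**2, 1e-8)
    mean_flat = S_psi.reshape(ns, d_lat)
    psi_cov = S_outer - np.einsum("ni,nj->nij", mean_flat, mean_flat)
    # symmetrize and regularize toward the diagonal
    psi_cov = 0.5 * (psi_cov + np.transpose(psi_cov, (0, 2, 1)))
    for i in range(ns):
        diag = np.maximum(np.diag(psi_cov[i]), 1e-8)
        psi_cov[i] = 0.8 * psi_cov[i] + 0.2 * np.diag(diag)
        psi_cov[i][np.diag_indices(d_lat)] = np.maximum(
            np.diag(psi_cov[i]), 1e-8)

    # convergence: relative spread of theta over the last window
    win = traj.tail(st.convergence_window)
    converged = bool(len(win) >= 2 and all(
        (win[p].max() - win[p].min()) / max(abs(win[p].median()), 1e-12) < 0.05
        for p in ("Tlag", "Tk0", "V", "Vmax", "Km")
    ))

    # EBE table: posterior-mean individual deviations
    dev = S_psi - m
    ebe_rows = []
    for i, sid in enumerate(fd.subject_ids):
        for o in range(nocc):
            row = {"ID": sid, "OCC": o + 1}
            for j, p in enumerate(PARAM_ORDER):
                row[f"dev_{p}"] = dev[i, o, j]
                row[p] = math.exp(S_psi[i, o, j])
            ebe_rows.append(row)
    ebe = pd.DataFrame(ebe_rows)

    theta_rse = _approx_theta_rse(fd, fitted_model, m, lkm, a, b)

    result = FitResult(
        model=fitted_model, theta=theta, theta_rse=theta_rse,
        iiv_cv=iiv_cv, iov_cv=iov_cv,
        corr_iov_tlag_tk0=fitted_model.corr_iov_tlag_tk0,
        error_a=a, error_b=b,
        ofv=float("nan"), ofv_se=float("nan"), bicc=float("nan"),
        converged=converged, trajectory=traj, ebe=ebe,
        psi_mean=S_psi, psi_var=psi_var, psi_cov=psi_cov, prior_mean=m,
        n_obs=fd.n_obs_total, n_subjects=fd.ns, seed=st.seed,
    )
    if compute_ofv:
        result.ofv, result.ofv_se = ofv(table, fitted_model, result,
                                        mc_size=st.ofv_mc_size,
                                        seed=st.seed + 1)
        result.bicc = bicc(result.ofv, fd.ns, fd.n_obs_total,
                           fitted_model.n_fixed_params(),
                           fitted_model.n_random_params())
    return result


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------

def _mvt_logpdf(x, mean, chol, df):
    """Multivariate t log-density with scale Cholesky ``chol`` (lower)."""
    d = x.shape[-1]
    z = np.linalg.solve(chol, (x - mean).T).T
    maha = np.sum(z * z, axis=-1)
    logdet = np.sum(np.log(np.diag(chol)))
    return (math.lgamma((df + d) / 2) - math.lgamma(df / 2)
            - 0.5 * d * math.log(df * math.pi) - logdet
            - 0.5 * (df + d) * np.log1p(maha / df))


def ofv(table: EventTable, model: PopulationModel, fit: FitResult | None = None,
        mc_size: int = 2000, seed: int = 0) -> tuple[float, float]:
    """-2 log marginal likelihood by importance sampling.

    The proposal is a defensive mixture: a multivariate t (4 df) centred at
    each subject's empirical conditional mean with 1.3x the conditional
    covariance from the SAEM smoothing phase, mixed with 10% prior draws so
    the weights stay bounded.  Without a fit, sampling falls back to the
    prior alone.  Returns ``(ofv, mc_se)``.
    """
    fd = FitData(table)
    if model.has_unresolved_references():
        model = model.resolve_references(table.reference_values())
    flags = model.variant.flags
    off, free = _design(model, fd)
    betas = {}
    for j, terms in free.items():
        for t_i, (spec, _x) in enumerate(terms):
            betas[(j, t_i)] = spec.beta
    mu = np.log([model.theta[p] for p in PARAM_ORDER])
    lkm = math.log(model.theta["Km"])
    m = _prior_means(mu, off, free, betas)
    d = 4 * fd.nocc
    sigma = model.sigma(fd.nocc)
    a, b = model.error_a, model.error_b

    no_re = not model.iiv_cv and not model.iov_cv
    if no_re:
        ll = 0.0
        for i in range(fd.ns):
            for o in range(fd.nocc):
                ll += K._occ_loglik(m[i, o], lkm, fd.dose[i, o], fd.times[i, o],
                                    fd.y[i, o], fd.cens[i, o], fd.nobs[i, o],
                                    a, b, fd.lloq, *flags)
        return -2.0 * ll, 0.0

    rng = np.random.default_rng(seed)
    chol_prior = np.linalg.cholesky(sigma + 1e-12 * np.eye(d))
    logdet_prior = np.sum(np.log(np.diag(chol_prior)))
    df = 4.0
    w_def = 0.20  # defensive prior-mixture weight
    total = 0.0
    var_total = 0.0
    for i in range(fd.ns):
        m_i = m[i].reshape(d)
        if fit is not None and fit.psi_cov is not None \
                and fit.psi_cov.shape[1] == d:
            center = fit.psi_mean[i].reshape(d)
            cov = 1.6 * fit.psi_cov[i] + 1e-10 * np.eye(d)
            try:
                chol_post = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                chol_post = np.linalg.cholesky(np.diag(np.diag(cov)))
        else:
            center = m_i
            chol_post = chol_prior
        n_post = int(round((1.0 - w_def) * mc_size))
        z = rng.standard_normal((n_post, d))
        u = rng.chisquare(df, size=n_post)
        draws_post = center[None] + (z @ chol_post.T) * np.sqrt(df / u)[:, None]
        draws_prior = m_i[None] + rng.standard_normal(
            (mc_size - n_post, d)) @ chol_prior.T
        draws = np.concatenate([draws_post, draws_prior], axis=0)

        log_q_post = _mvt_logpdf(draws, center, chol_post, df)
        zp = np.linalg.solve(chol_prior, (draws - m_i).T).T
        log_p = (-0.5 * np.sum(zp * zp, axis=1) - logdet_prior
                 - 0.5 * d * math.log(2 * math.pi))
        log_q = np.logaddexp(math.log(1.0 - w_def) + log_q_post,
                             math.log(w_def) + log_p)

        ll_y = np.empty(mc_size)
        K._batch_subject_loglik(draws.reshape(mc_size, fd.nocc, 4), lkm,
                                fd.times[i], fd.y[i], fd.cens[i], fd.nobs[i],
                                fd.dose[i], a, b, fd.lloq, *flags, ll_y)
        w = ll_y + log_p - log_q
        wmax = w.max()
        ws = np.exp(w - wmax)
        mean_w = ws.mean()
        ll_i = wmax + math.log(mean_w)
        se_i = ws.std(ddof=1) / (math.sqrt(mc_size) * mean_w)
        total += ll_i
        var_total += se_i**2
    return -2.0 * total, 2.0 * math.sqrt(var_total)


def bicc(ofv_value: float, n_subjects: int, n_obs: int,
         n_fixed_params: int, n_random_params: int,
         hybrid: bool = True) -> float:
    """Corrected BIC with the hybrid sample-size penalty.

    Random-effect-related parameters are penalized by log(n_subjects), fixed
    effects and residual parameters by log(n_obs).  ``hybrid=False`` gives the
    plain BIC (everything penalized by log(n_obs)).
    """
    if min(n_subjects, n_obs) <= 0:
        raise ValueError("counts must be positive")
    if hybrid:
        return ofv_value + n_random_params * math.log(n_subjects) \
            + n_fixed_params * math.log(n_obs)
    return ofv_value + (n_random_params + n_fixed_params) * math.log(n_obs)
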