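"""Model evaluation: weighted residuals, NPDE, prediction-corrected VPC, bootstrap.

* IWRES — individual weighted residuals at the empirical Bayes estimates,
  ``(dv - f_ebe) / g(f_ebe)``.
* PWRES — population weighted residuals: the observation vector of each
  subject decorrelated by the Cholesky factor of the Monte Carlo covariance
  of ``k_sim`` population simulations.
* NPDE — normalized prediction distribution errors (Brendel/Comets): the
  rank of the decorrelated observation among the decorrelated simulations,
  mapped through the inverse normal CDF; standard normal when the model is
  correct.
* pcVPC — Bergstrand prediction correction ``pcY = Y * median(PRED_bin) /
  PRED`` with bins at the nominal sampling times; simulated 90% confidence
  bands for the 10th/50th/90th percentiles.
* bootstrap — nonparametric, subjects resampled with replacement stratified
  by sex, each replicate refitted (warm-started at the original estimates).

BQL rows are imputed from the conditional residual distribution truncated to
[0, LLOQ) and flagged; their residuals are simulation-imputed quantities,
not observed ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from . import _kernels as K
from .dataio import EventTable
from .popmodel import PARAM_ORDER, PopulationModel
from .saem import FitData, FitResult, SAEMSettings, _design, _prior_means, fit_saem

__all__ = ["residuals", "pc_vpc", "bootstrap"]


def _model_arrays(model: PopulationModel, fd: FitData):
    off, free = _design(model, fd)
    betas = {}
    for j, terms in free.items():
        for t_i, (spec, _x) in enumerate(terms):
            betas[(j, t_i)] = spec.beta
    mu = np.log([model.theta[p] for p in PARAM_ORDER])
    lkm = math.log(model.theta["Km"])
    m = _prior_means(mu, off, free, betas)
    return m, lkm


def _simulate_subject_obs(model, fd, m, lkm, i, k_sim, rng,
                          with_noise=True):
    """k_sim replicate observation vectors for subject i (stacked occasions)."""
    nocc = fd.nocc
    d = 4 * nocc
    sigma = model.sigma(nocc)
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(d))
    z = rng.standard_normal((k_sim, d))
    psis = m[i].reshape(d)[None] + z @ chol.T
    sims = []
    flags = model.variant.flags
    for o in range(nocc):
        n = fd.nobs[i, o]
        if n == 0:
            continue
        params = np.empty((k_sim, 5))
        params[:, :4] = np.exp(psis[:, o * 4:(o + 1) * 4])
        params[:, 4] = math.exp(lkm)
        out = np.empty((k_sim, n))
        K._batch_conc(params, fd.times[i, o, :n], fd.dose[i, o], *flags, out)
        if with_noise:
            g = np.maximum(model.error_a + model.error_b * out, 1e-12)
            out = out + g * rng.standard_normal(out.shape)
        sims.append(out)
    return np.concatenate(sims, axis=1)  # (k_sim, n_obs_i)


def residuals(table: EventTable, model: PopulationModel,
              fit: FitResult | None = None, k_sim: int = 1000,
              rng: np.random.Generator | None = None,
              decorrelate: bool = True) -> pd.DataFrame:
    """Residual table: time, dv, PRED, IPRED, PWRES, IWRES, NPDE, flags.

    Without a fit result, empirical Bayes predictions fall back to the
    population means (IWRES then equals PWRES-like quantities only in the
    no-variability limit).
    """
    if k_sim < 50:
        raise ValueError("k_sim < 50 gives an unstable decorrelation")
    rng = rng if rng is not None else np.random.default_rng(0)
    fd = FitData(table)
    if model.has_unresolved_references():
        model = model.resolve_references(table.reference_values())
    m, lkm = _model_arrays(model, fd)
    flags = model.variant.flags

    psi_ind = fit.psi_mean if fit is not None else m
    rows = []
    for i, sid in enumerate(fd.subject_ids):
        # observed vector (with BQL imputation at the individual prediction)
        y_parts, f_ind_parts, f_pop_parts, cens_parts, t_parts, occ_parts = \
            [], [], [], [], [], []
        for o in range(fd.nocc):
            n = fd.nobs[i, o]
            if n == 0:
                continue
            f_ind = np.empty(n)
            K._occ_conc(psi_ind[i, o], lkm, fd.dose[i, o], fd.times[i, o], n,
                        *flags, f_ind)
            f_pop = np.empty(n)
            K._occ_conc(m[i, o], lkm, fd.dose[i, o], fd.times[i, o], n,
                        *flags, f_pop)
            y = fd.y[i, o, :n].copy()
            cens = fd.cens[i, o, :n]
            bql = cens == 1
            if bql.any():
                g = np.maximum(model.error_a + model.error_b * f_ind[bql],
                               1e-12)
                lo = ndtr((0.0 - f_ind[bql]) / g)
                hi = ndtr((fd.lloq - f_ind[bql]) / g)
                u = np.clip(lo + rng.random(bql.sum()) * np.maximum(hi - lo,
                                                                    1e-14),
                            1e-13, 1 - 1e-13)
                y[bql] = np.clip(f_ind[bql] + g * ndtri(u), 0.0, fd.lloq)
            y_parts.append(y)
            f_ind_parts.append(f_ind)
            f_pop_parts.append(f_pop)
            cens_parts.append(cens)
            t_parts.append(fd.times[i, o, :n])
            occ_parts.append(np.full(n, o + 1))
        yv = np.concatenate(y_parts)
        f_ind = np.concatenate(f_ind_parts)
        f_pop = np.concatenate(f_pop_parts)
        censv = np.concatenate(cens_parts)

        sims = _simulate_subject_obs(model, fd, m, lkm, i, k_sim, rng)
        e_y = sims.mean(axis=0)
        if decorrelate:
            cov = np.cov(sims, rowvar=False)
            cov += np.eye(cov.shape[0]) * (1e-10 + 1e-6 * np.trace(cov)
                                           / cov.shape[0])
            lch = np.linalg.cholesky(cov)
            dec_y = np.linalg.solve(lch, yv - e_y)
            dec_sims = np.linalg.solve(lch, (sims - e_y).T).T
        else:
            sd = sims.std(axis=0, ddof=1) + 1e-12
            dec_y = (yv - e_y) / sd
            dec_sims = (sims - e_y) / sd

        pwres = dec_y
        rank = (dec_sims < dec_y[None, :]).mean(axis=0)
        rank = np.clip(rank, 1.0 / (2 * k_sim), 1.0 - 1.0 / (2 * k_sim))
        npde = ndtri(rank)
        g_ind = np.maximum(model.error_a + model.error_b * f_ind, 1e-12)
        iwres = (yv - f_ind) / g_ind

        tv = np.concatenate(t_parts)
        ov = np.concatenate(occ_parts)
        for j in range(len(yv)):
            rows.append({
                "ID": sid, "OCC": int(ov[j]), "TIME": tv[j], "DV": yv[j],
                "PRED": f_pop[j], "IPRED": f_ind[j], "PWRES": pwres[j],
                "IWRES": iwres[j], "NPDE": npde[j],
                "CENS": int(censv[j]), "imputed": bool(censv[j]),
            })
    return pd.DataFrame(rows)


def pc_vpc(table: EventTable, model: PopulationModel,
           fit: FitResult | None = None, n_rep: int = 1000,
           bins=None, rng: np.random.Generator | None = None,
           percentiles=(10.0, 50.0, 90.0), ci: float = 90.0) -> pd.DataFrame:
    """Prediction-corrected visual predictive check summary table.

    Returns one row per (time bin, percentile) with the observed
    prediction-corrected percentile and the simulated confidence band across
    ``n_rep`` replicate studies.  Default bins are the nominal sampling times
    (the design is rich and nominal, so data-driven binning is unnecessary).
    """
    if n_rep < 100:
        raise ValueError("n_rep must be >= 100")
    rng = rng if rng is not None else np.random.default_rng(0)
    fd = FitData(table)
    if model.has_unresolved_references():
        model = model.resolve_references(table.reference_values())
    m, lkm = _model_arrays(model, fd)

    # flatten observations with PRED per row
    obs_t, obs_y, obs_pred = [], [], []
    sub_occ = []
    flags = model.variant.flags
    for i in range(fd.ns):
        for o in range(fd.nocc):
            n = fd.nobs[i, o]
            if n == 0:
                continue
            f_pop = np.empty(n)
            K._occ_conc(m[i, o], lkm, fd.dose[i, o], fd.times[i, o], n,
                        *flags, f_pop)
            obs_t.append(fd.times[i, o, :n])
            obs_y.append(np.maximum(fd.y[i, o, :n], fd.lloq))
            obs_pred.append(f_pop)
            sub_occ.append((i, o, n))
    obs_t = np.concatenate(obs_t)
    obs_y = np.concatenate(obs_y)
    obs_pred = np.maximum(np.concatenate(obs_pred), 1e-12)

    if bins is None:
        bin_values = np.unique(np.round(obs_t, 6))
        bin_of = np.searchsorted(bin_values,
                                 np.round(obs_t, 6))
    else:
        edges = np.asarray(bins, dtype=float)
        bin_of = np.clip(np.digitize(obs_t, edges) - 1, 0, len(edges) - 2)
        bin_values = 0.5 * (edges[:-1] + edges[1:])

    # prediction correction on the observed data
    pc_obs = obs_y.copy()
    med_pred = np.empty(len(bin_values))
    for bi in range(len(bin_values)):
        sel = bin_of == bi
        med_pred[bi] = np.median(obs_pred[sel]) if sel.any() else np.nan
        pc_obs[sel] = obs_y[sel] * med_pred[bi] / obs_pred[sel]

    # replicate studies
    sigma = model.sigma(fd.nocc)
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(sigma.shape[0]))
    rep_pcts = np.empty((n_rep, len(bin_values), len(percentiles)))
    n_total = len(obs_t)
    for r in range(n_rep):
        sim_y = np.empty(n_total)
        pos = 0
        for (i, o, n) in sub_occ:
            z = rng.standard_normal(4 * fd.nocc)
            psi = m[i].reshape(-1) + chol @ z
            params = np.empty((1, 5))
            params[0, :4] = np.exp(psi[o * 4:(o + 1) * 4])
            params[0, 4] = math.exp(lkm)
            out = np.empty((1, n))
            K._batch_conc(params, fd.times[i, o, :n], fd.dose[i, o], *flags,
                          out)
            g = np.maximum(model.error_a + model.error_b * out[0], 1e-12)
            sim_y[pos:pos + n] = out[0] + g * rng.standard_normal(n)
            pos += n
        sim_y = np.maximum(sim_y, fd.lloq)
        pc_sim = sim_y * med_pred[bin_of] / obs_pred
        for bi in range(len(bin_values)):
            sel = bin_of == bi
            rep_pcts[r, bi] = np.percentile(pc_sim[sel], percentiles)

    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    rows = []
    for bi, bv in enumerate(bin_values):
        sel = bin_of == bi
        if not sel.any():
            warnings.warn(f"empty VPC bin at {bv}; dropped")
            continue
        for pj, pct in enumerate(percentiles):
            rows.append({
                "bin_time": bv, "n_obs": int(sel.sum()), "percentile": pct,
                "observed": float(np.percentile(pc_obs[sel], pct)),
                "sim_median": float(np.median(rep_pcts[:, bi, pj])),
                "sim_lo": float(np.percentile(rep_pcts[:, bi, pj], lo_q)),
                "sim_hi": float(np.percentile(rep_pcts[:, bi, pj], hi_q)),
                "n_rep": n_rep,
            })
    return pd.DataFrame(rows)


def bootstrap(table: EventTable, model: PopulationModel, n_boot: int = 1000,
              settings: SAEMSettings | None = None,
              rng: np.random.Generator | None = None,
              stratify_by_sex: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nonparametric bootstrap: resample subjects, refit, summarize.

    Returns ``(replicates, summary)`` where summary holds the median and the
    2.5/97.5 percentile CI per parameter.  Non-convergent replicates are
    excluded and counted; more than 20% failures raises a warning.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(0)
    settings = settings or SAEMSettings()
    if model.has_unresolved_references():
        model = model.resolve_references(table.reference_values())

    covs = table.covariates()
    ids = table.subjects
    by_sex = {"female": [s for s in ids if covs[s].sex == "female"],
              "male": [s for s in ids if covs[s].sex == "male"]}
    rows = []
    n_failed = 0
    for r in range(n_boot):
        if stratify_by_sex:
            chosen = [sid for sex, members in by_sex.items() if members
                      for sid in rng.choice(members, size=len(members))]
        else:
            chosen = list(rng.choice(ids, size=len(ids)))
        parts = []
        for new_idx, sid in enumerate(chosen):
            sub = table.df[table.df["ID"] == sid].copy()
            sub["ID"] = f"B{new_idx:03d}"
            parts.append(sub)
        btab = EventTable(pd.concat(parts, ignore_index=True),
                          lloq=table.lloq)
        st = replace(settings, seed=int((settings.seed + 7919 * (r + 1))
                                        % (2**31 - 1)))
        try:
            fit = fit_saem(btab, model, st, compute_ofv=False)
        except Exception as exc:
            n_failed += 1
            warnings.warn(f"bootstrap replicate {r} failed: {exc!r}")
            continue
        row = {"replicate": r, **{p: fit.theta[p] for p in fit.theta}}
        for p, cv in fit.iiv_cv.items():
            row[f"iiv_{p}_cv"] = cv
        for p, cv in fit.iov_cv.items():
            row[f"iov_{p}_cv"] = cv
        row["corr_iov_tlag_tk0"] = fit.corr_iov_tlag_tk0
        row["error_a"] = fit.error_a
        row["error_b"] = fit.error_b
        rows.append(row)
    if n_boot and n_failed / n_boot > 0.2:
        warnings.warn(f"{n_failed}/{n_boot} bootstrap replicates failed")
    reps = pd.DataFrame(rows)
    summ_rows = []
    for col in reps.columns:
        if col == "replicate":
            continue
        v = reps[col].to_numpy(float)
        summ_rows.append({"parameter": col, "median": float(np.median(v)),
                          "ci_lo": float(np.percentile(v, 2.5)),
                          "ci_hi": float(np.percentile(v, 97.5)),
                          "n_ok": len(v), "n_failed": n_failed})
    return reps, pd.DataFrame(summ_rows)
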