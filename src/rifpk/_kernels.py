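"""Numba-compiled numerical core.

Everything on the hot path of SAEM, simulation and Monte Carlo exposure lives
here: the one-compartment structural model (zero-order input with lag,
Michaelis-Menten or linear elimination, optional first-order absorption for
the model-family catalogue), the BQL-censored observation log-likelihood, and
the Metropolis-within-Gibbs sweep over individual log-parameters.

Concentration profiles for the primary model (lagged zero-order input, MM
elimination) are computed semi-analytically: classical RK4 with fixed fine
steps across the input window, then the exact Lambert-W closed form of
post-absorption Michaelis-Menten decay,

    C(t) = Km * W0( u * exp(u - (Vmax/V) * (t - t_end) / Km) ),  u = C_end/Km.

Occasion-level log-parameter order is fixed everywhere:
``[Tlag, Tk0(or ka), V, Vmax(or CL)]``; Km is carried separately because it
never carries a random effect in the shipped models.
"""

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_LOG2PI = math.log(2.0 * math.pi)


@njit(cache=True)
def _phi(x):
    """Standard normal CDF."""
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=True)
def _lamw_log(y):
    """Solve w + log(w) = y for w > 0, i.e. w = W0(exp(y)), overflow-safe."""
    if y < -36.0:
        w = math.exp(y)
        return w * (1.0 - w)
    if y > 1.0:
        w = y - math.log(y)
    else:
        w = 0.6 * math.exp(y)
        if w < 1e-300:
            w = 1e-300
    for _ in range(100):
        f = w + math.log(w) - y
        dw = f * w / (w + 1.0)
        wn = w - dw
        while wn <= 0.0:
            dw *= 0.5
            wn = w - dw
        w = wn
        if abs(dw) <= 1e-15 * (w + 1e-300):
            break
    return w


@njit(cache=True)
def _rk4_absorb(c0, t0, t1, nstep, r_v, vmax_v, km):
    """Integrate dC/dt = r_v - vmax_v*C/(km+C) from t0 to t1 (RK4, fixed step)."""
    h = (t1 - t0) / nstep
    c = c0
    for _ in range(nstep):
        k1 = r_v - vmax_v * c / (km + c)
        c2 = c + 0.5 * h * k1
        if c2 < 0.0:
            c2 = 0.0
        k2 = r_v - vmax_v * c2 / (km + c2)
        c3 = c + 0.5 * h * k2
        if c3 < 0.0:
            c3 = 0.0
        k3 = r_v - vmax_v * c3 / (km + c3)
        c4 = c + h * k3
        if c4 < 0.0:
            c4 = 0.0
        k4 = r_v - vmax_v * c4 / (km + c4)
        c = c + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if c < 0.0:
            c = 0.0
    return c


_NSTEP_ABS = 64  # RK4 steps across the zero-order input window


@njit(cache=True)
def _conc_zero_mm(times, n, tlag, tk0, v, vmax, km, dose, out):
    """Concentration at `times[:n]` for the lagged zero-order + MM model."""
    r_v = dose / (tk0 * v)
    vmax_v = vmax / v
    t2 = tlag + tk0
    cend = _rk4_absorb(0.0, tlag, t2, _NSTEP_ABS, r_v, vmax_v, km)
    if cend > 0.0:
        lu = math.log(cend / km)
    else:
        lu = 0.0
    for j in range(n):
        t = times[j]
        if t <= tlag:
            out[j] = 0.0
        elif t <= t2:
            ns = int(_NSTEP_ABS * (t - tlag) / tk0) + 4
            out[j] = _rk4_absorb(0.0, tlag, t, ns, r_v, vmax_v, km)
        else:
            if cend <= 0.0:
                out[j] = 0.0
            else:
                y = lu + cend / km - vmax_v * (t - t2) / km
                out[j] = km * _lamw_log(y)
    return cend


@njit(cache=True)
def _rate_in(t, gate, tlag, p1, v, dose, abs_zero):
    """Drug input rate (concentration/h).

    The on/off decision for the piecewise-constant zero-order input is made
    per integration segment (``gate``), never from the evaluation time, so a
    RK4 stage at a segment boundary cannot sample the wrong branch.
    """
    if gate == 0:
        return 0.0
    if abs_zero == 1:
        return dose / (p1 * v)
    # first-order: analytic depot, p1 = ka
    dt = t - tlag
    if dt < 0.0:
        dt = 0.0
    return p1 * dose * math.exp(-p1 * dt) / v


@njit(cache=True)
def _elim_rate(c, v, p3, km, elim_mm):
    if c <= 0.0:
        return 0.0
    if elim_mm == 1:
        return p3 * c / ((km + c) * v)
    return p3 * c / v


@njit(cache=True)
def _rk4_general(c, t0, t1, tlag, p1, v, p3, km, dose, abs_zero, elim_mm):
    """RK4 with time-dependent input over [t0, t1]; no breakpoint inside."""
    span = t1 - t0
    if span <= 0.0:
        return c
    # input gate decided once per segment (segments never straddle breakpoints)
    mid = 0.5 * (t0 + t1)
    if abs_zero == 1:
        gate = 1 if (tlag < mid <= tlag + p1) else 0
    else:
        gate = 1 if mid > tlag else 0
    nstep = int(span / 0.005) + 2
    h = span / nstep
    t = t0
    for _ in range(nstep):
        k1 = _rate_in(t, gate, tlag, p1, v, dose, abs_zero) - _elim_rate(
            c, v, p3, km, elim_mm)
        c2 = c + 0.5 * h * k1
        k2 = _rate_in(t + 0.5 * h, gate, tlag, p1, v, dose, abs_zero) - _elim_rate(
            c2, v, p3, km, elim_mm
        )
        c3 = c + 0.5 * h * k2
        k3 = _rate_in(t + 0.5 * h, gate, tlag, p1, v, dose, abs_zero) - _elim_rate(
            c3, v, p3, km, elim_mm
        )
        c4 = c + h * k3
        k4 = _rate_in(t + h, gate, tlag, p1, v, dose, abs_zero) - _elim_rate(
            c4, v, p3, km, elim_mm
        )
        c = c + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if c < 0.0:
            c = 0.0
        t += h
    return c


@njit(cache=True)
def _conc_general(times, n, tlag, p1, v, p3, km, dose, abs_zero, has_lag, elim_mm, out):
    """Concentration at sorted `times[:n]` for any one-compartment variant."""
    if has_lag == 0:
        tlag = 0.0
    t_stop = tlag + p1 if abs_zero == 1 else 1e30
    c = 0.0
    tprev = 0.0
    for j in range(n):
        t = times[j]
        if t <= tprev:
            out[j] = c
            continue
        # split the segment at the input breakpoints
        a = tprev
        for brk in (tlag, t_stop):
            if a < brk < t:
                c = _rk4_general(c, a, brk, tlag, p1, v, p3, km, dose, abs_zero, elim_mm)
                a = brk
        c = _rk4_general(c, a, t, tlag, p1, v, p3, km, dose, abs_zero, elim_mm)
        out[j] = c
        tprev = t
    return c


@njit(cache=True)
def _occ_conc(lpsi, lkm, dose, times, n, abs_zero, has_lag, elim_mm, out):
    """Concentration profile for one subject-occasion from log-parameters."""
    tlag = math.exp(lpsi[0])
    p1 = math.exp(lpsi[1])
    v = math.exp(lpsi[2])
    p3 = math.exp(lpsi[3])
    km = math.exp(lkm)
    if abs_zero == 1 and has_lag == 1 and elim_mm == 1:
        _conc_zero_mm(times, n, tlag, p1, v, p3, km, dose, out)
    else:
        _conc_general(times, n, tlag, p1, v, p3, km, dose, abs_zero, has_lag, elim_mm, out)


@njit(cache=True)
def _occ_loglik(lpsi, lkm, dose, times, y, cens, n, a, b, lloq,
                abs_zero, has_lag, elim_mm):
    """Censored observation log-likelihood for one subject-occasion.

    cens == 1 rows contribute the Gaussian probability mass on [0, LLOQ)
    (interval censoring with a physical lower bound at zero concentration).
    """
    if n == 0:
        return 0.0
    work = np.empty(n)
    _occ_conc(lpsi, lkm, dose, times, n, abs_zero, has_lag, elim_mm, work)
    ll = 0.0
    for j in range(n):
        f = work[j]
        g = a + b * f
        if g < 1e-10:
            g = 1e-10
        if cens[j] == 1:
            p = _phi((lloq - f) / g) - _phi((0.0 - f) / g)
            if p < 1e-290:
                p = 1e-290
            ll += math.log(p)
        else:
            r = (y[j] - f) / g
            ll += -0.5 * r * r - math.log(g) - 0.5 * _LOG2PI
    return ll


@njit(cache=True)
def _all_occ_loglik(lpsi, lkm, times, y, cens, nobs, dose, a, b, lloq,
                    abs_zero, has_lag, elim_mm, ll_occ):
    """Fill the per-(chain, subject, occasion) log-likelihood cache."""
    nc, ns, nocc = lpsi.shape[0], lpsi.shape[1], lpsi.shape[2]
    for ic in range(nc):
        for i in range(ns):
            for o in range(nocc):
                ll_occ[ic, i, o] = _occ_loglik(
                    lpsi[ic, i, o], lkm, dose[i, o], times[i, o], y[i, o],
                    cens[i, o], nobs[i, o], a, b, lloq,
                    abs_zero, has_lag, elim_mm,
                )


@njit(cache=True)
def _quad_form(vec, m_flat, prec, d):
    q = 0.0
    for r in range(d):
        er = vec[r] - m_flat[r]
        s = 0.0
        for cidx in range(d):
            s += prec[r, cidx] * (vec[cidx] - m_flat[cidx])
        q += er * s
    return q


@njit(cache=True)
def _mh_sweep(seed, lpsi, ll_occ, lkm, m, chol, prec, rw_scales, rw_joint,
              times, y, cens, nobs, dose, a, b, lloq,
              abs_zero, has_lag, elim_mm, acc, tot):
    """One Metropolis-within-Gibbs sweep over all chains and subjects.

    Three kernels per subject: an independent draw from the Gaussian prior of
    the individual log-parameters, a componentwise random walk (one
    subject-occasion likelihood re-evaluation per component), and a joint
    random walk along the prior Cholesky directions.

    acc/tot: acceptance bookkeeping, length 2 + D with D = n_occasions*4
    (slot 0: prior kernel, slots 1..D: componentwise, slot D+1: joint).
    """
    np.random.seed(seed)
    nc = lpsi.shape[0]
    ns = lpsi.shape[1]
    nocc = lpsi.shape[2]
    d = nocc * 4
    vec = np.empty(d)
    vecp = np.empty(d)
    z = np.empty(d)
    m_flat = np.empty(d)
    ll_new = np.empty(nocc)
    for ic in range(nc):
        for i in range(ns):
            for o in range(nocc):
                for p in range(4):
                    vec[o * 4 + p] = lpsi[ic, i, o, p]
                    m_flat[o * 4 + p] = m[i, o, p]

            # --- kernel 1: independent prior proposal -------------------
            for k in range(d):
                z[k] = np.random.normal()
            for r in range(d):
                s = m_flat[r]
                for cidx in range(r + 1):
                    s += chol[r, cidx] * z[cidx]
                vecp[r] = s
            ll_new_tot = 0.0
            for o in range(nocc):
                ll_new[o] = _occ_loglik(
                    vecp[o * 4:(o + 1) * 4], lkm, dose[i, o], times[i, o],
                    y[i, o], cens[i, o], nobs[i, o], a, b, lloq,
                    abs_zero, has_lag, elim_mm,
                )
                ll_new_tot += ll_new[o]
            ll_old_tot = 0.0
            for o in range(nocc):
                ll_old_tot += ll_occ[ic, i, o]
            tot[0] += 1.0
            if math.log(np.random.random() + 1e-300) < ll_new_tot - ll_old_tot:
                acc[0] += 1.0
                for r in range(d):
                    vec[r] = vecp[r]
                for o in range(nocc):
                    ll_occ[ic, i, o] = ll_new[o]

            # --- kernel 2: componentwise random walk --------------------
            for k in range(d):
                o = k // 4
                delta = rw_scales[k] * np.random.normal()
                for r in range(d):
                    vecp[r] = vec[r]
                vecp[k] = vec[k] + delta
                lo = _occ_loglik(
                    vecp[o * 4:(o + 1) * 4], lkm, dose[i, o], times[i, o],
                    y[i, o], cens[i, o], nobs[i, o], a, b, lloq,
                    abs_zero, has_lag, elim_mm,
                )
                # prior log-ratio for a single-coordinate move
                s = 0.0
                for cidx in range(d):
                    s += prec[k, cidx] * (vec[cidx] - m_flat[cidx])
                dq = -(delta * s + 0.5 * prec[k, k] * delta * delta)
                tot[1 + k] += 1.0
                if math.log(np.random.random() + 1e-300) < (lo - ll_occ[ic, i, o]) + dq:
                    acc[1 + k] += 1.0
                    vec[k] = vecp[k]
                    ll_occ[ic, i, o] = lo

            # --- kernel 3: joint random walk ----------------------------
            for k in range(d):
                z[k] = np.random.normal()
            for r in range(d):
                s = 0.0
                for cidx in range(r + 1):
                    s += chol[r, cidx] * z[cidx]
                vecp[r] = vec[r] + rw_joint * s
            ll_new_tot = 0.0
            for o in range(nocc):
                ll_new[o] = _occ_loglik(
                    vecp[o * 4:(o + 1) * 4], lkm, dose[i, o], times[i, o],
                    y[i, o], cens[i, o], nobs[i, o], a, b, lloq,
                    abs_zero, has_lag, elim_mm,
                )
                ll_new_tot += ll_new[o]
            ll_old_tot = 0.0
            for o in range(nocc):
                ll_old_tot += ll_occ[ic, i, o]
            dq = 0.5 * (_quad_form(vec, m_flat, prec, d)
                        - _quad_form(vecp, m_flat, prec, d))
            tot[1 + d] += 1.0
            if math.log(np.random.random() + 1e-300) < (ll_new_tot - ll_old_tot) + dq:
                acc[1 + d] += 1.0
                for r in range(d):
                    vec[r] = vecp[r]
                for o in range(nocc):
                    ll_occ[ic, i, o] = ll_new[o]

            for o in range(nocc):
                for p in range(4):
                    lpsi[ic, i, o, p] = vec[o * 4 + p]


@njit(cache=True)
def _predict_all(lpsi, lkm, times, nobs, dose, abs_zero, has_lag, elim_mm, out):
    """Predicted concentrations for every (chain, subject, occasion, sample)."""
    nc, ns, nocc = lpsi.shape[0], lpsi.shape[1], lpsi.shape[2]
    for ic in range(nc):
        for i in range(ns):
            for o in range(nocc):
                n = nobs[i, o]
                if n > 0:
                    _occ_conc(lpsi[ic, i, o], lkm, dose[i, o], times[i, o], n,
                              abs_zero, has_lag, elim_mm, out[ic, i, o])


@njit(cache=True)
def _total_obs_loglik(lpsi, lkm, times, y, cens, nobs, dose, a, b, lloq,
                      abs_zero, has_lag, elim_mm):
    """Observation log-likelihood summed over subjects, averaged over chains."""
    nc, ns, nocc = lpsi.shape[0], lpsi.shape[1], lpsi.shape[2]
    tt = 0.0
    for ic in range(nc):
        for i in range(ns):
            for o in range(nocc):
                tt += _occ_loglik(
                    lpsi[ic, i, o], lkm, dose[i, o], times[i, o], y[i, o],
                    cens[i, o], nobs[i, o], a, b, lloq,
                    abs_zero, has_lag, elim_mm,
                )
    return tt / nc


@njit(cache=True)
def _batch_subject_loglik(lpsis, lkm, times_i, y_i, cens_i, nobs_i, dose_i,
                          a, b, lloq, abs_zero, has_lag, elim_mm, out):
    """p(y_i | psi) for a batch of candidate psi draws (importance sampling)."""
    m = lpsis.shape[0]
    nocc = lpsis.shape[1]
    for k in range(m):
        ll = 0.0
        for o in range(nocc):
            ll += _occ_loglik(
                lpsis[k, o], lkm, dose_i[o], times_i[o], y_i[o], cens_i[o],
                nobs_i[o], a, b, lloq, abs_zero, has_lag, elim_mm,
            )
        out[k] = ll


@njit(cache=True)
def _batch_conc(params, times, dose, abs_zero, has_lag, elim_mm, out):
    """Concentration profiles for a batch of natural-scale parameter sets.

    params: (M, 5) columns [Tlag, Tk0/ka, V, Vmax/CL, Km]; out: (M, K).
    """
    m = params.shape[0]
    k = times.shape[0]
    for j in range(m):
        tlag = params[j, 0]
        p1 = params[j, 1]
        v = params[j, 2]
        p3 = params[j, 3]
        km = params[j, 4]
        if abs_zero == 1 and has_lag == 1 and elim_mm == 1:
            _conc_zero_mm(times, k, tlag, p1, v, p3, km, dose, out[j])
        else:
            _conc_general(times, k, tlag, p1, v, p3, km, dose,
                          abs_zero, has_lag, elim_mm, out[j])


@njit(cache=True)
def _auc_zero_mm(tlag, tk0, v, vmax, km, dose, t_end):
    """AUC of the lagged zero-order + MM model up to t_end (np.inf allowed).

    Absorption window by composite Simpson on the RK4 grid; everything past
    the end of input analytically from dC/dt = -(Vmax/V) C/(Km+C):
    integral C dt = (V/Vmax) * (Km*(C1-C2) + (C1^2-C2^2)/2).
    """
    r_v = dose / (tk0 * v)
    vmax_v = vmax / v
    t2 = tlag + tk0
    if t_end <= tlag:
        return 0.0
    # concentrations on the absorption grid
    nseg = _NSTEP_ABS
    t_hi = t2 if t_end >= t2 else t_end
    grid = np.empty(nseg + 1)
    grid[0] = 0.0
    c = 0.0
    h = (t_hi - tlag) / nseg
    for s in range(nseg):
        c = _rk4_absorb(c, tlag + s * h, tlag + (s + 1) * h, 4, r_v, vmax_v, km)
        grid[s + 1] = c
    # composite Simpson (nseg even)
    auc = grid[0] + grid[nseg]
    for s in range(1, nseg):
        auc += (4.0 if s % 2 == 1 else 2.0) * grid[s]
    auc *= h / 3.0
    if t_end <= t2:
        return auc
    cend = grid[nseg]
    if vmax_v <= 0.0:
        return np.inf
    if t_end == np.inf:
        c_t = 0.0
    else:
        if cend > 0.0:
            ylog = math.log(cend / km) + cend / km - vmax_v * (t_end - t2) / km
            c_t = km * _lamw_log(ylog)
        else:
            c_t = 0.0
    auc += (km * (cend - c_t) + 0.5 * (cend * cend - c_t * c_t)) / vmax_v
    return auc


@njit(cache=True)
def _batch_auc_zero_mm(params, dose, t_end, out):
    for j in range(params.shape[0]):
        out[j] = _auc_zero_mm(params[j, 0], params[j, 1], params[j, 2],
                              params[j, 3], params[j, 4], dose, t_end)
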