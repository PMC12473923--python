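"""Compiled FOCE-with-interaction marginal likelihood kernels.

Per subject i with observations y_j at times t_j the contribution to the
objective function value (OFV = -2 log marginal likelihood) is obtained by
the Laplace method at the conditional mode eta* of the random effects:

    OFV_i = sum_j [ ln(2 pi var_j) + (y_j - f_j)^2 / var_j ]
          + sum_k [ ln omega2_k + eta*_k^2 / omega2_k ]
          + ln det G

with f_j = f_j(eta*), var_j = sigma^2 f_j^2 + eps^2 (proportional residual
error evaluated at the conditional prediction: the "interaction" part),
and the Gauss-Newton information G = Omega^-1 + sum_j F_j F_j' / var_j
where F_j = df_j/deta at the mode.  The inner mode search is a damped
(Levenberg-Marquardt) Newton iteration on the penalized extended
least-squares objective; prediction gradients come from forward
differences.  Random effects with omega2 = 0 are excluded (fixed at 0).

The tiny additive variance floor eps^2 keeps records with predicted
concentration zero (leading below-quantification samples imputed to zero)
from producing a zero residual variance.
"""

import numpy as np
from numba import njit

from ._ode import conc_at_times

#: additive residual-SD floor, mg/L
EPS_FLOOR = 1e-6

_LOG2PI = np.log(2.0 * np.pi)


@njit(cache=True)
def _predict(theta, e0, e1, e2, wt, study, trtind, dose_t, dose_amt, obs_t, rtol, atol):
    cl = np.exp(theta[0] + theta[5] * np.log(wt / 70.0) + theta[7] * trtind + e0)
    v = np.exp(theta[1] + theta[6] * study + theta[8] * trtind + e1)
    ka = np.exp(theta[2] + theta[9] * trtind + e2)
    km = np.exp(theta[3])
    vm = np.exp(theta[4])
    conc, _a1, _a2, _a3 = conc_at_times(
        ka, v, cl, km, vm, dose_t, dose_amt, obs_t, rtol, atol
    )
    return conc


@njit(cache=True)
def _gval(f, dv, sig2, eps2, eta, om2, act, m):
    g = 0.0
    for j in range(f.size):
        fj = f[j]
        if np.isnan(fj):
            return np.inf
        var = sig2 * fj * fj + eps2
        r = dv[j] - fj
        g += 0.5 * (_LOG2PI + np.log(var) + r * r / var)
    for jj in range(m):
        k = act[jj]
        g += 0.5 * eta[k] * eta[k] / om2[k]
    return g


@njit(cache=True)
def _chol(A, m, L):
    """Cholesky of the leading m-by-m block; returns False if not SPD."""
    for i in range(m):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return True


@njit(cache=True)
def _chol_solve(L, b, m, x):
    for i in range(m):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * x[k]
        x[i] = s / L[i, i]
    for i in range(m - 1, -1, -1):
        s = x[i]
        for k in range(i + 1, m):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]


@njit(cache=True)
def _subject_foce(
    theta,
    om2,
    sig2,
    eps2,
    wt,
    study,
    trtind,
    dose_t,
    dose_amt,
    obs_t,
    dv,
    eta,
    rtol,
    atol,
    exact_hess,
    gtol,
    stol,
    max_inner,
):
    """FOCE-I OFV contribution of one subject; updates ``eta`` in place to
    the conditional mode (inner convergence: gradient below ``gtol`` or
    step below ``stol``, at most ``max_inner`` damped-Newton iterations).
    Returns inf on failure.

    ``exact_hess`` selects the finite-difference exact curvature for the
    Laplace ln-det term; otherwise the Gauss-Newton information is used
    (the classical FOCE linearization, cheaper and noise-robust, used
    during optimization)."""
    act = np.empty(3, dtype=np.int64)
    m = 0
    for k in range(3):
        if om2[k] > 0.0:
            act[m] = k
            m += 1
        else:
            eta[k] = 0.0

    f = _predict(
        theta, eta[0], eta[1], eta[2], wt, study, trtind,
        dose_t, dose_amt, obs_t, rtol, atol,
    )
    g = _gval(f, dv, sig2, eps2, eta, om2, act, m)
    # a stale warm start can be worse than the prior mode: compare with
    # eta = 0 and keep the better starting point
    if eta[0] != 0.0 or eta[1] != 0.0 or eta[2] != 0.0:
        f0 = _predict(
            theta, 0.0, 0.0, 0.0, wt, study, trtind,
            dose_t, dose_amt, obs_t, rtol, atol,
        )
        zero = np.zeros(3)
        g0 = _gval(f0, dv, sig2, eps2, zero, om2, act, m)
        if g0 < g:
            g = g0
            f = f0
            for k in range(3):
                eta[k] = 0.0
    if not np.isfinite(g):
        return np.inf

    n = obs_t.size
    F = np.empty((n, 3))
    grad = np.empty(3)
    H = np.empty((3, 3))
    Hd = np.empty((3, 3))
    L = np.zeros((3, 3))
    step = np.empty(3)
    etry = np.empty(3)
    lam = 1e-8
    fd = 1e-5

    if m > 0:
        for _it in range(max_inner):
            # prediction gradients wrt active etas (forward differences)
            for jj in range(m):
                k = act[jj]
                e0, e1, e2 = eta[0], eta[1], eta[2]
                if k == 0:
                    e0 += fd
                elif k == 1:
                    e1 += fd
                else:
                    e2 += fd
                fp = _predict(
                    theta, e0, e1, e2, wt, study, trtind,
                    dose_t, dose_amt, obs_t, rtol, atol,
                )
                for j in range(n):
                    if np.isnan(fp[j]):
                        return np.inf
                    F[j, jj] = (fp[j] - f[j]) / fd
            # gradient and Gauss-Newton Hessian of g
            for jj in range(m):
                grad[jj] = eta[act[jj]] / om2[act[jj]]
                for ll in range(jj + 1):
                    H[jj, ll] = 0.0
            for j in range(n):
                fj = f[j]
                var = sig2 * fj * fj + eps2
                r = dv[j] - fj
                w = sig2 * fj / var - r / var - r * r * sig2 * fj / (var * var)
                for jj in range(m):
                    grad[jj] += F[j, jj] * w
                    for ll in range(jj + 1):
                        H[jj, ll] += F[j, jj] * F[j, ll] / var
            for jj in range(m):
                H[jj, jj] += 1.0 / om2[act[jj]]
                for ll in range(jj):
                    H[ll, jj] = H[jj, ll]
            gmax = 0.0
            for jj in range(m):
                if abs(grad[jj]) > gmax:
                    gmax = abs(grad[jj])
            if gmax < gtol:
                break
            # damped Newton step
            accepted = False
            for _t in range(14):
                for jj in range(m):
                    for ll in range(m):
                        Hd[jj, ll] = H[jj, ll]
                    Hd[jj, jj] += lam * H[jj, jj]
                if not _chol(Hd, m, L):
                    lam = lam * 10.0 + 1e-8
                    continue
                for jj in range(m):
                    step[jj] = -grad[jj]
                _chol_solve(L, step, m, step)
                # trust-region clamp: random effects live on the log scale,
                # steps beyond ~2 are never useful
                smax0 = 0.0
                for jj in range(m):
                    if abs(step[jj]) > smax0:
                        smax0 = abs(step[jj])
                if smax0 > 2.0:
                    for jj in range(m):
                        step[jj] *= 2.0 / smax0
                for k in range(3):
                    etry[k] = eta[k]
                for jj in range(m):
                    etry[act[jj]] = eta[act[jj]] + step[jj]
                ftry = _predict(
                    theta, etry[0], etry[1], etry[2], wt, study, trtind,
                    dose_t, dose_amt, obs_t, rtol, atol,
                )
                gtry = _gval(ftry, dv, sig2, eps2, etry, om2, act, m)
                if gtry < g:
                    for k in range(3):
                        eta[k] = etry[k]
                    for j in range(n):
                        f[j] = ftry[j]
                    g = gtry
                    lam *= 0.1
                    if lam < 1e-10:
                        lam = 1e-10
                    accepted = True
                    break
                lam *= 10.0
            if not accepted:
                break
            smax = 0.0
            for jj in range(m):
                if abs(step[jj]) > smax:
                    smax = abs(step[jj])
            if smax < stol:
                break

        # exact curvature of g at the mode by finite differences (the
        # Laplace correction); central along each axis, forward for the
        # cross terms.  Falls back to the Gauss-Newton information if the
        # difference estimate is not positive definite.
        # the exact curvature goes into its own matrix so the in-loop
        # Gauss-Newton information (always SPD) survives as the fallback
        # when the difference estimate fails or is not positive definite
        have_h = False
        if exact_hess:
            He = np.empty((3, 3))
            have_h = _exact_hess(
                theta, om2, sig2, eps2, wt, study, trtind,
                dose_t, dose_amt, obs_t, dv, eta, f, act, m, He, rtol, atol,
            )
            if have_h:
                have_h = _chol(He, m, L)
        if not have_h:
            # GN information from the last inner iteration, evaluated at
            # (or within a vanishing step of) the mode; re-factorize since
            # L was overwritten by the damped-step / exact-H attempts
            if not _chol(H, m, L):
                return np.inf

    ofv = 0.0
    for j in range(n):
        fj = f[j]
        var = sig2 * fj * fj + eps2
        r = dv[j] - fj
        ofv += _LOG2PI + np.log(var) + r * r / var
    for jj in range(m):
        k = act[jj]
        ofv += np.log(om2[k]) + eta[k] * eta[k] / om2[k]
        ofv += 2.0 * np.log(L[jj, jj])  # ln det G
    return ofv


@njit(cache=True)
def _exact_hess(
    theta, om2, sig2, eps2, wt, study, trtind,
    dose_t, dose_amt, obs_t, dv, eta, f, act, m, H, rtol, atol,
):
    """Finite-difference curvature of the joint -log density at the mode.
    Fills the leading m-by-m block of H; returns False when unusable."""
    hh = 1e-3
    etry = np.empty(3)
    g0 = _gval(f, dv, sig2, eps2, eta, om2, act, m)
    gp = np.empty(3)
    gm = np.empty(3)
    for jj in range(m):
        k = act[jj]
        for kk in range(3):
            etry[kk] = eta[kk]
        etry[k] = eta[k] + hh
        fp = _predict(
            theta, etry[0], etry[1], etry[2], wt, study, trtind,
            dose_t, dose_amt, obs_t, rtol, atol,
        )
        gp[jj] = _gval(fp, dv, sig2, eps2, etry, om2, act, m)
        etry[k] = eta[k] - hh
        fp = _predict(
            theta, etry[0], etry[1], etry[2], wt, study, trtind,
            dose_t, dose_amt, obs_t, rtol, atol,
        )
        gm[jj] = _gval(fp, dv, sig2, eps2, etry, om2, act, m)
        if not (np.isfinite(gp[jj]) and np.isfinite(gm[jj])):
            return False
        H[jj, jj] = (gp[jj] - 2.0 * g0 + gm[jj]) / (hh * hh)
    for jj in range(m):
        for ll in range(jj + 1, m):
            for kk in range(3):
                etry[kk] = eta[kk]
            etry[act[jj]] += hh
            etry[act[ll]] += hh
            fp = _predict(
                theta, etry[0], etry[1], etry[2], wt, study, trtind,
                dose_t, dose_amt, obs_t, rtol, atol,
            )
            gpp = _gval(fp, dv, sig2, eps2, etry, om2, act, m)
            if not np.isfinite(gpp):
                return False
            H[jj, ll] = (gpp - gp[jj] - gp[ll] + g0) / (hh * hh)
            H[ll, jj] = H[jj, ll]
    return True


@njit(cache=True)
def foce_total(
    theta,
    om2,
    sig2,
    eps2,
    obs_off,
    obs_t,
    dv,
    dose_off,
    dose_t,
    dose_amt,
    wt,
    study,
    trtind,
    etas,
    rtol,
    atol,
    exact_hess,
    gtol,
    stol,
    max_inner,
):
    """Total OFV over subjects; ``etas`` (n,3) holds warm-start conditional
    modes and is updated in place."""
    total = 0.0
    for i in range(wt.size):
        o0, o1 = obs_off[i], obs_off[i + 1]
        d0, d1 = dose_off[i], dose_off[i + 1]
        ofv_i = _subject_foce(
            theta,
            om2,
            sig2,
            eps2,
            wt[i],
            study[i],
            trtind[i],
            dose_t[d0:d1],
            dose_amt[d0:d1],
            obs_t[o0:o1],
            dv[o0:o1],
            etas[i],
            rtol,
            atol,
            exact_hess,
            gtol,
            stol,
            max_inner,
        )
        if not np.isfinite(ofv_i):
            return np.inf
        total += ofv_i
    return total
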