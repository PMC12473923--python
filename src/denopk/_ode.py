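"""Compiled kernels for the structural model.

The state is (depot amount, central amount, cumulative eliminated amount),
all in mg.  Concentration is central amount / V (mg/L).  Integration uses
an adaptive Dormand-Prince 5(4) pair; the system is non-stiff (rate
constants are of order 1/day or less at therapeutic concentrations), so an
explicit embedded pair at rtol 1e-8 is both accurate and fast.  Dose events
are handled by integrating exactly to each dose time and adding the dose to
the depot; observations falling on a dose time are evaluated pre-dose.
"""

import numpy as np
from numba import njit

# Dormand-Prince 5(4) coefficients
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (
    19372.0 / 6561.0,
    -25360.0 / 2187.0,
    64448.0 / 6561.0,
    -212.0 / 729.0,
)
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0,
    -355.0 / 33.0,
    46732.0 / 5247.0,
    49.0 / 176.0,
    -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = (
    35.0 / 384.0,
    500.0 / 1113.0,
    125.0 / 192.0,
    -2187.0 / 6784.0,
    11.0 / 84.0,
)
# 4th-order embedded weights
_E1, _E3, _E4, _E5, _E6, _E7 = (
    5179.0 / 57600.0,
    7571.0 / 16695.0,
    393.0 / 640.0,
    -92097.0 / 339200.0,
    187.0 / 2100.0,
    1.0 / 40.0,
)


@njit(cache=True, fastmath=False)
def _rhs(y, ka, v, cl, km, vmax, dy):
    a1 = y[0]
    c = y[1] / v
    if c < 0.0:
        c = 0.0
    denom = km + c
    mm = vmax * c / denom if denom > 0.0 else 0.0
    el = cl * c + mm
    dy[0] = -ka * a1
    dy[1] = ka * a1 - el
    dy[2] = el


@njit(cache=True)
def _advance(t0, t1, y, ka, v, cl, km, vmax, rtol, atol, h0):
    """Integrate y in place from t0 to t1; returns last accepted step size.

    Returns -1.0 on step-size underflow (signals invalid parameters).
    """
    if t1 <= t0:
        return h0
    t = t0
    h = h0
    if h <= 0.0 or h > t1 - t0:
        h = t1 - t0
    k1 = np.empty(3)
    k2 = np.empty(3)
    k3 = np.empty(3)
    k4 = np.empty(3)
    k5 = np.empty(3)
    k6 = np.empty(3)
    k7 = np.empty(3)
    yt = np.empty(3)
    yn = np.empty(3)
    _rhs(y, ka, v, cl, km, vmax, k1)
    nstep = 0
    while t < t1:
        nstep += 1
        if nstep > 20000:
            # pathological parameters (e.g. enormous saturable clearance
            # with tiny Km make the tail arbitrarily stiff): signal failure
            return -1.0
        if h > t1 - t:
            h = t1 - t
        for i in range(3):
            yt[i] = y[i] + h * _A21 * k1[i]
        _rhs(yt, ka, v, cl, km, vmax, k2)
        for i in range(3):
            yt[i] = y[i] + h * (_A31 * k1[i] + _A32 * k2[i])
        _rhs(yt, ka, v, cl, km, vmax, k3)
        for i in range(3):
            yt[i] = y[i] + h * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
        _rhs(yt, ka, v, cl, km, vmax, k4)
        for i in range(3):
            yt[i] = y[i] + h * (
                _A51 * k1[i] + _A52 * k2[i] + _A53 * k3[i] + _A54 * k4[i]
            )
        _rhs(yt, ka, v, cl, km, vmax, k5)
        for i in range(3):
            yt[i] = y[i] + h * (
                _A61 * k1[i]
                + _A62 * k2[i]
                + _A63 * k3[i]
                + _A64 * k4[i]
                + _A65 * k5[i]
            )
        _rhs(yt, ka, v, cl, km, vmax, k6)
        for i in range(3):
            yn[i] = y[i] + h * (
                _B1 * k1[i] + _B3 * k3[i] + _B4 * k4[i] + _B5 * k5[i] + _B6 * k6[i]
            )
        _rhs(yn, ka, v, cl, km, vmax, k7)
        err = 0.0
        for i in range(3):
            y4 = y[i] + h * (
                _E1 * k1[i]
                + _E3 * k3[i]
                + _E4 * k4[i]
                + _E5 * k5[i]
                + _E6 * k6[i]
                + _E7 * k7[i]
            )
            sc = atol + rtol * max(abs(y[i]), abs(yn[i]))
            e = (yn[i] - y4) / sc
            err += e * e
        err = np.sqrt(err / 3.0)
        if err <= 1.0:
            t += h
            for i in range(3):
                y[i] = yn[i]
                k1[i] = k7[i]
            fac = 5.0
            if err > 0.0:
                fac = 0.9 * err ** -0.2
                if fac > 5.0:
                    fac = 5.0
                elif fac < 0.2:
                    fac = 0.2
            h *= fac
        else:
            fac = 0.9 * err ** -0.2
            if fac < 0.1:
                fac = 0.1
            h *= fac
        if h < 1e-12:
            return -1.0
    return h


@njit(cache=True)
def conc_at_times(ka, v, cl, km, vmax, dose_t, dose_amt, obs_t, rtol, atol):
    """Concentrations (mg/L) and state at the sorted observation times.

    Observations coinciding with a dose time are evaluated before the dose
    is added (predose convention).  Returns (conc, depot, central,
    eliminated); all-NaN output signals integrator failure.
    """
    n_obs = obs_t.size
    n_d = dose_t.size
    conc = np.empty(n_obs)
    a1o = np.empty(n_obs)
    a2o = np.empty(n_obs)
    a3o = np.empty(n_obs)
    ok = (
        np.isfinite(ka) and np.isfinite(v) and np.isfinite(cl)
        and np.isfinite(km) and np.isfinite(vmax)
        and ka > 0.0 and v > 0.0 and km >= 0.0 and cl >= 0.0 and vmax >= 0.0
    )
    if not ok:
        conc[:] = np.nan
        a1o[:] = np.nan
        a2o[:] = np.nan
        a3o[:] = np.nan
        return conc, a1o, a2o, a3o
    y = np.zeros(3)
    t = 0.0
    i_o = 0
    i_d = 0
    h = 0.0
    big = 1e300
    while i_o < n_obs or i_d < n_d:
        t_o = obs_t[i_o] if i_o < n_obs else big
        t_d = dose_t[i_d] if i_d < n_d else big
        tt = t_o if t_o < t_d else t_d
        if tt > t:
            if y[0] < atol and y[1] < atol:
                # system is numerically empty: nothing left to integrate
                y[0] = 0.0
                y[1] = 0.0
                t = tt
            else:
                h = _advance(t, tt, y, ka, v, cl, km, vmax, rtol, atol, h)
            if h < 0.0:
                conc[:] = np.nan
                a1o[:] = np.nan
                a2o[:] = np.nan
                a3o[:] = np.nan
                return conc, a1o, a2o, a3o
            t = tt
        while i_o < n_obs and obs_t[i_o] == tt:
            c = y[1] / v
            conc[i_o] = c if c > 0.0 else 0.0
            a1o[i_o] = y[0]
            a2o[i_o] = y[1]
            a3o[i_o] = y[2]
            i_o += 1
        while i_d < n_d and dose_t[i_d] == tt:
            y[0] += dose_amt[i_d]
            i_d += 1
    return conc, a1o, a2o, a3o
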