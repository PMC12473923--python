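"""Structural PK model: one compartment, first-order SC absorption,
parallel linear and Michaelis-Menten (saturable, target-mediated)
elimination.

Internal units throughout the package: amounts in mg, volumes in L, time
in days, concentrations in mg/L (numerically equal to ug/mL).  Apparent
parameterization (CL/F, V/F): the full labeled dose enters the depot and
bioavailability is absorbed into the apparent parameters.

Individual parameters arise from population typical values on the natural
log scale (MU referencing) plus covariate terms and log-normal
inter-individual random effects:

    CL_i/F = exp(mu_cl + beta_bw_cl * ln(WT_i / 70) + eta_cl,i)
    V_i/F  = exp(mu_v  + beta_study_v * STUDY_i     + eta_v,i)
    KA_i   = exp(mu_ka                              + eta_ka,i)
    Km     = exp(mu_km),  Vmax = exp(mu_vm)          (no IIV)

Body weight is centered at 70 kg, so exp(mu_cl) is the typical clearance of
a 70 kg subject.  Optional treatment-arm effects (used only for covariate
testing) multiply CL, V or KA by exp(beta_trt_* * I[arm == test arm]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._ode import conc_at_times

#: default integration tolerances (relative; absolute in mg)
RTOL = 1e-8
ATOL = 1e-10


@dataclass(frozen=True)
class StructuralParams:
    """Individual-level kinetic constants.

    ka: absorption rate constant (1/day); v: apparent central volume V/F
    (L); cl: apparent linear clearance CL/F (L/day); km: Michaelis constant
    (mg/L); vmax: maximum saturable elimination rate (mg/day).
    """

    ka: float
    v: float
    cl: float
    km: float
    vmax: float

    def __post_init__(self) -> None:
        if not (self.ka > 0 and self.v > 0 and self.km > 0):
            raise ValueError("ka, v and km must be positive")
        if self.cl < 0 or self.vmax < 0:
            raise ValueError("cl and vmax must be nonnegative")
        for f in (self.ka, self.v, self.cl, self.km, self.vmax):
            if not math.isfinite(f):
                raise ValueError("non-finite structural parameter")


@dataclass(frozen=True)
class FixedEffects:
    """Population fixed effects: log-scale typical values plus covariate
    coefficients (weight power on CL, study shift on log V, optional
    treatment shifts used in covariate testing)."""

    mu_cl: float
    mu_v: float
    mu_ka: float
    mu_km: float
    mu_vm: float
    beta_bw_cl: float = 0.0
    beta_study_v: float = 0.0
    beta_trt_cl: float = 0.0
    beta_trt_v: float = 0.0
    beta_trt_ka: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.mu_cl,
                self.mu_v,
                self.mu_ka,
                self.mu_km,
                self.mu_vm,
                self.beta_bw_cl,
                self.beta_study_v,
                self.beta_trt_cl,
                self.beta_trt_v,
                self.beta_trt_ka,
            ]
        )


@dataclass
class RandomEffectsSpec:
    """Variances (omega^2) of the exponential inter-individual random
    effects on CL, V and KA (diagonal omega matrix)."""

    omega2_cl: float
    omega2_v: float
    omega2_ka: float

    def as_array(self) -> np.ndarray:
        return np.array([self.omega2_cl, self.omega2_v, self.omega2_ka])


@dataclass
class ResidualSpec:
    """Proportional residual error: DV = C * (1 + eps), eps ~ N(0, sigma^2)."""

    sigma_prop: float


@dataclass(frozen=True)
class CovariateRecord:
    """Subject covariates: body weight (kg), study indicator
    (0 = rich single-dose phase-I-like, 1 = sparse multi-dose
    phase-III-like) and treatment arm code."""

    wt: float
    study: int = 0
    trt: int = 1

    def __post_init__(self) -> None:
        if self.wt <= 0:
            raise ValueError("weight must be positive")
        if self.study not in (0, 1):
            raise ValueError("study must be 0 or 1")


@dataclass(frozen=True)
class DoseEvent:
    """A subcutaneous dose into the absorption depot."""

    time: float
    amount: float
    target: str = "depot"

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.time < 0:
            raise ValueError("dose time must be nonnegative")


@dataclass
class ConcProfile:
    """Predicted concentration-time profile with the underlying amounts."""

    times: np.ndarray
    conc: np.ndarray
    depot: np.ndarray
    central: np.ndarray
    eliminated: np.ndarray = field(default=None)  # type: ignore[assignment]


def individual_params(
    fixed: FixedEffects,
    eta: tuple[float, float, float] | np.ndarray,
    cov: CovariateRecord,
    trt_test_arm: int | None = None,
) -> StructuralParams:
    """Map population fixed effects + random effects + covariates to one
    subject's structural parameters.

    ``eta`` is (eta_cl, eta_v, eta_ka).  ``trt_test_arm`` activates the
    treatment coefficients for subjects in that arm (covariate testing).
    """
    ind = 1.0 if (trt_test_arm is not None and cov.trt == trt_test_arm) else 0.0
    cl = math.exp(
        fixed.mu_cl
        + fixed.beta_bw_cl * math.log(cov.wt / 70.0)
        + fixed.beta_trt_cl * ind
        + eta[0]
    )
    v = math.exp(
        fixed.mu_v + fixed.beta_study_v * cov.study + fixed.beta_trt_v * ind + eta[1]
    )
    ka = math.exp(fixed.mu_ka + fixed.beta_trt_ka * ind + eta[2])
    km = math.exp(fixed.mu_km)
    vmax = math.exp(fixed.mu_vm)
    for x in (cl, v, ka):
        if not math.isfinite(x):
            raise ValueError("non-finite individual parameter")
    return StructuralParams(ka=ka, v=v, cl=cl, km=km, vmax=vmax)


def rhs(t: float, amounts, p: StructuralParams):
    """Time derivative of (depot, central) amounts in mg/day.

    d(depot)/dt = -ka*depot; d(central)/dt = ka*depot - cl*C - vmax*C/(km+C)
    with C = central/v.
    """
    depot, central = amounts[0], amounts[1]
    c = max(central, 0.0) / p.v
    elim = p.cl * c + p.vmax * c / (p.km + c)
    return np.array([-p.ka * depot, p.ka * depot - elim])


def _events_arrays(doses) -> tuple[np.ndarray, np.ndarray]:
    dt = np.array([d.time for d in doses], dtype=float)
    da = np.array([d.amount for d in doses], dtype=float)
    order = np.argsort(dt, kind="stable")
    return dt[order], da[order]


def solve_profile(
    p: StructuralParams,
    doses,
    times,
    rtol: float = RTOL,
    atol: float = ATOL,
    method: str = "dopri",
) -> ConcProfile:
    """Solve the concentration-time profile at the requested times.

    ``times`` must be sorted and nonnegative; observations at a dose time
    are evaluated pre-dose.  ``method='lsoda'`` routes the integration
    through :func:`scipy.integrate.solve_ivp` (slower; used for
    cross-validation of the compiled integrator).
    """
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted nondecreasing")
    if times.size and times[0] < 0:
        raise ValueError("times must be nonnegative")
    if not doses:
        raise ValueError("at least one dose is required")
    dt, da = _events_arrays(doses)
    if method == "dopri":
        conc, a1, a2, a3 = conc_at_times(
            p.ka, p.v, p.cl, p.km, p.vmax, dt, da, times, rtol, atol
        )
        if np.any(np.isnan(conc)):
            raise RuntimeError("ODE integration failed (invalid parameters?)")
    elif method == "lsoda":
        conc, a1, a2, a3 = _solve_scipy(p, dt, da, times, rtol, atol)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ConcProfile(times=times, conc=conc, depot=a1, central=a2, eliminated=a3)


def _solve_scipy(p, dose_t, dose_amt, times, rtol, atol):
    from scipy.integrate import solve_ivp

    def f(t, y):
        c = max(y[1], 0.0) / p.v
        elim = p.cl * c + p.vmax * c / (p.km + c)
        return [-p.ka * y[0], p.ka * y[0] - elim, elim]

    y = np.zeros(3)
    t = 0.0
    n = times.size
    out = np.zeros((n, 3))
    i_o = 0
    i_d = 0
    big = np.inf
    while i_o < n or i_d < dose_t.size:
        t_o = times[i_o] if i_o < n else big
        t_d = dose_t[i_d] if i_d < dose_t.size else big
        tt = min(t_o, t_d)
        if tt > t:
            sol = solve_ivp(
                f, (t, tt), y, method="LSODA", rtol=rtol, atol=atol, dense_output=False
            )
            if not sol.success:
                raise RuntimeError("LSODA integration failed")
            y = sol.y[:, -1]
            t = tt
        while i_o < n and times[i_o] == tt:
            out[i_o] = y
            i_o += 1
        while i_d < dose_t.size and dose_t[i_d] == tt:
            y[0] += dose_amt[i_d]
            i_d += 1
    conc = np.maximum(out[:, 1], 0.0) / p.v
    return conc, out[:, 0], out[:, 1], out[:, 2]


def bateman_profile(dose: float, ka: float, v: float, cl: float, times) -> np.ndarray:
    """Closed-form linear one-compartment SC profile (vmax = 0):
    C(t) = D*ka / (v*(ka-k)) * (exp(-k t) - exp(-ka t)), k = cl/v."""
    times = np.asarray(times, dtype=float)
    k = cl / v
    if abs(ka - k) < 1e-12:
        return dose * ka * times * np.exp(-ka * times) / v
    return dose * ka / (v * (ka - k)) * (np.exp(-k * times) - np.exp(-ka * times))
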