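"""Approximate marginal-likelihood (FOCE-I/Laplace) estimation.

The population model couples the structural one-compartment MM model with
log-normal inter-individual variability on CL, V and KA, a proportional
residual error, and optional covariate terms (body-weight power on CL
centered at 70 kg, an additive study shift on log V, and treatment-arm
shifts used only for covariate testing).  The marginal likelihood is
approximated subject by subject with a Laplace expansion about the
conditional mode of the random effects, with the residual variance
evaluated at the conditional prediction (interaction).

Variance parameters are estimated on the log scale.  Standard errors come
from the inverse observed information (numeric Hessian of the OFV; the
OFV is -2 log L, so Cov = 2 H^-1), reported on the natural scale via the
delta method, as is conventional for NONMEM-style output tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from ._foce import EPS_FLOOR, _subject_foce, foce_total
from .dataset_io import SubjectData
from .model_core import (
    ATOL,
    RTOL,
    CovariateRecord,
    DoseEvent,
    FixedEffects,
    RandomEffectsSpec,
    ResidualSpec,
    individual_params,
    solve_profile,
)

_THETA_NAMES = (
    "mu_cl",
    "mu_v",
    "mu_ka",
    "mu_km",
    "mu_vm",
    "beta_bw_cl",
    "beta_study_v",
    "beta_trt_cl",
    "beta_trt_v",
    "beta_trt_ka",
)


@dataclass
class PopulationModel:
    """Fixed effects, IIV variances, residual error and covariate switches."""

    fixed: FixedEffects
    iiv: RandomEffectsSpec
    residual: ResidualSpec
    bw_on_cl: bool = True
    study_on_v: bool = False
    trt_on: tuple[str, ...] = ()
    trt_test_arm: int | None = None

    def free_names(self) -> list[str]:
        names = ["mu_cl", "mu_v", "mu_ka", "mu_km", "mu_vm"]
        if self.bw_on_cl:
            names.append("beta_bw_cl")
        if self.study_on_v:
            names.append("beta_study_v")
        for p in self.trt_on:
            if p not in ("cl", "v", "ka"):
                raise ValueError(f"unknown treatment covariate target {p!r}")
            names.append(f"beta_trt_{p}")
        for k, w in zip(("cl", "v", "ka"), self.iiv.as_array()):
            if w > 0:
                names.append(f"omega2_{k}")
        names.append("sigma_prop")
        return names


@dataclass
class FitResult:
    estimates: PopulationModel
    ofv: float
    converged: bool
    n_subjects: int
    n_obs: int
    param_names: list[str]
    se: dict = field(default_factory=dict)
    rse_pct: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    ebes: np.ndarray = None  # type: ignore[assignment]
    eta_shrinkage_pct: dict = field(default_factory=dict)
    n_evaluations: int = 0
    message: str = ""


@dataclass
class LRTResult:
    delta_ofv: float
    df: int
    p_value: float
    significant: bool
    ofv_reduced: float
    ofv_full: float


# ---------------------------------------------------------------------------
# packing / parameter vector plumbing


def pack_data(subjects: list[SubjectData], trt_test_arm: int | None = None):
    """Flatten subjects into the contiguous arrays the compiled kernel uses."""
    n = len(subjects)
    obs_off = np.zeros(n + 1, dtype=np.int64)
    dose_off = np.zeros(n + 1, dtype=np.int64)
    for i, s in enumerate(subjects):
        if s.n_obs < 1:
            raise ValueError(f"subject {s.id} has no observations")
        obs_off[i + 1] = obs_off[i] + s.n_obs
        dose_off[i + 1] = dose_off[i] + s.dose_times.size
    obs_t = np.concatenate([s.obs_times for s in subjects]).astype(float)
    dv = np.concatenate([s.dv for s in subjects]).astype(float)
    dose_t = np.concatenate([s.dose_times for s in subjects]).astype(float)
    dose_amt = np.concatenate([s.dose_amts for s in subjects]).astype(float)
    wt = np.array([s.wt for s in subjects], dtype=float)
    study = np.array([float(s.study) for s in subjects])
    trtind = np.array(
        [1.0 if (trt_test_arm is not None and s.trt == trt_test_arm) else 0.0 for s in subjects]
    )
    return obs_off, obs_t, dv, dose_off, dose_t, dose_amt, wt, study, trtind


def _model_vectors(model: PopulationModel):
    theta = model.fixed.as_array()
    om2 = model.iiv.as_array().astype(float)
    sig2 = float(model.residual.sigma_prop) ** 2
    return theta, om2, sig2


def _x_from_model(model: PopulationModel, names: list[str]) -> np.ndarray:
    theta, om2, sig2 = _model_vectors(model)
    lut = dict(zip(_THETA_NAMES, theta))
    lut["omega2_cl"], lut["omega2_v"], lut["omega2_ka"] = om2
    x = []
    for nm in names:
        if nm.startswith("omega2"):
            x.append(math.log(lut[nm]))
        elif nm == "sigma_prop":
            x.append(math.log(sig2))
        else:
            x.append(lut[nm])
    return np.array(x)


def _model_from_x(x: np.ndarray, names: list[str], template: PopulationModel) -> PopulationModel:
    theta, om2, sig2 = _model_vectors(template)
    lut = dict(zip(names, x))
    tvals = list(theta)
    for i, nm in enumerate(_THETA_NAMES):
        if nm in lut:
            tvals[i] = lut[nm]
    for i, nm in enumerate(("omega2_cl", "omega2_v", "omega2_ka")):
        if nm in lut:
            om2[i] = math.exp(lut[nm])
    if "sigma_prop" in lut:
        sig2 = math.exp(lut["sigma_prop"])
    fixed = FixedEffects(*tvals)
    iiv = RandomEffectsSpec(*om2)
    resid = ResidualSpec(sigma_prop=math.sqrt(sig2))
    return replace(template, fixed=fixed, iiv=iiv, residual=resid)


# ---------------------------------------------------------------------------
# objective and fitting


#: relaxed integration tolerances used inside the optimizer loop (final
#: reported OFVs are recomputed at the tight defaults)
FIT_RTOL = 1e-6
FIT_ATOL = 1e-8


def marginal_ofv(
    model: PopulationModel,
    subjects: list[SubjectData],
    etas: np.ndarray | None = None,
    return_etas: bool = False,
):
    """FOCE-I approximate -2 log marginal likelihood of the dataset, with
    the exact-curvature Laplace correction."""
    packed = pack_data(subjects, model.trt_test_arm)
    theta, om2, sig2 = _model_vectors(model)
    if etas is None:
        etas = np.zeros((len(subjects), 3))
    val = foce_total(theta, om2, sig2, EPS_FLOOR**2, *packed, etas, RTOL, ATOL, True, 1e-7, 1e-9, 60)
    if return_etas:
        return float(val), etas
    return float(val)


def empirical_bayes(model: PopulationModel, subject: SubjectData) -> np.ndarray:
    """Conditional mode of the subject's random effects under ``model``.

    Subjects whose observations carry no information (or a failed mode
    search) return eta = 0, the prior mode.
    """
    theta, om2, sig2 = _model_vectors(model)
    ind = 1.0 if (model.trt_test_arm is not None and subject.trt == model.trt_test_arm) else 0.0
    eta = np.zeros(3)
    ofv = _subject_foce(
        theta,
        om2,
        sig2,
        EPS_FLOOR**2,
        subject.wt,
        float(subject.study),
        ind,
        subject.dose_times.astype(float),
        subject.dose_amts.astype(float),
        subject.obs_times.astype(float),
        subject.dv.astype(float),
        eta,
        RTOL,
        ATOL,
        False,
        1e-7,
        1e-9,
        60,
    )
    if not np.isfinite(ofv):
        return np.zeros(3)
    return eta


def empirical_bayes_all(model: PopulationModel, subjects: list[SubjectData]) -> np.ndarray:
    return np.array([empirical_bayes(model, s) for s in subjects])


def eta_shrinkage(ebes: np.ndarray, iiv: RandomEffectsSpec) -> dict:
    """Shrinkage% = 100 (1 - SD(EBE)/omega) per random effect; omega = 0 -> NaN."""
    out = {}
    for k, (nm, w2) in enumerate(
        zip(("cl", "v", "ka"), (iiv.omega2_cl, iiv.omega2_v, iiv.omega2_ka))
    ):
        if w2 <= 0:
            out[nm] = float("nan")
        else:
            out[nm] = 100.0 * (1.0 - np.std(ebes[:, k], ddof=1) / math.sqrt(w2))
    return out


def fit(
    subjects: list[SubjectData],
    init: PopulationModel,
    fix: tuple[str, ...] = (),
    compute_se: bool = True,
    seed: int = 0,
    maxfev: int = 1200,
    max_total_fev: int | None = None,
    multistart: int = 3,
    verbose: bool = False,
) -> FitResult:
    """Maximize the FOCE-I marginal likelihood from ``init``.

    ``fix`` names parameters held at their initial values.  Non-convergence
    triggers up to ``multistart - 1`` restarts from jittered initial
    vectors; the best minimum found is returned either way.
    """
    names = [nm for nm in init.free_names() if nm not in fix]
    if not names:
        raise ValueError("no free parameters")
    packed = pack_data(subjects, init.trt_test_arm)
    n_sub = len(subjects)
    n_obs = int(packed[0][-1])
    etas = np.zeros((n_sub, 3))
    eps2 = EPS_FLOOR**2
    template = init
    n_eval = [0]

    def objective(x: np.ndarray) -> float:
        # classical FOCE linearization + relaxed ODE tolerance inside the
        # optimizer; the reported OFV is recomputed with the exact-curvature
        # correction at tight tolerance
        model = _model_from_x(x, names, template)
        theta, om2, sig2 = _model_vectors(model)
        val = foce_total(
            theta, om2, sig2, eps2, *packed, etas, FIT_RTOL, FIT_ATOL, False, 1e-5, 1e-7, 60
        )
        n_eval[0] += 1
        if not np.isfinite(val):
            # failed evaluations may leave stale conditional modes behind
            etas[:] = 0.0
            return 1e10
        return val

    x0 = _x_from_model(init, names)
    # generous but physiologically sane boxes (log scale for mu and
    # variances); they keep line searches out of regions where the ODE
    # becomes arbitrarily stiff
    _mu_bounds = dict(
        mu_cl=(-7.0, 3.0),    # CL/F 0.0009 .. 20 L/day
        mu_v=(-3.0, 6.0),     # V/F 0.05 .. 400 L
        mu_ka=(-7.0, 4.0),    # KA up to ~55 1/day
        mu_km=(-11.5, 5.0),   # Km 1e-5 .. 150 mg/L
        mu_vm=(-11.5, 5.0),   # Vmax 1e-5 .. 150 mg/day
    )
    bounds = []
    for nm in names:
        if nm in _mu_bounds:
            bounds.append(_mu_bounds[nm])
        elif nm.startswith("omega2") or nm == "sigma_prop":
            bounds.append((-12.0, 2.0))
        else:
            bounds.append((-10.0, 10.0))
    rng = np.random.default_rng(seed)

    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])
    box = optimize.Bounds(lb, ub)

    def run_one(xstart):
        # Derivative-free trust-region (COBYQA) stage followed by
        # small-radius restarts: the objective carries mild evaluation
        # noise (warm-started conditional modes, adaptive integration), and
        # a quadratic-model method handles that far more economically than
        # finite-difference quasi-Newton.  Restarts with a fresh model
        # escape the noise floor; convergence is declared when a restart
        # no longer improves the OFV materially.
        res = optimize.minimize(
            objective,
            xstart,
            method="cobyqa",
            bounds=box,
            options=dict(maxfev=maxfev, final_tr_radius=1e-5),
        )
        best_f, best_x = res.fun, res.x.copy()
        msg = str(res.message)
        if verbose:
            print(f"  stage ofv={res.fun:.4f} nfev={res.nfev}")
        ok = False
        radius = 0.05
        budget = 3 * maxfev if max_total_fev is None else max_total_fev
        start_eval = n_eval[0]
        for _restart in range(8):
            if n_eval[0] - start_eval >= budget:
                break
            res = optimize.minimize(
                objective,
                best_x,
                method="cobyqa",
                bounds=box,
                options=dict(
                    maxfev=min(maxfev // 2, budget - (n_eval[0] - start_eval)),
                    initial_tr_radius=radius,
                    final_tr_radius=1e-5,
                ),
            )
            improv = best_f - res.fun
            if res.fun < best_f:
                best_f, best_x = res.fun, res.x.copy()
            msg = str(res.message)
            if verbose:
                print(f"  restart ofv={res.fun:.4f} nfev={res.nfev} improv={improv:.3f}")
            if best_f < 9e9 and improv < 0.5:
                # below the restart-to-restart reproducibility of the
                # objective: converged
                ok = True
                break
            # a restart that is still descending steeply means the stage
            # quit far from the optimum: search wide again
            radius = 0.3 if improv > 5.0 else 0.05
        return best_x, best_f, ok, msg

    best_x, best_f, converged, message = None, np.inf, False, ""
    for attempt in range(max(1, multistart)):
        xstart = x0 if attempt == 0 else np.clip(
            x0 + rng.normal(0.0, 0.25, size=x0.size),
            [b[0] for b in bounds],
            [b[1] for b in bounds],
        )
        etas[:] = 0.0
        x, fval, ok, msg = run_one(xstart)
        if verbose:
            print(f"attempt {attempt}: ofv={fval:.4f} converged={ok}")
        if fval < best_f:
            best_x, best_f, message = x, fval, msg
        if ok and fval < 9e9:
            converged = True
            break
    assert best_x is not None
    xhat = best_x
    est_model = _model_from_x(xhat, names, template)

    # refresh conditional modes at the optimum
    ofv, ebes = marginal_ofv(est_model, subjects, return_etas=True)
    result = FitResult(
        estimates=est_model,
        ofv=float(ofv),
        converged=bool(converged),
        n_subjects=n_sub,
        n_obs=n_obs,
        param_names=list(names),
        ebes=ebes,
        eta_shrinkage_pct=eta_shrinkage(ebes, est_model.iiv),
        n_evaluations=n_eval[0],
        message=message,
    )
    if compute_se:
        # the information matrix is differenced on the exact-curvature,
        # tight-tolerance objective: the relaxed fit-time objective is too
        # noisy at the quadratic scale of the curvature
        etas_se = np.zeros((n_sub, 3))

        def objective_exact(x: np.ndarray) -> float:
            model = _model_from_x(x, names, template)
            theta, om2, sig2 = _model_vectors(model)
            val = foce_total(
                theta, om2, sig2, eps2, *packed, etas_se, RTOL, ATOL, True, 1e-7, 1e-9, 60
            )
            return val if np.isfinite(val) else 1e10

        _wald_intervals(result, objective_exact, xhat, names)
    return result


def _wald_intervals(result: FitResult, objective, xhat, names, target: float = 4.0) -> None:
    """Numeric observed information -> natural-scale SE / %RSE / 95% CI.

    Finite-difference steps are calibrated per parameter so the diagonal
    OFV increment is of order ``target`` units: a fixed step is either
    swamped by evaluation noise (flat directions) or dominated by
    higher-order terms (very steep ones, e.g. sigma at small residual
    error).
    """
    p = len(names)
    f0 = objective(xhat)
    h = np.full(p, 0.02)
    d = np.empty(p)
    for _pass in range(3):
        for i in range(p):
            xi = xhat.copy()
            xi[i] += h[i]
            fp = objective(xi)
            xi[i] -= 2 * h[i]
            fm = objective(xi)
            d[i] = fp - 2 * f0 + fm
        if np.all((d > target / 4) & (d < target * 4)):
            break
        grow = d <= 0
        h = np.clip(
            h * np.where(grow, 3.0, np.sqrt(target / np.clip(d, 1e-3, None))),
            1e-4,
            0.2,
        )
    H = np.diag(d / h**2)
    for i in range(p):
        for j in range(i + 1, p):
            x1 = xhat.copy()
            x1[i] += h[i]
            x1[j] += h[j]
            x2 = xhat.copy()
            x2[i] += h[i]
            x2[j] -= h[j]
            x3 = xhat.copy()
            x3[i] -= h[i]
            x3[j] += h[j]
            x4 = xhat.copy()
            x4[i] -= h[i]
            x4[j] -= h[j]
            H[i, j] = H[j, i] = (
                objective(x1) - objective(x2) - objective(x3) + objective(x4)
            ) / (4 * h[i] * h[j])
    try:
        cov = 2.0 * np.linalg.inv(H)
        dg = np.diag(cov)
        if np.any(dg <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
    except np.linalg.LinAlgError:
        result.converged = False
        result.message += " | singular information matrix: CIs omitted"
        return
    se_x = np.sqrt(dg)
    z = stats.norm.ppf(0.975)
    for nm, xv, sx in zip(names, xhat, se_x):
        if nm.startswith("mu_"):
            est = math.exp(xv)
            result.se[nm] = est * sx
            result.ci95[nm] = (math.exp(xv - z * sx), math.exp(xv + z * sx))
        elif nm.startswith("omega2") or nm == "sigma_prop":
            # reported on the SD scale: omega (or sigma) = exp(x/2)
            est = math.exp(xv / 2)
            result.se[nm] = est * sx / 2
            result.ci95[nm] = (math.exp((xv - z * sx) / 2), math.exp((xv + z * sx) / 2))
        else:
            est = xv
            result.se[nm] = sx
            result.ci95[nm] = (xv - z * sx, xv + z * sx)
        result.rse_pct[nm] = 100.0 * result.se[nm] / abs(est) if est != 0 else float("inf")


def lrt_covariate(
    subjects: list[SubjectData],
    base_init: PopulationModel,
    extended_init: PopulationModel,
    alpha: float = 0.05,
    seed: int = 0,
    **fit_kwargs,
) -> LRTResult:
    """Likelihood-ratio test of nested covariate models (chi-square, df =
    number of added parameters)."""
    base_names = set(base_init.free_names())
    ext_names = set(extended_init.free_names())
    if not base_names <= ext_names:
        raise ValueError("extended model must nest the base model")
    df = len(ext_names) - len(base_names)
    if df < 1:
        raise ValueError("extended model adds no parameters")
    fit_kwargs.setdefault("compute_se", False)
    base = fit(subjects, base_init, seed=seed, **fit_kwargs)
    full = fit(subjects, extended_init, seed=seed, **fit_kwargs)
    delta = base.ofv - full.ofv
    if delta < -0.5:
        raise RuntimeError(
            f"full-model OFV exceeds reduced-model OFV by {-delta:.2f}: convergence fault"
        )
    delta = max(delta, 0.0)
    p = float(stats.chi2.sf(delta, df))
    return LRTResult(
        delta_ofv=float(delta),
        df=df,
        p_value=p,
        significant=p < alpha,
        ofv_reduced=base.ofv,
        ofv_full=full.ofv,
    )


def model_to_dict(model: PopulationModel) -> dict:
    """JSON-serializable representation of a population model."""
    return dict(
        fixed={k: getattr(model.fixed, k) for k in _THETA_NAMES},
        iiv=dict(
            omega2_cl=model.iiv.omega2_cl,
            omega2_v=model.iiv.omega2_v,
            omega2_ka=model.iiv.omega2_ka,
        ),
        residual=dict(sigma_prop=model.residual.sigma_prop),
        bw_on_cl=model.bw_on_cl,
        study_on_v=model.study_on_v,
        trt_on=list(model.trt_on),
        trt_test_arm=model.trt_test_arm,
    )


def model_from_dict(d: dict) -> PopulationModel:
    return PopulationModel(
        fixed=FixedEffects(**d["fixed"]),
        iiv=RandomEffectsSpec(**d["iiv"]),
        residual=ResidualSpec(**d["residual"]),
        bw_on_cl=bool(d.get("bw_on_cl", True)),
        study_on_v=bool(d.get("study_on_v", False)),
        trt_on=tuple(d.get("trt_on", ())),
        trt_test_arm=d.get("trt_test_arm"),
    )


def fit_report(result: FitResult) -> dict:
    """JSON-serializable fit summary (estimates on the natural scale)."""
    e = result.estimates
    natural = dict(
        cl_f=math.exp(e.fixed.mu_cl),
        v_f=math.exp(e.fixed.mu_v),
        ka=math.exp(e.fixed.mu_ka),
        km=math.exp(e.fixed.mu_km),
        vmax=math.exp(e.fixed.mu_vm),
        beta_bw_cl=e.fixed.beta_bw_cl,
        beta_study_v=e.fixed.beta_study_v,
        iiv_cv_pct=dict(
            cl=100 * math.sqrt(e.iiv.omega2_cl),
            v=100 * math.sqrt(e.iiv.omega2_v),
            ka=100 * math.sqrt(e.iiv.omega2_ka),
        ),
        sigma_prop=e.residual.sigma_prop,
    )
    return dict(
        ofv=result.ofv,
        converged=result.converged,
        n_subjects=result.n_subjects,
        n_obs=result.n_obs,
        estimates=natural,
        model=model_to_dict(e),
        se=result.se,
        rse_pct=result.rse_pct,
        ci95={k: list(v) for k, v in result.ci95.items()},
        eta_shrinkage_pct=result.eta_shrinkage_pct,
        message=result.message,
    )


def format_fit_table(result: FitResult) -> str:
    """Human-readable estimate / %RSE / 95% CI / IIV table."""
    e = result.estimates
    rows = [
        ("KA (1/day)", "mu_ka", math.exp(e.fixed.mu_ka), "ka"),
        ("V/F (L)", "mu_v", math.exp(e.fixed.mu_v), "v"),
        ("CL/F (L/day)", "mu_cl", math.exp(e.fixed.mu_cl), "cl"),
        ("BW~CL", "beta_bw_cl", e.fixed.beta_bw_cl, None),
        ("Km (mg/L)", "mu_km", math.exp(e.fixed.mu_km), None),
        ("Vm (mg/day)", "mu_vm", math.exp(e.fixed.mu_vm), None),
    ]
    if e.study_on_v:
        rows.append(("Study~V", "beta_study_v", e.fixed.beta_study_v, None))
    om = dict(
        ka=100 * math.sqrt(e.iiv.omega2_ka),
        v=100 * math.sqrt(e.iiv.omega2_v),
        cl=100 * math.sqrt(e.iiv.omega2_cl),
    )
    lines = [
        f"{'Parameter':<14}{'Estimate':>10}{'%RSE':>8}{'95% CI':>22}{'IIV CV%':>9}"
    ]
    for label, nm, est, iiv_key in rows:
        if nm not in result.param_names:
            continue
        rse = result.rse_pct.get(nm)
        ci = result.ci95.get(nm)
        rse_s = f"{rse:.1f}" if rse is not None else "-"
        ci_s = f"[{ci[0]:.4g}, {ci[1]:.4g}]" if ci else "-"
        iiv_s = f"{om[iiv_key]:.0f}%" if iiv_key else ""
        lines.append(f"{label:<14}{est:>10.4g}{rse_s:>8}{ci_s:>22}{iiv_s:>9}")
    lines.append(
        f"{'Residual':<14}{100 * e.residual.sigma_prop:>9.1f}%  (proportional CV)"
    )
    lines.append(f"OFV {result.ofv:.3f} | converged: {result.converged}")
    return "\n".join(lines)


def nca_init(
    subjects: list[SubjectData],
    study_on_v: bool = False,
    trt_on: tuple[str, ...] = (),
    trt_test_arm: int | None = None,
) -> PopulationModel:
    """Data-driven starting values by crude noncompartmental reasoning.

    Clearance from dose over the observed trapezoidal AUC, volume from dose
    over Cmax, a generic absorption rate, and Michaelis-Menten constants
    scaled so the saturable pathway is comparable to the linear one at
    mid-range concentrations.  Only used to initialize the optimizer.
    """
    # trapezoid AUC and observed Cmax are only meaningful on subjects with
    # reasonably dense sampling; in a pooled rich + sparse dataset the
    # sparse (trough-only) subjects would wreck the medians
    n_meas = np.array([int((s.dv > 0).sum()) for s in subjects])
    dense_cut = 8 if (n_meas >= 8).any() else 3
    cls, vs = [], []
    cmaxes = []
    for s, nm in zip(subjects, n_meas):
        if nm < dense_cut:
            continue
        meas = s.dv > 0
        t, c = s.obs_times[meas], s.dv[meas]
        auc = np.trapezoid(c, t)
        if auc <= 0:
            continue
        dose_total = float(np.sum(s.dose_amts))
        cmax = float(c.max())
        cmaxes.append(cmax)
        cls.append(0.8 * dose_total / auc)
        vs.append(0.8 * s.dose_amts[0] / cmax)
    if not cls:
        raise ValueError("no usable subjects for initialization")
    cl0 = float(np.median(cls))
    v0 = float(np.median(vs))
    cmax0 = float(np.median(cmaxes))
    return PopulationModel(
        fixed=FixedEffects(
            mu_cl=math.log(cl0),
            mu_v=math.log(v0),
            mu_ka=math.log(0.3),
            mu_km=math.log(0.05 * cmax0),
            mu_vm=math.log(cl0 * cmax0 / 3.0),
            beta_bw_cl=0.75,
        ),
        iiv=RandomEffectsSpec(0.09, 0.09, 0.25),
        residual=ResidualSpec(sigma_prop=0.2),
        bw_on_cl=True,
        study_on_v=study_on_v,
        trt_on=trt_on,
        trt_test_arm=trt_test_arm,
    )


# ---------------------------------------------------------------------------
# individual predictions and the quadrature cross-check


def predict_subject(
    model: PopulationModel,
    subject: SubjectData,
    eta=(0.0, 0.0, 0.0),
    times=None,
    method: str = "dopri",
) -> np.ndarray:
    """Model-predicted concentrations for one subject at its (or given) times."""
    cov = CovariateRecord(wt=subject.wt, study=subject.study, trt=subject.trt)
    p = individual_params(model.fixed, eta, cov, model.trt_test_arm)
    doses = [DoseEvent(t, a) for t, a in zip(subject.dose_times, subject.dose_amts)]
    tt = subject.obs_times if times is None else times
    return solve_profile(p, doses, tt, method=method).conc


def gauss_hermite_ofv(
    model: PopulationModel, subject: SubjectData, n_nodes: int = 41
) -> float:
    """Exact (to quadrature accuracy) -2 log marginal likelihood for a
    subject with a single active random effect, by adaptive Gauss-Hermite
    quadrature centered at the conditional mode.

    Serves as an independent numerical oracle for the Laplace/FOCE
    approximation; predictions are routed through the LSODA integrator so
    the two paths share no stepping code.
    """
    om2 = model.iiv.as_array()
    active = np.flatnonzero(om2 > 0)
    if active.size != 1:
        raise ValueError("quadrature oracle requires exactly one active random effect")
    k = int(active[0])
    w2 = float(om2[k])
    sig2 = model.residual.sigma_prop**2
    eps2 = EPS_FLOOR**2
    dv = subject.dv

    def neglog(e: float) -> float:
        eta = np.zeros(3)
        eta[k] = e
        f = predict_subject(model, subject, eta, method="lsoda")
        var = sig2 * f**2 + eps2
        r = dv - f
        g = 0.5 * np.sum(np.log(2 * np.pi * var) + r**2 / var)
        g += 0.5 * (math.log(2 * math.pi * w2) + e * e / w2)
        return float(g)

    mode = optimize.minimize_scalar(
        neglog, bounds=(-6 * math.sqrt(w2), 6 * math.sqrt(w2)), method="bounded",
        options=dict(xatol=1e-10),
    ).x
    h = 1e-4
    g0 = neglog(mode)
    hess = (neglog(mode + h) - 2 * g0 + neglog(mode - h)) / h**2
    if hess <= 0:
        hess = 1.0 / w2
    s = 1.0 / math.sqrt(hess)
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    for xi, wi in zip(x, w):
        e = mode + math.sqrt(2.0) * s * xi
        total += wi * math.exp(xi * xi - (neglog(e) - g0))
    return float(2.0 * g0 - 2.0 * math.log(math.sqrt(2.0) * s * total))
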