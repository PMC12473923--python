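"""Virtual trials emulating the two source study designs.

Phase-I-like: three parallel arms of healthy men, single 35 mg SC dose,
23 rich sampling times over 253 days, body weight ~ truncated
Normal(82.97, 8.492^2) kg on [50, 130].

Phase-III-like: postmenopausal women in 2:1:1 arms, 60 mg SC at days 0,
183 and 365 (every 6 months), six sparse samples in the main period
(day 0 predose, day 11, months 1/3/6/12 with a 30.4-day month and the
month-6 and month-12 samples predose), weight ~ truncated
Normal(63.196, 8.787^2) kg on [40, 110].

Observations are generated as DV = C * (1 + eps) with proportional error,
floored at zero; samples below the LLOQ are flagged BLQ.  The generating
model and each subject's true random effects are retained so parameter
recovery can be checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import DEFAULT_LLOQ_NG_ML, NG_ML_TO_MG_L, SubjectData
from .estimation import PopulationModel
from .model_core import CovariateRecord, DoseEvent, individual_params, solve_profile
from .reference import PHASE1_WEIGHT_KG, PHASE3_WEIGHT_KG

#: rich sampling times, days (predose, 8 h, 16 h, 24/48/72 h, then days)
PHASE1_TIMES = (
    0.0, 0.3333, 0.6667, 1.0, 2.0, 3.0, 6.0, 8.0, 11.0, 15.0, 22.0, 29.0,
    43.0, 57.0, 71.0, 85.0, 99.0, 113.0, 141.0, 169.0, 197.0, 225.0, 253.0,
)

#: sparse main-period sampling times, days (day 1 predose, day 11,
#: months 1/3/6/12; month-6 and month-12 samples are predose troughs)
PHASE3_TIMES = (0.0, 11.0, 30.0, 91.0, 183.0, 365.0)

#: 60 mg SC every 6 months
PHASE3_DOSE_TIMES = (0.0, 183.0, 365.0)


@dataclass
class TrialDesign:
    """Arms, dosing, sampling schedule and demographics of one trial."""

    arms: tuple[tuple[int, float, tuple[float, ...]], ...]  # (code, dose mg, dose days)
    n_per_arm: tuple[int, ...]
    sampling: tuple[float, ...]
    wt_mean: float
    wt_sd: float
    wt_bounds: tuple[float, float]
    study: int
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.arms) != len(self.n_per_arm):
            raise ValueError("arms and n_per_arm must align")
        if any(n <= 0 for n in self.n_per_arm):
            raise ValueError("arm sizes must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_arm))


@dataclass
class SimulatedTrial:
    """Subjects with attached true individual parameters plus the
    generating population model."""

    subjects: list[SubjectData]
    truth: PopulationModel
    design: TrialDesign
    true_etas: np.ndarray = field(default=None)  # type: ignore[assignment]


def phase1_design(n_per_arm: int = 85, seed: int = 0, missing_rate: float = 0.0) -> TrialDesign:
    """Three-arm single-dose 35 mg rich-sampling design (healthy men)."""
    mean, sd, lo, hi = PHASE1_WEIGHT_KG
    return TrialDesign(
        arms=((1, 35.0, (0.0,)), (2, 35.0, (0.0,)), (3, 35.0, (0.0,))),
        n_per_arm=(n_per_arm,) * 3,
        sampling=PHASE1_TIMES,
        wt_mean=mean,
        wt_sd=sd,
        wt_bounds=(lo, hi),
        study=0,
        missing_rate=missing_rate,
        seed=seed,
    )


def phase3_design(n_total: int = 555, seed: int = 0, missing_rate: float = 0.0) -> TrialDesign:
    """2:1:1 three-arm 60 mg every-6-months sparse design (postmenopausal
    women); arm sizes are the largest-remainder 2:1:1 split."""
    n1 = int(n_total / 2 + 0.5)
    n2 = int(np.ceil((n_total - n1) / 2))
    n3 = n_total - n1 - n2
    mean, sd, lo, hi = PHASE3_WEIGHT_KG
    return TrialDesign(
        arms=(
            (1, 60.0, PHASE3_DOSE_TIMES),
            (2, 60.0, PHASE3_DOSE_TIMES),
            (3, 60.0, PHASE3_DOSE_TIMES),
        ),
        n_per_arm=(n1, n2, n3),
        sampling=PHASE3_TIMES,
        wt_mean=mean,
        wt_sd=sd,
        wt_bounds=(lo, hi),
        study=1,
        missing_rate=missing_rate,
        seed=seed,
    )


def truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    """Truncated-normal draws by rejection (bounds are several SD out, so
    acceptance is near 1)."""
    n = 1 if size is None else int(size)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=n - filled)
        ok = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + ok.size] = ok
        filled += ok.size
    return float(out[0]) if size is None else out


def simulate_trial(
    design: TrialDesign,
    truth: PopulationModel,
    lloq_ng_ml: float = DEFAULT_LLOQ_NG_ML,
    seed: int | None = None,
) -> SimulatedTrial:
    """Simulate one trial from ``truth`` under ``design``.

    Deterministic for a fixed seed (``design.seed`` unless overridden).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    lloq = lloq_ng_ml * NG_ML_TO_MG_L
    omega = np.sqrt(truth.iiv.as_array())
    sigma = truth.residual.sigma_prop
    times = np.asarray(design.sampling, dtype=float)
    subjects: list[SubjectData] = []
    etas_all = []
    sid = 0
    for (arm, dose, dose_times), n_arm in zip(design.arms, design.n_per_arm):
        doses = [DoseEvent(t, dose) for t in dose_times]
        dt = np.asarray(dose_times, dtype=float)
        da = np.full(dt.size, dose)
        for _ in range(n_arm):
            sid += 1
            wt = truncated_normal(rng, design.wt_mean, design.wt_sd, *design.wt_bounds)
            eta = rng.normal(0.0, 1.0, size=3) * omega
            cov = CovariateRecord(wt=wt, study=design.study, trt=arm)
            p = individual_params(truth.fixed, eta, cov, truth.trt_test_arm)
            conc = solve_profile(p, doses, times).conc
            eps = rng.normal(0.0, 1.0, size=times.size) * sigma
            dv = np.maximum(conc * (1.0 + eps), 0.0)
            keep = np.ones(times.size, dtype=bool)
            if design.missing_rate > 0:
                keep = rng.random(times.size) >= design.missing_rate
                if not keep.any():
                    keep[0] = True
            subjects.append(
                SubjectData(
                    id=sid,
                    wt=wt,
                    trt=arm,
                    study=design.study,
                    dose_times=dt.copy(),
                    dose_amts=da.copy(),
                    obs_times=times[keep],
                    dv=dv[keep],
                    blq=dv[keep] < lloq,
                    true_params=p,
                    true_eta=eta,
                )
            )
            etas_all.append(eta)
    return SimulatedTrial(
        subjects=subjects,
        truth=truth,
        design=design,
        true_etas=np.array(etas_all),
    )
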