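"""NONMEM-convention rectangular datasets and below-quantification policy.

Files are CSV with header columns ID, TIME, AMT, DV, EVID, MDV, WT, TRT,
STUDY, BLQ.  DV is stored in ng/mL in files ("." for missing) and held in
mg/L in memory; times are days (fractions for hour-scale samples).

The BLQ policy: concentrations below the lower limit of quantification
(LLOQ) at the start of a profile (before the first measurable value) are
imputed as zero and retained; BLQ values after the last measurable value,
and isolated BLQ values between two measurable values, are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID", "MDV", "WT", "TRT", "STUDY", "BLQ")

#: default assay lower limit of quantification, ng/mL
DEFAULT_LLOQ_NG_ML = 20.0

#: file DV unit (ng/mL) to internal unit (mg/L)
NG_ML_TO_MG_L = 1e-3


@dataclass
class SubjectData:
    """Dose events and time-stamped observations for one subject.

    Observation concentrations ``dv`` are in mg/L; ``blq`` flags samples
    below the LLOQ.  ``true_params``/``true_eta`` are attached by the
    synthetic-trial generator for recovery testing and are not serialized.
    """

    id: int
    wt: float
    trt: int
    study: int
    dose_times: np.ndarray
    dose_amts: np.ndarray
    obs_times: np.ndarray
    dv: np.ndarray
    blq: np.ndarray
    true_params: object = None
    true_eta: np.ndarray = None  # type: ignore[assignment]

    @property
    def n_obs(self) -> int:
        return int(self.obs_times.size)


@dataclass
class BLQPolicyReport:
    n_imputed_zero: int = 0
    n_dropped_trailing: int = 0
    n_dropped_intermediate: int = 0
    degenerate: bool = False

    def __add__(self, other: "BLQPolicyReport") -> "BLQPolicyReport":
        return BLQPolicyReport(
            self.n_imputed_zero + other.n_imputed_zero,
            self.n_dropped_trailing + other.n_dropped_trailing,
            self.n_dropped_intermediate + other.n_dropped_intermediate,
            self.degenerate or other.degenerate,
        )


def write_dataset(subjects: list[SubjectData], path) -> None:
    """Write subjects as a NONMEM-convention CSV (DV in ng/mL)."""
    rows = []
    for s in subjects:
        events = [(t, 1, a, np.nan, 1, False) for t, a in zip(s.dose_times, s.dose_amts)]
        events += [
            (t, 0, 0.0, c / NG_ML_TO_MG_L, 0, bool(b))
            for t, c, b in zip(s.obs_times, s.dv, s.blq)
        ]
        # observations at a dose time precede the dose (predose convention)
        events.sort(key=lambda e: (e[0], e[1]))
        for t, evid, amt, dvv, mdv, b in events:
            rows.append(
                dict(
                    ID=s.id,
                    TIME=t,
                    AMT=amt,
                    DV="." if evid == 1 else repr(float(dvv)),
                    EVID=evid,
                    MDV=mdv,
                    WT=s.wt,
                    TRT=s.trt,
                    STUDY=s.study,
                    BLQ=int(b),
                )
            )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def read_dataset(path, dv_unit: str = "ng/mL") -> list[SubjectData]:
    """Read a NONMEM-convention CSV into per-subject records (DV -> mg/L)."""
    df = pd.read_csv(path, na_values=["."])
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset missing required columns: {missing}")
    if dv_unit == "ng/mL":
        scale = NG_ML_TO_MG_L
    elif dv_unit == "mg/L":
        scale = 1.0
    else:
        raise ValueError(f"unknown DV unit {dv_unit!r}")
    bad_evid = set(df["EVID"].unique()) - {0, 1}
    if bad_evid:
        raise ValueError(f"unknown EVID values: {sorted(bad_evid)}")
    subjects = []
    for sid, g in df.groupby("ID", sort=False):
        t = g["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError(f"non-monotone TIME within subject {sid}")
        dose = g[g["EVID"] == 1]
        obs = g[g["EVID"] == 0]
        subjects.append(
            SubjectData(
                id=int(sid),
                wt=float(g["WT"].iloc[0]),
                trt=int(g["TRT"].iloc[0]),
                study=int(g["STUDY"].iloc[0]),
                dose_times=dose["TIME"].to_numpy(dtype=float),
                dose_amts=dose["AMT"].to_numpy(dtype=float),
                obs_times=obs["TIME"].to_numpy(dtype=float),
                dv=obs["DV"].to_numpy(dtype=float) * scale,
                blq=obs["BLQ"].to_numpy(dtype=float).astype(bool),
            )
        )
    return subjects


def apply_blq_policy(
    subject: SubjectData, lloq_ng_ml: float = DEFAULT_LLOQ_NG_ML
) -> tuple[SubjectData, BLQPolicyReport]:
    """Apply the leading-impute / trailing-drop / intermediate-drop policy.

    BLQ status is determined by DV < LLOQ.  Measurable records are never
    altered; the operation is idempotent (an imputed leading zero stays an
    imputed leading zero).
    """
    lloq = lloq_ng_ml * NG_ML_TO_MG_L
    dv = subject.dv
    below = dv < lloq
    report = BLQPolicyReport()
    if below.all():
        new_dv = np.zeros_like(dv)
        report.n_imputed_zero = int(dv.size)
        report.degenerate = dv.size > 0
        out = replace(
            subject,
            dv=new_dv,
            blq=np.ones(dv.size, dtype=bool),
            obs_times=subject.obs_times.copy(),
        )
        return out, report
    meas_idx = np.flatnonzero(~below)
    first, last = meas_idx[0], meas_idx[-1]
    idx = np.arange(dv.size)
    leading = below & (idx < first)
    trailing = below & (idx > last)
    intermediate = below & (idx > first) & (idx < last)
    keep = ~(trailing | intermediate)
    new_dv = dv.copy()
    new_dv[leading] = 0.0
    new_blq = below.copy()
    report.n_imputed_zero = int(leading.sum())
    report.n_dropped_trailing = int(trailing.sum())
    report.n_dropped_intermediate = int(intermediate.sum())
    out = replace(
        subject,
        obs_times=subject.obs_times[keep],
        dv=new_dv[keep],
        blq=new_blq[keep],
    )
    return out, report


def apply_blq_policy_all(
    subjects: list[SubjectData], lloq_ng_ml: float = DEFAULT_LLOQ_NG_ML
) -> tuple[list[SubjectData], BLQPolicyReport]:
    """Policy over a whole dataset; returns cleaned subjects and pooled counts."""
    out = []
    total = BLQPolicyReport()
    for s in subjects:
        s2, rep = apply_blq_policy(s, lloq_ng_ml)
        out.append(s2)
        total = total + rep
    return out, total
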