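"""Goodness-of-fit quantities and the visual predictive check.

PRED is the population prediction (eta = 0), IPRE the individual
prediction at the empirical Bayes estimates, and CWRES the conditional
weighted residual from the FOCE linearization about the conditional mode:
with F = df/deta at the EBE, Cov = F Omega F' + diag(sigma^2 IPRE^2) and
E[y] ~ IPRE - F.eta, CWRES = chol(Cov)^-1 (DV - E[y]).

The VPC simulates the dataset (same doses, times and covariates) many
times from the model with both variability levels, then compares observed
concentration percentiles per time bin with the distribution of the same
percentiles across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from ._foce import EPS_FLOOR
from .dataset_io import SubjectData
from .estimation import PopulationModel, empirical_bayes_all, predict_subject


@dataclass
class VPCResult:
    bin_edges: np.ndarray
    bin_mid: np.ndarray
    obs_pct: np.ndarray  # (nbin, 3): observed 5/50/95 percentiles
    sim_pct: np.ndarray  # (nbin, 3): median across replicates of the same
    sim_band: np.ndarray  # (nbin, 3, 2): 5-95% band of each percentile
    n_replicates: int
    n_obs_per_bin: np.ndarray


def gof_table(
    model: PopulationModel,
    subjects: list[SubjectData],
    ebes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-observation PRED / IPRE / CWRES table."""
    if ebes is None:
        ebes = empirical_bayes_all(model, subjects)
    sig2 = model.residual.sigma_prop**2
    om2 = model.iiv.as_array()
    act = np.flatnonzero(om2 > 0)
    rows = []
    fd = 1e-5
    for s, eta in zip(subjects, ebes):
        pred = predict_subject(model, s, np.zeros(3))
        ipre = predict_subject(model, s, eta)
        n = s.n_obs
        F = np.zeros((n, 3))
        for k in act:
            ep = eta.copy()
            ep[k] += fd
            F[:, k] = (predict_subject(model, s, ep) - ipre) / fd
        cov = F[:, act] @ np.diag(om2[act]) @ F[:, act].T + np.diag(
            sig2 * ipre**2 + EPS_FLOOR**2
        )
        mean = ipre - F[:, act] @ eta[act]
        L = cholesky(cov, lower=True)
        cwres = np.linalg.solve(L, s.dv - mean)
        for j in range(n):
            rows.append(
                dict(
                    id=s.id,
                    time=s.obs_times[j],
                    dv=s.dv[j],
                    pred=pred[j],
                    ipre=ipre[j],
                    cwres=cwres[j],
                    blq=bool(s.blq[j]),
                )
            )
    return pd.DataFrame(rows)


def _percentiles(values: np.ndarray) -> np.ndarray:
    return np.percentile(values, [5.0, 50.0, 95.0])


def make_bins(subjects: list[SubjectData], n_bins: int = 6) -> np.ndarray:
    """Bin edges for the VPC: one bin per nominal time when the design is
    rich in distinct times, quantile-based otherwise."""
    t = np.concatenate([s.obs_times for s in subjects])
    uniq = np.unique(t)
    if uniq.size <= 30:
        mids = (uniq[1:] + uniq[:-1]) / 2
        return np.concatenate([[uniq[0] - 0.5], mids, [uniq[-1] + 0.5]])
    qs = np.linspace(0, 100, n_bins + 1)
    edges = np.percentile(t, qs)
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    return np.unique(edges)


def vpc(
    model: PopulationModel,
    subjects: list[SubjectData],
    n_rep: int = 500,
    bins: np.ndarray | None = None,
    seed: int = 0,
    lloq_mg_l: float | None = None,
) -> VPCResult:
    """Visual predictive check at the observed design.

    Observed percentiles exclude BLQ records (consistent with the analysis
    policy); simulated values are retained regardless of magnitude.
    """
    rng = np.random.default_rng(seed)
    if bins is None:
        bins = make_bins(subjects)
    nbin = bins.size - 1
    obs_t = np.concatenate([s.obs_times for s in subjects])
    obs_dv = np.concatenate([s.dv for s in subjects])
    obs_blq = np.concatenate([s.blq for s in subjects])
    which = np.digitize(obs_t, bins) - 1
    which = np.clip(which, 0, nbin - 1)

    sigma = model.residual.sigma_prop
    omega = np.sqrt(model.iiv.as_array())

    obs_pct = np.full((nbin, 3), np.nan)
    n_per_bin = np.zeros(nbin, dtype=int)
    for b in range(nbin):
        sel = (which == b) & ~obs_blq
        n_per_bin[b] = int(sel.sum())
        if n_per_bin[b]:
            obs_pct[b] = _percentiles(obs_dv[sel])

    sim_pct_rep = np.full((n_rep, nbin, 3), np.nan)
    for r in range(n_rep):
        sim_dv = np.empty_like(obs_dv)
        pos = 0
        for s in subjects:
            eta = rng.normal(0.0, 1.0, 3) * omega
            conc = predict_subject(model, s, eta)
            eps = rng.normal(0.0, 1.0, s.n_obs) * sigma
            sim_dv[pos : pos + s.n_obs] = np.maximum(conc * (1 + eps), 0.0)
            pos += s.n_obs
        for b in range(nbin):
            sel = which == b
            if sel.any():
                sim_pct_rep[r, b] = _percentiles(sim_dv[sel])

    sim_pct = np.nanmedian(sim_pct_rep, axis=0)
    sim_band = np.stack(
        [
            np.nanpercentile(sim_pct_rep, 5.0, axis=0),
            np.nanpercentile(sim_pct_rep, 95.0, axis=0),
        ],
        axis=-1,
    )
    mid = (bins[:-1] + bins[1:]) / 2
    return VPCResult(
        bin_edges=bins,
        bin_mid=mid,
        obs_pct=obs_pct,
        sim_pct=sim_pct,
        sim_band=sim_band,
        n_replicates=n_rep,
        n_obs_per_bin=n_per_bin,
    )


def vpc_table(res: VPCResult) -> pd.DataFrame:
    """Tidy per-bin VPC summary."""
    rows = []
    for b in range(res.bin_mid.size):
        rows.append(
            dict(
                bin_mid=res.bin_mid[b],
                n_obs=res.n_obs_per_bin[b],
                obs_p5=res.obs_pct[b, 0],
                obs_p50=res.obs_pct[b, 1],
                obs_p95=res.obs_pct[b, 2],
                sim_p5=res.sim_pct[b, 0],
                sim_p50=res.sim_pct[b, 1],
                sim_p95=res.sim_pct[b, 2],
                sim_p50_lo=res.sim_band[b, 1, 0],
                sim_p50_hi=res.sim_band[b, 1, 1],
            )
        )
    return pd.DataFrame(rows)
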