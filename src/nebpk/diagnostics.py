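"""Goodness-of-fit diagnostics: residuals, NPDE and VPC machinery.

These functions produce the *data* behind the classic pharmacometric
diagnostic plots — observation vs prediction, individual weighted residuals
(IWRES), normalized prediction distribution errors (NPDE) and visual
predictive check (VPC) percentile bands — as plain arrays/frames; plotting
is left to the caller (a minimal matplotlib helper is included).

Conventions
-----------
* IWRES under the proportional error model: ``(obs - ipred) / (b * ipred)``.
* NPDE follow the rank-based probability-integral transform with per-subject
  decorrelation by the Cholesky factor of the simulated covariance, then a
  probit; under a correct model they are iid N(0, 1).  Rank ties are broken
  by seeded uniform jitter.
* VPC uses equal-count time bins (robust to dense-early/sparse-late PK
  sampling) and type-7 (linear-interpolation) percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset
from .population import PopulationModel, add_residual_error, sample_etas, individual_params, CovariateSet
from .structural import PARAM_NAMES, conc_matrix

__all__ = ["iwres", "npde", "vpc", "VPCResult", "gof_table",
           "simulate_replicates", "plot_vpc", "plot_gof"]


def iwres(obs, ipred, b: float):
    """Individual weighted residuals under the proportional error model.

    Zero iff ``obs == ipred``; invariant under common rescaling of ``obs``
    and ``ipred``.  Entries with ``ipred <= 0`` are returned as NaN (flagged
    undefined rather than raising, so vectorised use keeps alignment).
    """
    obs = np.asarray(obs, dtype=float)
    ipred = np.asarray(ipred, dtype=float)
    if b <= 0:
        raise ValueError("b must be > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (obs - ipred) / (b * ipred)
    out = np.where(ipred > 0, out, np.nan)
    return out if out.ndim else float(out)


def simulate_replicates(dataset: Dataset, popmodel: PopulationModel, k: int,
                        seed=None) -> np.ndarray:
    """Simulate ``k`` replicate observation vectors under the population model.

    Keeps each subject's design (doses, sampling times, covariates) fixed and
    redraws random effects and residual error.  Returns an array of shape
    ``(k, n_obs_total)`` aligned with the dataset's observation rows.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    subs = dataset.subjects()
    n = len(subs)
    out = np.empty((k, dataset.n_observations))
    covsets = [CovariateSet(age=s.age, bmi=s.bmi, genotype=s.geno) for s in subs]
    for r in range(k):
        etas = sample_etas(popmodel, n, rng)
        col = 0
        for i, s in enumerate(subs):
            eta = dict(zip(PARAM_NAMES, etas[i]))
            p = individual_params(popmodel.theta, popmodel.covmodel, covsets[i], eta)
            c = conc_matrix(p.as_array()[None, :],
                            s.dose_times[None, :], s.dose_amounts[None, :],
                            s.obs_times[None, :])[0]
            y = add_residual_error(c, popmodel.b, rng)
            out[r, col:col + len(y)] = y
            col += len(y)
    return out


def npde(dataset: Dataset, popmodel: PopulationModel, k: int = 500,
         seed=None) -> np.ndarray:
    """Normalized prediction distribution errors for every observation.

    Simulates ``k`` replicates of each subject's observation vector under the
    model, decorrelates observed and simulated vectors with the Cholesky
    factor of the simulated covariance, ranks each decorrelated observation
    within its simulated distribution, and applies the probit.  ``k`` must be
    large enough to resolve the extreme ranks (k >= 100).

    Concentrations carry an atom at zero (pre-lag samples under the lag-time
    model, where prediction and proportional noise both vanish).  The rank
    transform assumes a continuous distribution, so the atom is spread with
    seeded uniform jitter just below zero — applied to observations and
    replicates alike — which makes the PIT exactly uniform under the model
    while leaving quantifiable concentrations untouched.
    """
    if k < 100:
        raise ValueError("k too small for the requested resolution; use k >= 100")
    rng = np.random.default_rng(seed)
    sims = simulate_replicates(dataset, popmodel, k, rng)
    obs_all = dataset.df.loc[dataset.df["EVID"] == 0, "DV"].to_numpy(float)
    out = np.full_like(obs_all, np.nan)
    atom = 1e-9
    col = 0
    for s in dataset.subjects():
        m = len(s.obs_times)
        sim = sims[:, col:col + m].copy()
        obs = obs_all[col:col + m].copy()
        zs = sim == 0
        if zs.any():
            sim[zs] = -atom * rng.random(int(zs.sum()))
        zo = obs == 0
        if zo.any():
            obs[zo] = -atom * rng.random(int(zo.sum()))
        mu = sim.mean(axis=0)
        cov = np.cov(sim.T) if m > 1 else np.array([[np.var(sim[:, 0])]])
        cov = np.atleast_2d(cov) + 1e-10 * np.eye(m)
        lchol = np.linalg.cholesky(cov)
        dec_obs = np.linalg.solve(lchol, obs - mu)
        dec_sim = np.linalg.solve(lchol, (sim - mu).T).T
        # rank-based PIT with seeded jitter breaking any remaining ties
        jitter = 1e-12 * rng.standard_normal(dec_sim.shape)
        pit = ((dec_sim + jitter) < dec_obs[None, :]).mean(axis=0)
        pit = np.clip(pit, 1.0 / (2 * k), 1.0 - 1.0 / (2 * k))
        out[col:col + m] = stats.norm.ppf(pit)
        col += m
    return out


@dataclass
class VPCResult:
    """Observed percentiles per time bin with simulated prediction bands."""

    bin_edges: np.ndarray
    bin_mid: np.ndarray
    percentiles: tuple[float, ...]
    observed: np.ndarray        # (n_bins, n_pctl)
    band_lo: np.ndarray         # (n_bins, n_pctl) lower PI bound per percentile
    band_hi: np.ndarray         # (n_bins, n_pctl)
    level: float
    outliers: np.ndarray        # (n_bins, n_pctl) bool: observed outside band

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.bin_mid)):
            for j, p in enumerate(self.percentiles):
                rows.append({
                    "bin_mid": self.bin_mid[i], "percentile": p,
                    "observed": self.observed[i, j],
                    "band_lo": self.band_lo[i, j], "band_hi": self.band_hi[i, j],
                    "outlier": bool(self.outliers[i, j]),
                })
        return pd.DataFrame(rows)


def _equal_count_edges(times: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.linspace(0, 100, n_bins + 1)
    edges = np.percentile(times, qs, method="linear")
    return np.unique(edges)


def vpc(dataset: Dataset, popmodel: PopulationModel, n_sim: int = 500,
        bins: int = 8, level: float = 90.0,
        percentiles: tuple[float, ...] = (10.0, 50.0, 90.0),
        seed=None) -> VPCResult:
    """Visual-predictive-check bands.

    Bins observations into ``bins`` equal-count time bins; within each bin
    computes the observed percentiles and, from ``n_sim`` simulated
    replicates of the whole study, the central ``level``% prediction interval
    of each percentile.  Bins that end up empty are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    obs_df = dataset.df[dataset.df["EVID"] == 0]
    times = obs_df["TIME"].to_numpy(float)
    obs = obs_df["DV"].to_numpy(float)
    if len(times) == 0:
        raise ValueError("no observations to bin")
    edges = _equal_count_edges(times, bins)
    if len(edges) < 2:
        raise ValueError("degenerate time support; cannot form bins")
    idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(edges) - 2)

    sims = simulate_replicates(dataset, popmodel, n_sim, rng)
    pct = np.asarray(percentiles)
    n_bins = len(edges) - 1
    observed = np.full((n_bins, len(pct)), np.nan)
    lo = np.full((n_bins, len(pct)), np.nan)
    hi = np.full((n_bins, len(pct)), np.nan)
    keep = []
    alpha = (100.0 - level) / 2.0
    for b in range(n_bins):
        sel = idx == b
        if not np.any(sel):
            warnings.warn(f"empty VPC bin {b}; dropped")
            continue
        keep.append(b)
        observed[b] = np.percentile(obs[sel], pct, method="linear")
        sim_pct = np.percentile(sims[:, sel], pct, axis=1, method="linear")  # (n_pctl, n_sim)
        lo[b] = np.percentile(sim_pct, alpha, axis=1, method="linear")
        hi[b] = np.percentile(sim_pct, 100.0 - alpha, axis=1, method="linear")
    keep = np.array(keep, dtype=int)
    edges_kept = np.append(edges[keep], edges[keep[-1] + 1])
    observed, lo, hi = observed[keep], lo[keep], hi[keep]
    outliers = (observed < lo) | (observed > hi)
    return VPCResult(bin_edges=edges_kept,
                     bin_mid=0.5 * (edges_kept[:-1] + edges_kept[1:]),
                     percentiles=tuple(pct), observed=observed,
                     band_lo=lo, band_hi=hi, level=level, outliers=outliers)


def gof_table(dataset: Dataset, popmodel: PopulationModel, fit=None,
              k_npde: int = 500, seed=None) -> pd.DataFrame:
    """Per-observation goodness-of-fit records.

    Population predictions use the population parameters with covariate
    effects only; individual predictions add the EBE random effects when a
    fitted result is supplied.  Returns one row per observation with PRED,
    IPRED, IWRES and NPDE columns.
    """
    rows = []
    ebes = None
    if fit is not None and fit.ebes is not None:
        ebes = fit.ebes.set_index("ID")
    for s in dataset.subjects():
        cov = CovariateSet(age=s.age, bmi=s.bmi, genotype=s.geno)
        p_pop = individual_params(popmodel.theta, popmodel.covmodel, cov, None)
        pred = conc_matrix(p_pop.as_array()[None, :], s.dose_times[None, :],
                           s.dose_amounts[None, :], s.obs_times[None, :])[0]
        if ebes is not None and s.subject_id in ebes.index:
            eta = {p: float(ebes.loc[s.subject_id, f"eta_{p}"])
                   for p in PARAM_NAMES if f"eta_{p}" in ebes.columns}
            p_ind = individual_params(popmodel.theta, popmodel.covmodel, cov, eta)
            ipred = conc_matrix(p_ind.as_array()[None, :], s.dose_times[None, :],
                                s.dose_amounts[None, :], s.obs_times[None, :])[0]
        else:
            ipred = pred
        iw = iwres(s.dv, ipred, popmodel.b)
        for j in range(len(s.obs_times)):
            rows.append({"ID": s.subject_id, "TIME": s.obs_times[j],
                         "DV": s.dv[j], "PRED": pred[j], "IPRED": ipred[j],
                         "IWRES": iw[j]})
    df = pd.DataFrame(rows)
    df["NPDE"] = npde(dataset, popmodel, k=k_npde, seed=seed)
    return df


# ---------------------------------------------------------------------------
# Minimal static figures
# ---------------------------------------------------------------------------

def plot_vpc(result: VPCResult, ax=None):
    """Draw the VPC bands and observed percentiles on a matplotlib axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for j, p in enumerate(result.percentiles):
        ax.fill_between(result.bin_mid, result.band_lo[:, j],
                        result.band_hi[:, j], alpha=0.25,
                        label=f"{result.level:.0f}% PI of P{p:.0f}")
        ax.plot(result.bin_mid, result.observed[:, j], "o-", ms=3)
        bad = result.outliers[:, j]
        if bad.any():
            ax.plot(result.bin_mid[bad], result.observed[bad, j], "rs", ms=6)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (ng/mL)")
    ax.legend(fontsize=7)
    return ax


def plot_gof(gof: pd.DataFrame, ax=None):
    """Observed vs individual-predicted concentrations with the identity line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(gof["IPRED"], gof["DV"], "o", ms=3, alpha=0.6)
    lim = float(max(gof["IPRED"].max(), gof["DV"].max())) * 1.05
    ax.plot([0, lim], [0, lim], "k-", lw=1)
    ax.set_xlabel("individual prediction (ng/mL)")
    ax.set_ylabel("observation (ng/mL)")
    return ax
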