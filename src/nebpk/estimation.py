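"""Nonlinear mixed-effects estimation by SAEM.

Implements the Stochastic Approximation Expectation-Maximization algorithm
for the population PK models of this package: individual log-parameters
``phi_i = mu_i + eta_i`` with ``mu_i = X_i B`` (intercept plus multiplicative
covariate effects on the log scale), diagonal lognormal random effects
``eta_i ~ N(0, diag(omega^2))`` and a residual error model on observations
(proportional by default).

The E-step is Metropolis-within-Gibbs on the random effects with three
kernels — an independence proposal from the prior, a component-wise random
walk and a joint random walk, both with acceptance-rate adaptation — run
vectorised across subjects and chains.  The M-step is exact: the Gaussian
sufficient statistics of ``phi`` give closed-form updates of the coefficient
matrix, the omegas and (for proportional/additive error) the error
coefficient.  Step sizes follow the usual two-phase schedule: gamma = 1
during exploration with simulated-annealing lower bounds on the variance
terms, then gamma = 1/(k - K1) for smoothing.

The marginal likelihood (OFV = -2 log L) is estimated by importance sampling
with per-subject Gaussian proposals fitted to the conditional samples;
standard errors come from Louis' identity evaluated with conditional MCMC
draws at the final estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .data import Dataset
from .structural import STRUCTURES, PKParams

__all__ = [
    "ModelSpec",
    "SAEMConfig",
    "FitResult",
    "saem_fit",
    "fit_from_population_model",
    "log_likelihood",
    "ebe_map",
    "ebe_table",
    "covariate_search",
    "model_select",
]

_CONTINUOUS_COVS = {"age": ("AGE", 26.7), "bmi": ("BMI", 25.0)}
_OMEGA_FLOOR = 1e-3
_SD_FLOOR = 1e-3   # additive floor on the residual SD, ng/mL
_F_TRIM = 1e-3     # predictions below this (ng/mL) are excluded from the
                   # proportional-error statistic: they are pre-lag points
                   # whose ratio residual is not informative about b
_PHI_CLIP = 30.0   # |log parameter| bound inside the samplers


@dataclass(frozen=True)
class ModelSpec:
    """Structural + statistical model choice.

    ``covariate_terms`` is a collection of (parameter, covariate) pairs with
    covariate in {"age", "bmi", "geno"}; each target parameter must belong to
    the chosen structure.
    """

    structure: str = "two_compartment"
    error_model: str = "proportional"
    covariate_terms: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.error_model not in ("proportional", "additive", "combined"):
            raise ValueError(f"unknown error model {self.error_model!r}")
        names = STRUCTURES[self.structure][0]
        terms = tuple((p, c) for p, c in self.covariate_terms)
        for p, c in terms:
            if p not in names:
                raise ValueError(f"covariate target {p!r} not a parameter of {self.structure}")
            if c not in ("age", "bmi", "geno"):
                raise ValueError(f"unknown covariate {c!r}")
        object.__setattr__(self, "covariate_terms", terms)

    @property
    def param_names(self) -> tuple[str, ...]:
        return STRUCTURES[self.structure][0]

    @property
    def error_param_names(self) -> tuple[str, ...]:
        return {"proportional": ("b",), "additive": ("a",), "combined": ("a", "b")}[
            self.error_model
        ]

    def n_parameters(self, n_design_columns: int) -> int:
        """Estimated-parameter count: coefficients + omegas + error terms."""
        return n_design_columns + len(self.param_names) + len(self.error_param_names)


@dataclass
class SAEMConfig:
    """Tuning knobs of the SAEM run."""

    k1: int = 300                 # exploration iterations (gamma = 1)
    k2: int = 200                 # smoothing iterations (gamma = 1/(k - k1))
    n_chains: int = 2
    seed: int = 0
    anneal: float = 0.95          # per-iteration lower-bound factor on variances
    init_theta: dict[str, float] | None = None
    init_omega: float = 0.3
    init_error: float = 0.2
    ll_mc_size: int = 1000        # importance-sampling draws per subject
    se_mc_size: int = 400         # conditional draws per subject for Louis SEs
    bic_n: str = "subjects"       # or "observations"
    compute_se: bool = True
    compute_ll: bool = True


def _design_matrices(spec: ModelSpec, cov_df: pd.DataFrame):
    """Per-parameter fixed-effect design matrices.

    Returns ``{param: (colnames, X)}`` with X of shape (n_subjects, c);
    the first column is always the intercept.
    """
    n = len(cov_df)
    out = {}
    for p in spec.param_names:
        cols = [np.ones(n)]
        names = [f"{p}_pop"]
        for tp, cov in spec.covariate_terms:
            if tp != p:
                continue
            if cov in _CONTINUOUS_COVS:
                col, ref = _CONTINUOUS_COVS[cov]
                cols.append(np.log(cov_df[col].to_numpy(float) / ref))
                names.append(f"beta_{p}_{cov}")
            else:  # geno: EM reference, IM/PM indicators
                g = cov_df["GENO"].to_numpy()
                cols.append((g == "IM").astype(float))
                cols.append((g == "PM").astype(float))
                names.append(f"beta_{p}_geno_IM")
                names.append(f"beta_{p}_geno_PM")
        x = np.column_stack(cols)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            warnings.warn(f"collinear design for parameter {p!r}; "
                          "estimates for dependent columns are not unique")
        out[p] = (names, x)
    return out


class _Model:
    """Internal bundle: padded data, design, prediction and likelihood kernels."""

    def __init__(self, dataset: Dataset, spec: ModelSpec):
        if dataset.n_subjects == 0:
            raise ValueError("cannot fit an empty dataset")
        self.spec = spec
        self.param_names, self.conc_fn = STRUCTURES[spec.structure]
        self.np_ = len(self.param_names)
        pad = dataset.padded_arrays()
        self.dose_t = pad["dose_t"]
        self.dose_amt = pad["dose_amt"]
        self.obs_t = pad["obs_t"]
        self.dv = pad["dv"]
        self.mask = pad["obs_mask"]
        self.subject_ids = pad["subject_ids"]
        self.n = len(self.subject_ids)
        self.n_obs = int(self.mask.sum())
        cov_df = dataset.covariates()
        self.cov_df = cov_df
        self.design = _design_matrices(spec, cov_df)
        self.n_coef = sum(x.shape[1] for _, x in self.design.values())

    def mu(self, coefs: dict[str, np.ndarray]) -> np.ndarray:
        """(n, P) matrix of per-subject log-parameter means."""
        return np.column_stack(
            [self.design[p][1] @ coefs[p] for p in self.param_names]
        )

    def predict(self, phi: np.ndarray) -> np.ndarray:
        """(n, M) predicted concentrations from log-parameters ``phi``."""
        return self.conc_fn(np.exp(np.clip(phi, -_PHI_CLIP, _PHI_CLIP)),
                            self.dose_t, self.dose_amt, self.obs_t)

    def resid_sd(self, f: np.ndarray, err: dict[str, float]) -> np.ndarray:
        if self.spec.error_model == "proportional":
            return err["b"] * f + _SD_FLOOR
        if self.spec.error_model == "additive":
            return np.full_like(f, err["a"] + _SD_FLOOR)
        return err["a"] + err["b"] * f + _SD_FLOOR

    def loglik_obs(self, phi: np.ndarray, err: dict[str, float]) -> np.ndarray:
        """Per-subject conditional log-likelihood of the observations."""
        f = self.predict(phi)
        sd = self.resid_sd(f, err)
        ll = -np.log(sd) - 0.5 * ((self.dv - f) / sd) ** 2 - 0.5 * np.log(2 * np.pi)
        out = np.where(self.mask, ll, 0.0).sum(axis=1)
        return np.where(np.isfinite(out), out, -1e100)


@dataclass
class FitResult:
    """SAEM estimation output."""

    spec: ModelSpec
    theta_hat: dict[str, float]
    omega_hat: dict[str, float]
    error_hat: dict[str, float]
    coefficients: dict[str, float]
    se: dict[str, float] = field(default_factory=dict)
    rse_percent: dict[str, float] = field(default_factory=dict)
    ofv: float = float("nan")
    ofv_mc_se: float = float("nan")
    aic: float = float("nan")
    bic: float = float("nan")
    n_parameters: int = 0
    bic_sample_size: int = 0
    ebes: pd.DataFrame | None = None
    trace: pd.DataFrame | None = None
    converged: bool = True
    message: str = ""
    config: SAEMConfig | None = None
    _model: "_Model | None" = field(default=None, repr=False)
    _coef_vectors: dict[str, np.ndarray] | None = field(default=None, repr=False)
    _cond_mean: np.ndarray | None = field(default=None, repr=False)
    _cond_cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def b_hat(self) -> float | None:
        return self.error_hat.get("b")

    @property
    def pk_params(self) -> PKParams:
        if self.spec.structure != "two_compartment":
            raise ValueError("pk_params only defined for the two-compartment structure")
        return PKParams(**self.theta_hat)

    def information_criteria(self) -> dict[str, float]:
        return {"ofv": self.ofv, "aic": self.aic, "bic": self.bic}


# ---------------------------------------------------------------------------
# MCMC kernels (vectorised over subjects; one state per chain)
# ---------------------------------------------------------------------------

class _MCMCState:
    def __init__(self, model: _Model, n_chains: int, rng: np.random.Generator):
        self.model = model
        self.rng = rng
        self.eta = np.zeros((n_chains, model.n, model.np_))
        self.ll = None  # per chain (n,) conditional obs log-likelihood
        self.step_cw = np.full(model.np_, 0.4)
        self.step_joint = 0.4

    def refresh_ll(self, mu, err):
        self.ll = np.stack([
            self.model.loglik_obs(mu + self.eta[c], err)
            for c in range(self.eta.shape[0])
        ])

    def sweep(self, mu: np.ndarray, omega: np.ndarray, err: dict[str, float]):
        """One SAEM E-step sweep: prior MH, component-wise RW, joint RW."""
        m = self.model
        rng = self.rng
        om = np.maximum(omega, _OMEGA_FLOOR)
        n_chains = self.eta.shape[0]
        # population parameters moved in the M-step: cached likelihoods are stale
        self.refresh_ll(mu, err)
        for c in range(n_chains):
            eta, ll = self.eta[c], self.ll[c]
            # kernel 1: independence proposal from the prior
            prop = rng.standard_normal(eta.shape) * om[None, :]
            ll_prop = m.loglik_obs(mu + prop, err)
            acc = np.log(rng.random(m.n)) < (ll_prop - ll)
            eta[acc] = prop[acc]
            ll[acc] = ll_prop[acc]
            # kernel 2: component-wise random walk
            acc_rates = np.zeros(m.np_)
            for p in range(m.np_):
                prop = eta.copy()
                prop[:, p] += self.step_cw[p] * om[p] * rng.standard_normal(m.n)
                ll_prop = m.loglik_obs(mu + prop, err)
                dprior = -0.5 * (prop[:, p] ** 2 - eta[:, p] ** 2) / om[p] ** 2
                acc = np.log(rng.random(m.n)) < (ll_prop - ll + dprior)
                eta[acc] = prop[acc]
                ll[acc] = ll_prop[acc]
                acc_rates[p] = acc.mean()
            # kernel 3: joint random walk
            prop = eta + self.step_joint * om[None, :] * rng.standard_normal(eta.shape)
            ll_prop = m.loglik_obs(mu + prop, err)
            dprior = -0.5 * ((prop / om) ** 2 - (eta / om) ** 2).sum(axis=1)
            acc = np.log(rng.random(m.n)) < (ll_prop - ll + dprior)
            eta[acc] = prop[acc]
            ll[acc] = ll_prop[acc]
            acc_joint = acc.mean()
        # adapt step sizes toward ~0.4 acceptance (shared across chains)
        self.step_cw = np.clip(
            self.step_cw * np.where(acc_rates > 0.4, 1.08, 0.93), 1e-3, 5.0
        )
        self.step_joint = float(np.clip(
            self.step_joint * (1.08 if acc_joint > 0.4 else 0.93), 1e-3, 5.0
        ))


# ---------------------------------------------------------------------------
# SAEM main loop
# ---------------------------------------------------------------------------

def _initial_values(model: _Model, config: SAEMConfig) -> dict[str, float]:
    """Crude data-driven starting values (overridable via config.init_theta)."""
    dv, mask, obs_t = model.dv, model.mask, model.obs_t
    dose = np.where(model.dose_amt > 0, model.dose_amt, np.nan)
    mean_dose = float(np.nanmean(dose))
    cmax = np.array([dv[i, mask[i]].max(initial=0.0) for i in range(model.n)])
    cmax = np.where(cmax > 0, cmax, np.nan)
    if np.all(np.isnan(cmax)):
        cmax = np.array([1.0])
    aucs = []
    for i in range(model.n):
        t, y = obs_t[i, mask[i]], dv[i, mask[i]]
        if len(t) >= 2:
            aucs.append(np.trapezoid(y, t))
    auc = float(np.nanmean(aucs)) if aucs else mean_dose
    cl0 = max(mean_dose / max(auc, 1e-6), 1e-4)
    v10 = max(mean_dose / max(np.nanmean(cmax), 1e-6) / 2.0, 1e-4)
    pos_t = obs_t[mask & (dv > 0)]
    tlag0 = max(0.5 * float(pos_t.min()) if pos_t.size else 0.1, 1e-3)
    defaults = {
        "tlag": tlag0, "ka": 1.0, "cl": cl0, "v1": v10, "q": cl0, "v2": 2 * v10,
        "ktr": max(1.0 / tlag0, 0.5),
    }
    init = {p: defaults[p] for p in model.param_names}
    if config.init_theta:
        init.update({k: v for k, v in config.init_theta.items() if k in init})
    return init


def saem_fit(dataset: Dataset, spec: ModelSpec | None = None,
             config: SAEMConfig | None = None) -> FitResult:
    """Fit a nonlinear mixed-effects PK model by SAEM.

    Deterministic for a fixed ``config.seed``.  Estimates the fixed-effect
    coefficients (population values and covariate betas, log scale), the
    random-effect SDs and the residual-error coefficient(s); then computes
    EBEs, the importance-sampling OFV with AIC/BIC, and Louis-identity
    standard errors (RSE%).
    """
    spec = spec or ModelSpec()
    config = config or SAEMConfig()
    model = _Model(dataset, spec)
    if model.n < 2:
        warnings.warn("omega is estimated from a single subject; expect shrinkage "
                      "of the IIV estimates toward the annealing floor")
    rng = np.random.default_rng(config.seed)

    pnames = model.param_names
    init = _initial_values(model, config)
    coefs = {p: np.zeros(model.design[p][1].shape[1]) for p in pnames}
    for p in pnames:
        coefs[p][0] = np.log(init[p])
    omega = np.full(model.np_, config.init_omega)
    err = dict.fromkeys(spec.error_param_names, config.init_error)

    state = _MCMCState(model, config.n_chains, rng)
    # sufficient statistics (SA averages)
    s_phi = None     # (n, P)
    s_phi2 = None    # (n, P)
    s_err = None     # scalar(s) for the error model
    pinvs = {p: np.linalg.pinv(model.design[p][1]) for p in pnames}

    trace_rows = []
    n_iter = config.k1 + config.k2
    for k in range(1, n_iter + 1):
        mu = model.mu(coefs)
        state.sweep(mu, omega, err)
        phi_chains = mu[None, :, :] + state.eta
        phi_bar = phi_chains.mean(axis=0)
        phi2_bar = (phi_chains ** 2).mean(axis=0)

        # error-model statistics from the current samples
        f_stack = np.stack([model.predict(phi_chains[c])
                            for c in range(config.n_chains)])
        resid = model.dv[None] - f_stack
        if spec.error_model == "proportional":
            valid = model.mask[None] & (f_stack > _F_TRIM)
            stat = ((resid / np.maximum(f_stack, _F_TRIM)) ** 2)[valid].sum() / config.n_chains
            cnt = valid.sum() / config.n_chains
            err_stat = (stat, cnt)
        elif spec.error_model == "additive":
            stat = (resid ** 2)[:, model.mask].sum() / config.n_chains
            err_stat = (stat, float(model.n_obs))
        else:  # combined: keep SA averages of f and squared residuals per obs
            err_stat = (f_stack.mean(axis=0), (resid ** 2).mean(axis=0))

        gamma = 1.0 if k <= config.k1 else 1.0 / (k - config.k1)
        if s_phi is None:
            s_phi, s_phi2, s_err = phi_bar, phi2_bar, err_stat
        else:
            s_phi = s_phi + gamma * (phi_bar - s_phi)
            s_phi2 = s_phi2 + gamma * (phi2_bar - s_phi2)
            if spec.error_model == "combined":
                s_err = (s_err[0] + gamma * (err_stat[0] - s_err[0]),
                         s_err[1] + gamma * (err_stat[1] - s_err[1]))
            else:
                s_err = (s_err[0] + gamma * (err_stat[0] - s_err[0]),
                         s_err[1] + gamma * (err_stat[1] - s_err[1]))

        # M-step: exact Gaussian updates
        new_omega2 = np.empty(model.np_)
        for j, p in enumerate(pnames):
            coefs[p] = pinvs[p] @ s_phi[:, j]
            mu_p = model.design[p][1] @ coefs[p]
            new_omega2[j] = np.mean(s_phi2[:, j] - 2 * mu_p * s_phi[:, j] + mu_p ** 2)
        if spec.error_model in ("proportional", "additive"):
            new_err2 = s_err[0] / max(s_err[1], 1.0)
            key = spec.error_param_names[0]
            if k <= config.k1:  # simulated annealing: variances shrink slowly
                new_omega2 = np.maximum(new_omega2, (config.anneal ** 2) * omega ** 2)
                new_err2 = max(new_err2, (config.anneal ** 2) * err[key] ** 2)
            err[key] = float(np.sqrt(max(new_err2, 1e-12)))
        else:
            fbar, r2bar = s_err

            def _neg_q(x):
                a, b = np.exp(x)
                sd = a + b * fbar + _SD_FLOOR
                return float((np.log(sd) + 0.5 * r2bar / sd ** 2)[model.mask].sum())

            res = optimize.minimize(_neg_q, np.log([max(err["a"], 1e-4),
                                                    max(err["b"], 1e-4)]),
                                    method="Nelder-Mead")
            err["a"], err["b"] = np.exp(res.x)
            if k <= config.k1:
                new_omega2 = np.maximum(new_omega2, (config.anneal ** 2) * omega ** 2)
        omega = np.sqrt(np.maximum(new_omega2, _OMEGA_FLOOR ** 2))

        row = {f"{p}_pop": float(np.exp(coefs[p][0])) for p in pnames}
        row.update({f"omega_{p}": float(omega[j]) for j, p in enumerate(pnames)})
        row.update(err)
        row["iteration"] = k
        trace_rows.append(row)

    theta_hat = {p: float(np.exp(coefs[p][0])) for p in pnames}
    omega_hat = {p: float(omega[j]) for j, p in enumerate(pnames)}
    coefficients = {}
    for p in pnames:
        names, _ = model.design[p]
        for name, val in zip(names, coefs[p]):
            coefficients[name] = float(val)

    fit = FitResult(
        spec=spec, theta_hat=theta_hat, omega_hat=omega_hat,
        error_hat={k_: float(v) for k_, v in err.items()},
        coefficients=coefficients, trace=pd.DataFrame(trace_rows),
        config=config, _model=model,
        _coef_vectors={p: coefs[p].copy() for p in pnames},
    )

    # conditional samples at the final estimates (for EBEs/SEs/OFV proposals)
    cond = _conditional_samples(fit, rng, n_draws=config.se_mc_size)
    fit._cond_mean = cond.mean(axis=0)
    cc = np.empty((model.n, model.np_, model.np_))
    for i in range(model.n):
        cc[i] = np.cov(cond[:, i, :].T) + 1e-10 * np.eye(model.np_)
    fit._cond_cov = cc

    fit.ebes = ebe_table(fit)
    _check_convergence(fit)
    if config.compute_se:
        _louis_standard_errors(fit, cond)
    if config.compute_ll:
        log_likelihood(fit, config=config)
    return fit


def _check_convergence(fit: FitResult) -> None:
    """Flag fits whose estimates are implausible or whose trace still drifts.

    Non-identifiable designs make SAEM wander rather than fail loudly; the
    two symptoms checked here are estimates outside a generous physical
    range and smoothing-phase drift of the population values.
    """
    problems = []
    for p, v in fit.theta_hat.items():
        if not (1e-6 < v < 1e6):
            problems.append(f"{p}_pop={v:.3g} outside plausible range")
    for p, v in fit.omega_hat.items():
        if v > 5.0:
            problems.append(f"omega_{p}={v:.3g} diverged")
    for e, v in fit.error_hat.items():
        if v > 5.0:
            problems.append(f"error {e}={v:.3g} diverged")
    model = fit._model
    if model is not None:
        distinct = np.unique(np.round(model.obs_t[model.mask], 6))
        if distinct.size < len(fit.spec.param_names):
            problems.append(
                f"only {distinct.size} distinct observation times for "
                f"{len(fit.spec.param_names)} structural parameters"
            )
    tr = fit.trace
    k1 = fit.config.k1
    tail = tr[tr["iteration"] > k1]
    if len(tail) >= 10:
        for p in fit.spec.param_names:
            col = tail[f"{p}_pop"].to_numpy()
            lo = np.log(np.maximum(col, 1e-12))
            if abs(lo[-1] - lo[len(lo) // 2]) > 0.5:
                problems.append(f"{p}_pop drifted during the smoothing phase")
    if problems:
        fit.converged = False
        fit.message = ("flagged non-convergence (likely non-identifiable from "
                       "this design): " + "; ".join(problems))
        warnings.warn(f"SAEM non-convergence: {fit.message}")


def _conditional_samples(fit: FitResult, rng, n_draws: int = 400,
                         thin: int = 2, burn: int = 50) -> np.ndarray:
    """MCMC draws of phi from the conditional p(phi_i | y_i) at the estimates.

    Returns an array of shape (n_draws, n_subjects, P).
    """
    model = fit._model
    mu = model.mu(fit._coef_vectors)
    omega = np.array([fit.omega_hat[p] for p in model.param_names])
    state = _MCMCState(model, 1, rng)
    out = np.empty((n_draws, model.n, model.np_))
    for k in range(burn + n_draws * thin):
        state.sweep(mu, omega, fit.error_hat)
        if k >= burn and (k - burn) % thin == 0:
            out[(k - burn) // thin] = mu + state.eta[0]
    return out


# ---------------------------------------------------------------------------
# Likelihood, information criteria
# ---------------------------------------------------------------------------

def log_likelihood(fit: FitResult, dataset: Dataset | None = None,
                   config: SAEMConfig | None = None, seed: int | None = None) -> float:
    """Importance-sampling estimate of OFV = -2 log L; updates AIC/BIC in place.

    The proposal for each subject is a Gaussian fitted to the conditional
    MCMC samples.  With degenerate omega (all SDs at the floor) the integral
    collapses and the exact Gaussian-residual likelihood is used instead.
    """
    config = config or fit.config or SAEMConfig()
    model = fit._model if dataset is None else _Model(dataset, fit.spec)
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    mu = model.mu(fit._coef_vectors)
    omega = np.array([fit.omega_hat[p] for p in model.param_names])

    if np.all(omega <= _OMEGA_FLOOR * 1.01):
        ll = float(model.loglik_obs(mu, fit.error_hat).sum())
        fit.ofv_mc_se = 0.0
    else:
        kmc = config.ll_mc_size
        mean = fit._cond_mean if fit._cond_mean is not None else mu
        cov = fit._cond_cov
        ll = 0.0
        var_sum = 0.0
        for i in range(model.n):
            ci = (cov[i] if cov is not None
                  else np.diag(np.maximum(omega, _OMEGA_FLOOR) ** 2))
            ci = ci * 1.5  # inflate the proposal for tail coverage
            lchol = np.linalg.cholesky(ci)
            z = rng.standard_normal((kmc, model.np_))
            phi = mean[i][None, :] + z @ lchol.T
            # conditional log-lik of subject i for all draws at once
            sub = _SingleSubjectView(model, i)
            ll_obs = sub.loglik_obs(phi, fit.error_hat)
            lp_prior = stats.norm.logpdf(
                phi, loc=mu[i][None, :],
                scale=np.maximum(omega, _OMEGA_FLOOR)[None, :]).sum(axis=1)
            lp_prop = (stats.multivariate_normal.logpdf(phi, mean=mean[i], cov=ci)
                       if model.np_ > 1 else
                       stats.norm.logpdf(phi[:, 0], mean[i][0], np.sqrt(ci[0, 0])))
            logw = ll_obs + lp_prior - lp_prop
            li = logsumexp(logw) - np.log(kmc)
            ll += float(li)
            w = np.exp(logw - logw.max())
            var_sum += float(np.var(w) / (np.mean(w) ** 2 * kmc))
        fit.ofv_mc_se = 2.0 * float(np.sqrt(var_sum))

    fit.ofv = -2.0 * ll
    k = fit.spec.n_parameters(model.n_coef)
    n_big = model.n if config.bic_n == "subjects" else model.n_obs
    fit.n_parameters = k
    fit.bic_sample_size = n_big
    fit.aic = fit.ofv + 2 * k
    fit.bic = fit.ofv + k * np.log(max(n_big, 1))
    return fit.ofv


class _SingleSubjectView:
    """Evaluate one subject's conditional likelihood for many phi draws at once."""

    def __init__(self, model: _Model, i: int):
        self.model = model
        self.i = i

    def loglik_obs(self, phi: np.ndarray, err: dict[str, float]) -> np.ndarray:
        m, i = self.model, self.i
        k = phi.shape[0]
        f = m.conc_fn(np.exp(np.clip(phi, -_PHI_CLIP, _PHI_CLIP)),
                      np.broadcast_to(m.dose_t[i], (k, m.dose_t.shape[1])),
                      np.broadcast_to(m.dose_amt[i], (k, m.dose_amt.shape[1])),
                      np.broadcast_to(m.obs_t[i], (k, m.obs_t.shape[1])))
        sd = m.resid_sd(f, err)
        ll = -np.log(sd) - 0.5 * ((m.dv[i][None] - f) / sd) ** 2 - 0.5 * np.log(2 * np.pi)
        out = np.where(m.mask[i][None], ll, 0.0).sum(axis=1)
        return np.where(np.isfinite(out), out, -1e100)


# ---------------------------------------------------------------------------
# Standard errors (Louis' identity)
# ---------------------------------------------------------------------------

def _louis_standard_errors(fit: FitResult, cond: np.ndarray) -> None:
    """Observed Fisher information from conditional draws of phi.

    The complete-data log-likelihood separates into the Gaussian phi-part
    (coefficients and omegas) and the residual-error part, so its score and
    Hessian are analytic; Louis' identity combines their conditional moments.
    Parameters are taken on the scale they are estimated on (coefficients as
    is, omegas and error coefficients on the log scale), so RSE% of a
    population value exp(coef) equals 100*SE(coef).
    """
    model = fit._model
    pnames = model.param_names
    omega = np.array([max(fit.omega_hat[p], _OMEGA_FLOOR) for p in pnames])
    err = fit.error_hat
    kdraws = cond.shape[0]

    labels: list[str] = []
    for p in pnames:
        labels.extend(model.design[p][0])
    labels.extend([f"omega_{p}" for p in pnames])
    labels.extend(list(fit.spec.error_param_names))
    dim = len(labels)

    info = np.zeros((dim, dim))
    col_of = {lab: j for j, lab in enumerate(labels)}

    # precompute error-part statistics per draw/subject
    prop = fit.spec.error_model == "proportional"
    for i in range(model.n):
        scores = np.zeros((kdraws, dim))
        hess = np.zeros((kdraws, dim, dim))
        phi_i = cond[:, i, :]
        off = 0
        for j, p in enumerate(pnames):
            names, x = model.design[p]
            xi = x[i]
            c = len(names)
            mu_ip = xi @ fit._coef_vectors[p]
            r = phi_i[:, j] - mu_ip
            w2 = omega[j] ** 2
            scores[:, off:off + c] = (r / w2)[:, None] * xi[None, :]
            hess[:, off:off + c, off:off + c] = np.outer(xi, xi)[None] / w2
            jo = col_of[f"omega_{p}"]
            scores[:, jo] = -1.0 + r ** 2 / w2
            hess[:, jo, jo] = 2.0 * r ** 2 / w2
            cross = (2.0 * r / w2)[:, None] * xi[None, :]
            hess[:, off:off + c, jo] = cross
            hess[:, jo, off:off + c] = cross
            off += c
        # error part (proportional / additive exact; combined via numeric diff)
        sub = _SingleSubjectView(model, i)
        msk = model.mask[i]
        f = sub.model.conc_fn(np.exp(phi_i),
                              np.broadcast_to(model.dose_t[i], (kdraws, model.dose_t.shape[1])),
                              np.broadcast_to(model.dose_amt[i], (kdraws, model.dose_amt.shape[1])),
                              np.broadcast_to(model.obs_t[i], (kdraws, model.obs_t.shape[1])))
        resid = model.dv[i][None] - f
        if prop:
            jb = col_of["b"]
            valid = msk[None] & (f > _F_TRIM)
            ratio2 = np.where(valid, (resid / np.maximum(f, _F_TRIM)) ** 2, 0.0).sum(axis=1)
            nval = valid.sum(axis=1)
            scores[:, jb] = -nval + ratio2 / err["b"] ** 2
            hess[:, jb, jb] = 2.0 * ratio2 / err["b"] ** 2
        else:
            jb = col_of[fit.spec.error_param_names[0]]
            sd = model.resid_sd(f, err)
            r2s = np.where(msk[None], (resid / sd) ** 2, 0.0).sum(axis=1)
            nobs_i = int(msk.sum())
            scores[:, jb] = -nobs_i + r2s
            hess[:, jb, jb] = 2.0 * r2s

        e_h = hess.mean(axis=0)
        s_bar = scores.mean(axis=0)
        cov_s = (scores - s_bar).T @ (scores - s_bar) / kdraws
        info += e_h - cov_s

    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        if np.any(diag < 0):
            raise np.linalg.LinAlgError("negative variance")
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        diag = np.abs(np.diag(cov))
        fit.message += " Fisher information not positive definite; SEs from pseudo-inverse."
    se_vec = np.sqrt(diag)

    se, rse = {}, {}
    for j, lab in enumerate(labels):
        se[lab] = float(se_vec[j])
        if lab.endswith("_pop"):
            p = lab[:-4]
            est = fit.theta_hat[p]
            se[lab] = est * float(se_vec[j])        # delta method, log scale
            rse[lab] = 100.0 * float(se_vec[j])
        elif lab.startswith("omega_"):
            p = lab.split("_", 1)[1]
            est = fit.omega_hat[p]
            se[lab] = est * float(se_vec[j])
            rse[lab] = 100.0 * float(se_vec[j])
        elif lab in fit.error_hat:
            est = fit.error_hat[lab]
            se[lab] = est * float(se_vec[j])
            rse[lab] = 100.0 * float(se_vec[j])
        else:
            est = fit.coefficients.get(lab, np.nan)
            rse[lab] = 100.0 * float(se_vec[j]) / abs(est) if est else float("inf")
    fit.se = se
    fit.rse_percent = rse


def fit_from_population_model(dataset: Dataset, popmodel,
                              config: SAEMConfig | None = None,
                              compute_ebes: bool = True) -> FitResult:
    """Evaluation-only FitResult at known population values (no estimation).

    Wraps a :class:`~nebpk.population.PopulationModel` so that EBEs,
    diagnostics and the covariate search can be run against a model whose
    parameters are fixed — e.g. the generating model of a simulation study.
    Uses the base two-compartment spec without covariate terms; the
    population covariate effects, if any, are intentionally left out so that
    their signal appears in the random effects.
    """
    config = config or SAEMConfig()
    spec = ModelSpec()
    model = _Model(dataset, spec)
    coefs = {}
    for p in model.param_names:
        c = np.zeros(model.design[p][1].shape[1])
        c[0] = np.log(getattr(popmodel.theta, p))
        coefs[p] = c
    omega_hat = {p: max(popmodel.omega.get(p, 0.0), _OMEGA_FLOOR)
                 for p in model.param_names}
    fit = FitResult(
        spec=spec,
        theta_hat={p: float(np.exp(coefs[p][0])) for p in model.param_names},
        omega_hat=omega_hat,
        error_hat={"b": max(popmodel.b, 1e-4)},
        coefficients={f"{p}_pop": float(coefs[p][0]) for p in model.param_names},
        config=config, _model=model, _coef_vectors=coefs,
    )
    if compute_ebes:
        fit.ebes = ebe_table(fit)
    return fit


# ---------------------------------------------------------------------------
# Empirical Bayes estimates
# ---------------------------------------------------------------------------

def ebe_map(fit: FitResult, subject_id) -> dict[str, float]:
    """Mode of the conditional distribution of one subject's random effects.

    Subjects without observations return the prior mode (all zeros); as
    omega -> 0 the mode shrinks to zero through the prior term.
    """
    model = fit._model
    i = model.subject_ids.index(subject_id)
    mu = model.mu(fit._coef_vectors)[i]
    omega = np.array([max(fit.omega_hat[p], _OMEGA_FLOOR) for p in model.param_names])
    if not model.mask[i].any():
        return dict.fromkeys(model.param_names, 0.0)
    sub = _SingleSubjectView(model, i)

    def neg_post(eta):
        ll = sub.loglik_obs((mu + eta)[None, :], fit.error_hat)[0]
        return -(ll - 0.5 * np.sum((eta / omega) ** 2))

    starts = [np.zeros(model.np_)]
    if fit._cond_mean is not None:
        starts.append(fit._cond_mean[i] - mu)
    best = None
    for x0 in starts:
        res = optimize.minimize(neg_post, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8,
                                         "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    return dict(zip(model.param_names, (float(v) for v in best.x)))


def ebe_table(fit: FitResult) -> pd.DataFrame:
    """EBEs for every subject: one row per subject, eta_<param> columns."""
    model = fit._model
    rows = []
    for sid in model.subject_ids:
        eta = ebe_map(fit, sid)
        rows.append({"ID": sid, **{f"eta_{p}": v for p, v in eta.items()}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Covariate search (forward/backward on EBEs)
# ---------------------------------------------------------------------------

def _cov_column(cov: str, cov_df: pd.DataFrame):
    if cov in _CONTINUOUS_COVS:
        col, ref = _CONTINUOUS_COVS[cov]
        return np.log(cov_df[col].to_numpy(float) / ref)
    return cov_df["GENO"].to_numpy()


def _term_pvalue(eta: np.ndarray, cov: str, cov_df: pd.DataFrame,
                 adjust: list[str]) -> float:
    """p-value of covariate vs random effect, adjusted for included covariates.

    The random effect is residualised on the already-included covariates of
    the same parameter; continuous covariates use Pearson's correlation test,
    the genotype class uses one-way ANOVA.
    """
    resid = eta.astype(float).copy()
    if adjust:
        cols = [np.ones(len(resid))]
        for a in adjust:
            v = _cov_column(a, cov_df)
            if v.dtype.kind in "OU":  # genotype: indicator columns
                cols.append((v == "IM").astype(float))
                cols.append((v == "PM").astype(float))
            else:
                cols.append(v)
        x = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(x, resid, rcond=None)
        resid = resid - x @ beta
    v = _cov_column(cov, cov_df)
    if v.dtype.kind in "OU":
        groups = [resid[v == g] for g in np.unique(v)]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            return 1.0
        return float(stats.f_oneway(*groups).pvalue)
    if np.allclose(v, v[0]):
        return 1.0
    return float(stats.pearsonr(v, resid).pvalue)


def covariate_search(fit: FitResult, candidates: list[tuple[str, str]],
                     p_in: float = 0.05, p_out: float = 0.05):
    """Forward/backward covariate selection on the empirical Bayes estimates.

    Iteratively adds the candidate (parameter, covariate) pair with the
    smallest p-value below ``p_in`` and removes the included term with the
    largest p-value above ``p_out`` until the set is stable.  Returns the
    final :class:`ModelSpec` and a ledger of (step, action, term, p) tuples.
    """
    if fit.ebes is None:
        raise ValueError("fit has no EBEs")
    cov_df = fit._model.cov_df
    # drop duplicate / collinear candidates, keeping first occurrence
    seen = set()
    cand = []
    for term in candidates:
        if term in seen:
            warnings.warn(f"duplicate candidate {term}; keeping first occurrence")
            continue
        seen.add(term)
        cand.append(tuple(term))
    included = [t for t in fit.spec.covariate_terms]
    ledger: list[tuple[int, str, tuple[str, str], float]] = []
    step = 0
    while step < 25:
        step += 1
        changed = False
        # forward
        best_term, best_p = None, None
        for term in cand:
            if term in included:
                continue
            p, cov = term
            eta = fit.ebes[f"eta_{p}"].to_numpy()
            adj = [c for q, c in included if q == p]
            pv = _term_pvalue(eta, cov, cov_df, adj)
            if pv < p_in and (best_p is None or pv < best_p):
                best_term, best_p = term, pv
        if best_term is not None:
            included.append(best_term)
            ledger.append((step, "add", best_term, best_p))
            changed = True
        # backward
        worst_term, worst_p = None, None
        for term in included:
            p, cov = term
            eta = fit.ebes[f"eta_{p}"].to_numpy()
            adj = [c for q, c in included if q == p and (q, c) != term]
            pv = _term_pvalue(eta, cov, cov_df, adj)
            if pv > p_out and (worst_p is None or pv > worst_p):
                worst_term, worst_p = term, pv
        if worst_term is not None:
            included.remove(worst_term)
            ledger.append((step, "remove", worst_term, worst_p))
            changed = True
            if ledger[-2][1:3] == ("add", worst_term):
                break  # adding and immediately removing the same term: stable
        if not changed:
            break
    final = replace(fit.spec, covariate_terms=tuple(included))
    return final, ledger


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def model_select(dataset: Dataset, specs: list[ModelSpec],
                 config: SAEMConfig | None = None):
    """Fit every candidate spec and return the one minimising BIC.

    Ties within 0.01 BIC points resolve to the model with fewer estimated
    parameters.  Returns ``(best_spec, table, fits)`` where ``table`` has one
    row per candidate with ofv/aic/bic, and ``fits`` maps spec -> FitResult.
    """
    if not specs:
        raise ValueError("need at least one candidate ModelSpec")
    config = config or SAEMConfig()
    rows = []
    fits: dict[ModelSpec, FitResult] = {}
    failures = []
    for spec in specs:
        try:
            fit = saem_fit(dataset, spec, config)
        except Exception as exc:  # noqa: BLE001 - collected and reported
            failures.append((spec, exc))
            continue
        fits[spec] = fit
        rows.append({"structure": spec.structure, "error_model": spec.error_model,
                     "n_covariate_terms": len(spec.covariate_terms),
                     "k": fit.n_parameters, "ofv": fit.ofv, "aic": fit.aic,
                     "bic": fit.bic, "converged": fit.converged})
    if not fits:
        raise RuntimeError(f"all candidate fits failed: {failures}")
    table = pd.DataFrame(rows)
    order = sorted(fits, key=lambda s: (round(fits[s].bic / 0.01) * 0.01,
                                        fits[s].n_parameters))
    best = order[0]
    return best, table, fits
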