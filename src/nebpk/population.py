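"""Synthetic-cohort generator: the statistical population model.

Recreates the statistical structure assumed by the analysis — demographics of
a young healthy adult pool, multiplicative covariate effects on the apparent
parameters, lognormal inter-individual variability (IIV) and proportional
residual error — and emits event-stream datasets from a study-design table.

The default study design reproduces the pooled literature population: thirty
subjects, of whom one received 20 mg daily for 27 days, five a single 5 mg
dose and twenty-four a single 10 mg dose.  Demographics default to
age ~ Normal(26.70, 1.40) truncated to [20, 34] years, BMI ~ Normal(25, 1),
and CYP2D6 metaboliser classes EM/IM/PM with probabilities 17/30, 12/30 and
1/30.

Individual parameters are multiplicative:

    cl_i   = cl_pop * (age_i/age_ref)^beta_age_cl * exp(beta_geno_cl) * exp(eta_cl)
    v1_i   = v1_pop * exp(beta_geno_v1) * exp(eta_v1)
    tlag_i = tlag_pop * exp(beta_geno_tlag) * exp(eta_tlag)

with ka, q, v2 carrying random effects only, eta ~ N(0, omega^2) per
parameter.  The covariate coefficients are not reported by the source
analysis; they default to 0 and exist so that the covariate-search machinery
has ground truth to recover in simulation studies.

An optional *shared exposure* random effect scales cl, v1, q and v2 of a
subject by one common lognormal factor.  Because the micro rate constants are
ratios of these four parameters, this factor moves every concentration of the
subject proportionally — the natural representation of unexplained
bioavailability variability (CYP2D6-driven F spans roughly 12–96% for
nebivolol) and the handle the attainment calibration adjusts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import Dataset, GENOTYPES
from .structural import PARAM_NAMES, PKParams, conc_matrix

__all__ = [
    "CovariateSet",
    "CovariateModel",
    "PopulationModel",
    "VirtualSubject",
    "StudyArm",
    "sample_covariates",
    "individual_params",
    "add_residual_error",
    "generate_dataset",
    "default_design",
    "default_population_model",
    "TABLE_DEMOGRAPHICS",
]

#: Demographic summary of the pooled literature population.
TABLE_DEMOGRAPHICS = {
    "age_mean": 26.70,
    "age_sd": 1.40,
    "age_range": (20.0, 34.0),
    "bmi_mean": 25.0,
    "bmi_sd": 1.0,
    "genotype_probs": {"EM": 17 / 30, "IM": 12 / 30, "PM": 1 / 30},
}

#: Rich post-dose sampling schedule (h), spanning the 48 h observation window.
DEFAULT_SAMPLING_TIMES = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0,
                          24.0, 36.0, 48.0)


@dataclass(frozen=True)
class CovariateSet:
    """Subject-level covariates: age (years), BMI (kg/m^2), CYP2D6 class."""

    age: float
    bmi: float
    genotype: str
    plausible_age_range: tuple[float, float] = (18.0, 80.0)

    def __post_init__(self) -> None:
        lo, hi = self.plausible_age_range
        if not lo <= self.age <= hi:
            raise ValueError(f"age {self.age} outside plausible range [{lo}, {hi}]")
        if self.bmi <= 0:
            raise ValueError(f"bmi must be > 0, got {self.bmi}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")


@dataclass(frozen=True)
class CovariateModel:
    """Multiplicative covariate effects, log-scale, EM as reference class."""

    beta_age_cl: float = 0.0
    age_ref: float = 26.7
    beta_im_cl: float = 0.0
    beta_pm_cl: float = 0.0
    beta_im_v1: float = 0.0
    beta_pm_v1: float = 0.0
    beta_im_tlag: float = 0.0
    beta_pm_tlag: float = 0.0

    def log_shifts(self, cov: CovariateSet) -> dict[str, float]:
        """Per-parameter log-scale shift for one subject's covariates."""
        shifts = dict.fromkeys(PARAM_NAMES, 0.0)
        shifts["cl"] += self.beta_age_cl * np.log(cov.age / self.age_ref)
        if cov.genotype == "IM":
            shifts["cl"] += self.beta_im_cl
            shifts["v1"] += self.beta_im_v1
            shifts["tlag"] += self.beta_im_tlag
        elif cov.genotype == "PM":
            shifts["cl"] += self.beta_pm_cl
            shifts["v1"] += self.beta_pm_v1
            shifts["tlag"] += self.beta_pm_tlag
        return shifts


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, IIV magnitudes, covariate model and residual error.

    ``omega`` holds the lognormal random-effect SDs per parameter
    (dimensionless, log scale); ``b`` is the proportional residual-error
    coefficient; ``shared_exposure_sd`` the SD of the common lognormal
    exposure factor applied to (cl, v1, q, v2) jointly.
    """

    theta: PKParams
    omega: dict[str, float] = field(default_factory=lambda: dict.fromkeys(PARAM_NAMES, 0.2))
    covmodel: CovariateModel = field(default_factory=CovariateModel)
    b: float = 0.13
    shared_exposure_sd: float = 0.0

    def __post_init__(self) -> None:
        for name, val in self.omega.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown omega entry {name!r}")
            if val < 0:
                raise ValueError(f"omega[{name!r}] must be >= 0")
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.shared_exposure_sd < 0:
            raise ValueError("shared_exposure_sd must be >= 0")

    def omega_vector(self) -> np.ndarray:
        return np.array([self.omega.get(n, 0.0) for n in PARAM_NAMES])

    def replace(self, **kwargs) -> "PopulationModel":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class VirtualSubject:
    id: object
    covariates: CovariateSet
    params: PKParams


@dataclass(frozen=True)
class StudyArm:
    """One row of the study-design table."""

    dose: float                      # mg per administration
    n_subjects: int
    n_doses: int = 1
    interval: float = 24.0           # h between doses (multi-dose arms)
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES  # h after last dose
    label: str = ""


def default_design() -> list[StudyArm]:
    """The pooled 30-subject design: 1x20 mg qd 27 d, 5x5 mg, 24x10 mg."""
    return [
        StudyArm(dose=20.0, n_subjects=1, n_doses=27, interval=24.0, label="20mg-qd-27d"),
        StudyArm(dose=5.0, n_subjects=5, label="5mg-single"),
        StudyArm(dose=10.0, n_subjects=24, label="10mg-single"),
    ]


def default_population_model() -> PopulationModel:
    """Population model at the reported final estimates with default IIV."""
    return PopulationModel(
        theta=PKParams(tlag=0.30, ka=2.06, cl=0.22, v1=4.21, q=0.59, v2=7.12)
    )


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_covariates(n: int, seed=None,
                      demographics: dict = TABLE_DEMOGRAPHICS) -> list[CovariateSet]:
    """Draw ``n`` covariate sets from the study demographics.

    Age is truncated normal on the observed range; genotype frequencies follow
    the observed class counts.  Reproducible for a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(seed)
    d = demographics
    lo, hi = d["age_range"]
    a = (lo - d["age_mean"]) / d["age_sd"]
    b = (hi - d["age_mean"]) / d["age_sd"]
    ages = stats.truncnorm.rvs(a, b, loc=d["age_mean"], scale=d["age_sd"],
                               size=n, random_state=rng)
    bmis = rng.normal(d["bmi_mean"], d["bmi_sd"], size=n)
    bmis = np.maximum(bmis, 1e-6)
    classes = list(d["genotype_probs"])
    probs = np.array([d["genotype_probs"][g] for g in classes])
    genos = rng.choice(classes, size=n, p=probs / probs.sum())
    return [CovariateSet(age=float(ages[i]), bmi=float(bmis[i]), genotype=str(genos[i]))
            for i in range(n)]


def individual_params(theta: PKParams, covmodel: CovariateModel, cov: CovariateSet,
                      eta: dict[str, float] | None = None) -> PKParams:
    """Individual parameters from population values, covariates and random effects.

    With all betas and etas zero the output equals ``theta`` exactly.
    """
    eta = eta or {}
    shifts = covmodel.log_shifts(cov)
    values = {}
    for name in PARAM_NAMES:
        log_val = np.log(getattr(theta, name)) + shifts[name] + eta.get(name, 0.0)
        values[name] = float(np.exp(log_val))
    return PKParams(**values)


def add_residual_error(c, b: float, seed=None):
    """Proportional residual error ``y = c * (1 + b*eps)``, eps ~ N(0, 1).

    Negative draws are truncated to 0 (concentrations are physical; the event
    has negligible probability at b = 0.13).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    if b < 0:
        raise ValueError("b must be >= 0")
    if b == 0:
        return c.copy() if c.ndim else float(c)
    rng = _rng(seed)
    y = c * (1.0 + b * rng.standard_normal(c.shape))
    y = np.maximum(y, 0.0)
    return y if y.ndim else float(y)


def sample_etas(popmodel: PopulationModel, n: int, rng) -> np.ndarray:
    """Draw (n, 6) log-scale random effects, including the shared exposure factor.

    The shared factor multiplies concentrations by exp(+eta_shared), which is
    implemented as dividing cl, v1, q and v2 by its exponential (the micro
    rate constants are unchanged by a common scaling of those four).
    """
    omega = popmodel.omega_vector()
    etas = rng.standard_normal((n, len(PARAM_NAMES))) * omega[None, :]
    if popmodel.shared_exposure_sd > 0:
        shared = rng.standard_normal(n) * popmodel.shared_exposure_sd
        for j, name in enumerate(PARAM_NAMES):
            if name in ("cl", "v1", "q", "v2"):
                etas[:, j] -= shared
    return etas


def draw_subjects(popmodel: PopulationModel, n: int, seed=None,
                  covariates: list[CovariateSet] | None = None,
                  demographics: dict = TABLE_DEMOGRAPHICS) -> list[VirtualSubject]:
    """Sample ``n`` virtual subjects (covariates, then individual parameters)."""
    rng = _rng(seed)
    if covariates is None:
        covariates = sample_covariates(n, rng, demographics)
    elif len(covariates) != n:
        raise ValueError("covariates length must equal n")
    etas = sample_etas(popmodel, n, rng)
    out = []
    for i, cov in enumerate(covariates):
        eta = dict(zip(PARAM_NAMES, etas[i]))
        out.append(VirtualSubject(id=i + 1,
                                  covariates=cov,
                                  params=individual_params(popmodel.theta,
                                                           popmodel.covmodel, cov, eta)))
    return out


def generate_dataset(design: list[StudyArm] | None = None,
                     popmodel: PopulationModel | None = None,
                     seed=None, demographics: dict = TABLE_DEMOGRAPHICS) -> Dataset:
    """Simulate an event-stream dataset from a study design.

    Each subject receives the arm's dose schedule; observations are placed at
    the arm's sampling times after the last dose, with proportional residual
    error on the model-predicted concentrations.
    """
    if design is None:
        design = default_design()
    if popmodel is None:
        popmodel = default_population_model()
    rng = _rng(seed)
    rows: list[dict] = []
    next_id = 1
    for arm in design:
        if arm.n_subjects == 0:
            continue
        subjects = draw_subjects(popmodel, arm.n_subjects, rng, demographics=demographics)
        dose_times = np.arange(arm.n_doses) * arm.interval
        last_dose = float(dose_times[-1])
        obs_times = last_dose + np.asarray(arm.sampling_times, dtype=float)
        params = np.vstack([s.params.as_array() for s in subjects])
        conc = conc_matrix(
            params,
            np.broadcast_to(dose_times, (len(subjects), arm.n_doses)),
            np.full((len(subjects), arm.n_doses), arm.dose),
            np.broadcast_to(obs_times, (len(subjects), obs_times.size)),
        )
        dv = add_residual_error(conc, popmodel.b, rng)
        for i, subj in enumerate(subjects):
            sid = next_id
            next_id += 1
            base = {"ID": sid, "AGE": subj.covariates.age, "BMI": subj.covariates.bmi,
                    "GENO": subj.covariates.genotype}
            for td in dose_times:
                rows.append({**base, "TIME": float(td), "AMT": arm.dose,
                             "DV": np.nan, "EVID": 1})
            for j, t in enumerate(obs_times):
                rows.append({**base, "TIME": float(t), "AMT": 0.0,
                             "DV": float(dv[i, j]), "EVID": 0})
    if not rows:
        return Dataset.empty()
    return Dataset.from_rows(rows)
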